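"""Genotype editing-site alleles across synthetic species sequences.

Uses the packaged C/T 31-mer pairs to genotype a small synthetic gene
collection: one sequence carries the editable C allele, one the pre-edited
genomic T (on the reverse strand), and one lacks the site. The genomic calls
are then combined with transcript editing observations into an editotype
matrix (edited / unedited C / genomic T / no data).
"""

import numpy as np

from organedit import build_editotype, editotype_matrix, load_kmer_pairs, revcomp, scan_alleles
from organedit.allelescan import NDHB_PREEDITED_PEPTIDE, scan_peptide

pair = next(p for p in load_kmer_pairs() if p.site_name == "ndhB-291")
rng = np.random.default_rng(9)
flank = lambda n: "".join(rng.choice(list("ACGT"), size=n))

species_seqs = {
    "brassica_like": {"gene1": flank(40) + pair.kmer_C + flank(40)},
    "cacao_like": {"gene1": flank(30) + pair.kmer_C + flank(30)},
    "preedited_sp": {"gene1": flank(25) + revcomp(pair.kmer_T) + flank(25)},
    "divergent_sp": {"gene1": flank(90)},
}
calls = {sp: scan_alleles(seqs, pair) for sp, seqs in species_seqs.items()}
for sp, cs in calls.items():
    print(f"{sp:<14} call={cs[0].call:<9} strand={cs[0].strand_found}")

observations = {
    "brassica_like": {"ndhB-291": True},   # transcript editing observed
    "cacao_like": {"ndhB-291": False},     # editable C, never edited
}
matrix = editotype_matrix(build_editotype(calls, observations))
print("\neditotype matrix:")
print(matrix.to_string())

codons = {
    "R": "CGT", "I": "ATT", "F": "TTT", "D": "GAT", "P": "CCT", "Y": "TAT",
    "L": "TTA", "S": "TCT", "N": "AAT", "E": "GAA", "W": "TGG", "H": "CAT",
}
preedited_dna = "GA" + "".join(codons[aa] for aa in NDHB_PREEDITED_PEPTIDE) + "TT"
hits = scan_peptide({"preedited_dna": preedited_dna}, NDHB_PREEDITED_PEPTIDE)
print(f"\n6-frame pre-edited peptide scan hits: {len(hits)} "
      "(a hit means the leucine codon is already encoded in the DNA)")
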