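# organedit

Discovery and characterization of C-to-U RNA-editing off-target sites in
plant organellar transcriptomes.

## The problem

In chloroplasts and mitochondria of land plants, specific cytidines are
post-transcriptionally deaminated to uridines. Each edited C is recognised
by a pentatricopeptide-repeat (PPR) protein whose ordered array of P/L/S
motifs reads the RNA one repeat per base; the amino acids at motif positions
5 and last select the preferred nucleotide (the "PPR code"). When such a
factor is expressed outside its native context — or simply overexpressed —
it can edit dozens of *off-target* cytidines, detectable as C→T
substitutions in strand-specific RNA-seq of cDNA.

`organedit` implements the computational workflow around this phenomenon as
a reusable, fully testable library:

- **Synthetic data** — toy organellar genomes and strand-specific paired-end
  reads (2 × 150 nt, ~250 bp inserts) with per-site binomial editing
  fractions, partial intron splicing, antisense transcription and per-base
  error, so every downstream stage can be validated against known truth.
- **Reference preparation** — IUPAC masking of known editing sites
  (C→`Y` on the plus strand, G→`R` on the minus strand, so alignment is
  unbiased for or against edited reads) and inverted-repeat collapse
  (removal of the second IR copy, keeping 75 nt borders).
- **Mapping** — a built-in substitution-only aligner (k-mer seed +
  ungapped extension) with the organellar read-pair selection rule (both
  mates > 100 nt, at least one aligned at ≥ 85 % identity over > 50 % of
  its length) and strand-aware pileups.
- **Discovery** — SNP calling at a ≥ 5 % rate, restriction to C→T / G→A
  (i.e. C→U on the transcript strand), exclusion of known sites and
  tRNA/rRNA, wild-type subtraction, editing efficiency as
  100·T/(T+C), codon-impact annotation, and high/low-affinity
  classification by whether a site is edited at moderate factor expression.
- **PPR code** — motif arrays, code-table lookup, anchoring of the last
  motif at position −4 from the edited C, per-position match/mismatch
  scorecards, base-frequency matrices and degenerate IUPAC consensus.
- **Context similarity** — mean pairwise identity in a sliding 14-nt window
  over −50..+50 windows, excluding the edited position ([C]) or −1..+1
  ([nCn]).
- **Quantification** — splice ratios from explicit exon–exon / exon–intron
  junction references, RPKM, and ΔΔCt relative expression
  (fold = 2^(−ΔΔCt)).
- **Allele scanning** — exact 31-mer C/T genotyping of editing-site alleles
  across gene collections on both strands, 6-frame pre-edited peptide
  search, and editotype matrices (edited / unedited C / genomic T / no
  data).

Three editing-percentage tables (site × library) are packaged as TSV
fixtures with exactly known values, so the threshold arithmetic of the
discovery filters can be tested without any sequencing data.

## Worked example

`examples/01_simulate_and_discover.py` builds a 900-nt toy plastome with one
CDS carrying two editable cytidines, simulates a mutant library (sites
edited at 60 % and 15 %) and an unedited wild type, and runs the full
pipeline:

```
position  strand  location  efficiency%  (simulated)
     300       +       CDS        61.6  (60)
     400       +       CDS        15.9  (15)

2 sites discovered; the wild-type library contributes the subtraction that
removes genomic SNPs and shared noise.
```

The recovered efficiencies are binomial samples of the simulated fractions;
at the ~1300× site coverage of this example, 61.6 % and 15.9 % are both
within sampling noise of the truth, and the wild-type library yields no
calls. The other examples cover the fixture-table filters
(`02_fixture_tables.py`), PPR-code scoring (`03_ppr_scoring.py`), context
similarity (`04_context_similarity.py`), splice/RPKM/ΔΔCt quantification
(`05_splice_and_expression.py`) and allele genotyping
(`06_allele_scan.py`). A thin CLI (`organedit --help`) wraps the same
operations for shell use.

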