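"""Cross-species allele genotyping by exact k-mer and peptide scans.

Whether a species carries an editable genomic C or a pre-edited genomic T
at an editing site is decided by exact matching of two 31-mers — the site
base (C or T) flanked by 15 nt on each side — against gene-sequence
collections, on both strands. A complementary 6-frame scan for a pre-edited
peptide detects genomic leucine codons at the protein level. Exact matching
keeps every call checkable by independent substring search; approximate
matching is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio.Seq import Seq

from .errors import ConfigurationError
from .genome import revcomp

KMER_LENGTH = 31
KMER_CENTER = 15  # 0-based offset of the variable site within the k-mer

# Pre-edited (S-to-L) peptide around the serine codon restored by editing
# at the focal site; a genomic hit means the plant encodes leucine in DNA.
NDHB_PREEDITED_PEPTIDE = "RIFDIPFYFLSNEWHLLLE"

EDITOTYPE_STATUSES = (
    "edited",
    "unedited_C",
    "C_unknown_editing",
    "genomic_T",
    "no_data",
    "gene_absent",
)


@dataclass(frozen=True)
class AlleleKmerPair:
    site_name: str
    kmer_C: str
    kmer_T: str

    def __post_init__(self) -> None:
        for k in (self.kmer_C, self.kmer_T):
            if len(k) != KMER_LENGTH:
                raise ConfigurationError(
                    f"{self.site_name}: k-mer length {len(k)} != {KMER_LENGTH}"
                )
        diffs = [
            i for i, (a, b) in enumerate(zip(self.kmer_C, self.kmer_T)) if a != b
        ]
        if diffs != [KMER_CENTER]:
            raise ConfigurationError(
                f"{self.site_name}: k-mers must differ exactly at offset {KMER_CENTER}"
            )
        if self.kmer_C[KMER_CENTER] != "C" or self.kmer_T[KMER_CENTER] != "T":
            raise ConfigurationError(
                f"{self.site_name}: central bases must be C and T"
            )


@dataclass(frozen=True)
class AlleleCall:
    sequence_id: str
    site_name: str
    call: str  # C | T | ambiguous | no_match
    strand_found: str | None  # + | - | both | None


def load_kmer_pairs(path: str | Path | None = None) -> list[AlleleKmerPair]:
    """K-mer pairs from TSV (site, kmer_C, kmer_T); default: packaged pairs."""
    if path is None:
        with resources.files("organedit.data").joinpath("allele_kmers.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return [
        AlleleKmerPair(
            site_name=r["site"], kmer_C=r["kmer_C"], kmer_T=r["kmer_T"]
        )
        for _, r in df.iterrows()
    ]


def _find(seq: str, kmer: str) -> str | None:
    fwd = kmer in seq
    rev = revcomp(kmer) in seq
    if fwd and rev:
        return "both"
    if fwd:
        return "+"
    if rev:
        return "-"
    return None


def scan_alleles(
    sequences: Mapping[str, str], kmers: AlleleKmerPair
) -> list[AlleleCall]:
    """Genotype each sequence for one site by exact C/T 31-mer search.

    Both strands are searched. A sequence matching both variants (e.g. a
    tandem duplication carrying both alleles) is flagged ambiguous, never
    silently resolved.
    """
    calls = []
    for seq_id, seq in sequences.items():
        seq = seq.upper().replace("U", "T")
        c_strand = _find(seq, kmers.kmer_C)
        t_strand = _find(seq, kmers.kmer_T)
        if c_strand and t_strand:
            call, strand = "ambiguous", "both"
        elif c_strand:
            call, strand = "C", c_strand
        elif t_strand:
            call, strand = "T", t_strand
        else:
            call, strand = "no_match", None
        calls.append(
            AlleleCall(
                sequence_id=seq_id, site_name=kmers.site_name, call=call,
                strand_found=strand,
            )
        )
    return calls


@dataclass(frozen=True)
class PeptideHit:
    sequence_id: str
    frame: int  # +1..+3 forward, -1..-3 reverse
    aa_offset: int  # 0-based offset of the peptide within the frame translation


def scan_peptide(
    sequences: Mapping[str, str], peptide: str
) -> list[PeptideHit]:
    """Exact peptide matches over all six reading frames of each sequence."""
    if not peptide:
        raise ConfigurationError("peptide must be non-empty")
    peptide = peptide.upper()
    hits = []
    for seq_id, seq in sequences.items():
        seq = seq.upper().replace("U", "T")
        for strand_sign, s in ((1, seq), (-1, revcomp(seq))):
            for shift in range(3):
                sub = s[shift:]
                sub = sub[: len(sub) - len(sub) % 3]
                if not sub:
                    continue
                aa = str(Seq(sub).translate())
                start = 0
                while True:
                    i = aa.find(peptide, start)
                    if i == -1:
                        break
                    hits.append(
                        PeptideHit(
                            sequence_id=seq_id,
                            frame=strand_sign * (shift + 1),
                            aa_offset=i,
                        )
                    )
                    start = i + 1
    return hits


def species_call(calls: Iterable[AlleleCall]) -> str:
    """Aggregate per-sequence calls for one species.

    C if any sequence calls C and none calls T; T symmetrically; mixed C/T
    or any ambiguous sequence -> ambiguous; otherwise no_match.
    """
    seen = {c.call for c in calls}
    if "ambiguous" in seen or {"C", "T"} <= seen:
        return "ambiguous"
    if "C" in seen:
        return "C"
    if "T" in seen:
        return "T"
    return "no_match"


@dataclass(frozen=True)
class EditotypeEntry:
    species: str
    site: str
    status: str

    def __post_init__(self) -> None:
        if self.status not in EDITOTYPE_STATUSES + ("ambiguous",):
            raise ConfigurationError(f"unknown editotype status {self.status!r}")


def build_editotype(
    calls_by_species: Mapping[str, Iterable[AlleleCall]],
    editing_observations: Mapping[str, Mapping[str, bool | None]],
) -> list[EditotypeEntry]:
    """Combine genomic allele calls with transcript editing observations.

    A genomic T is a pre-edited allele; a genomic C is classified as
    edited / unedited / unknown from the observation table (``True`` /
    ``False`` / ``None`` or absent); no k-mer match means no data.
    Conflicting sequence calls within a species surface as ambiguous.
    """
    entries = []
    for species, calls in calls_by_species.items():
        calls = list(calls)
        by_site: dict[str, list[AlleleCall]] = {}
        for c in calls:
            by_site.setdefault(c.site_name, []).append(c)
        for site, site_calls in by_site.items():
            agg = species_call(site_calls)
            if agg == "T":
                status = "genomic_T"
            elif agg == "C":
                observed = editing_observations.get(species, {}).get(site)
                if observed is True:
                    status = "edited"
                elif observed is False:
                    status = "unedited_C"
                else:
                    status = "C_unknown_editing"
            elif agg == "ambiguous":
                status = "ambiguous"
            else:
                status = "no_data"
            entries.append(EditotypeEntry(species=species, site=site, status=status))
    return entries


def editotype_matrix(entries: Iterable[EditotypeEntry]) -> pd.DataFrame:
    rows: dict[str, dict[str, str]] = {}
    for e in entries:
        rows.setdefault(e.species, {})[e.site] = e.status
    return pd.DataFrame.from_dict(rows, orient="index").fillna("no_data")
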