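"""PPR motif arrays, code-based binding prediction, and cis-element scoring.

Editing-type PPR proteins carry an ordered array of PLS-class repeats
(P1/P2, L1/L2/LL, S1/S2/SS); the amino acids at position 5 and at the last
position of each repeat jointly select the preferred RNA base, an empirical
mapping known as the PPR code. The code is degenerate: many amino-acid
combinations have no reliable prediction ("n.p.").

A cis-element (the RNA immediately upstream of the edited cytidine, here
positions -20..+5 with the edit at 0) is scored against a protein by
anchoring the last motif at position -4 and walking one motif per
nucleotide upstream, so an array of n motifs covers -4-(n-1) .. -4.
Positions outside the footprint are "unaligned"; aligned positions are
"match" when the observed base is in the predicted set, "mismatch"
otherwise, and "n.p." positions never count toward mismatch totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigurationError, DataError

MOTIF_CLASSES = {"P1", "P2", "L1", "L2", "LL", "S1", "S2", "SS"}
RNA_BASES = "ACGU"

IUPAC_FROM_SET = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("U"): "U",
    frozenset("AG"): "R",
    frozenset("CU"): "Y",
    frozenset("GU"): "K",
    frozenset("AC"): "M",
    frozenset("CG"): "S",
    frozenset("AU"): "W",
    frozenset("CGU"): "B",
    frozenset("AGU"): "D",
    frozenset("ACU"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGU"): "N",
}

# The array structure of the editing factor studied throughout this package.
QED1_MOTIF_CLASSES = (
    "L1 S1 P1 L1 S1 P1 L1 S1 SS P1 L1 S1 P2 L2 S2".split()
)
ANCHOR_OFFSET = -4


def rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class PprMotif:
    index: int  # 1-based order within the array
    mclass: str
    aa5: str
    aaLast: str
    aa2: str | None = None

    def __post_init__(self) -> None:
        if self.mclass not in MOTIF_CLASSES:
            raise ConfigurationError(f"unknown motif class {self.mclass!r}")


@dataclass
class PprProtein:
    id: str
    motifs: list[PprMotif]
    cterm: tuple[str, ...] = ("E1", "E2", "DYW")

    def __post_init__(self) -> None:
        if [m.index for m in self.motifs] != list(range(1, len(self.motifs) + 1)):
            raise ConfigurationError("motif indices must be consecutive from 1")

    @property
    def n_motifs(self) -> int:
        return len(self.motifs)


class CodeTable:
    """Editable lookup (motif class, key amino acids) -> preferred base set.

    Rules are looked up most-specific first: an exact motif-class rule wins
    over a wildcard ('*') rule. Two variants exist: the two-amino-acid code
    keys on positions 5 and last; the three-amino-acid code additionally
    uses position 2. A missing combination is not predictable (``None``).
    """

    def __init__(self, rules: dict[tuple[str, str], frozenset[str]], variant: str = "two_aa"):
        if variant not in ("two_aa", "three_aa"):
            raise ConfigurationError(f"unknown code variant {variant!r}")
        for key, bases in rules.items():
            if not bases or not set(bases) <= set(RNA_BASES):
                raise ConfigurationError(f"rule {key}: invalid base set {bases}")
        self.rules = dict(rules)
        self.variant = variant

    def lookup(self, motif: PprMotif) -> frozenset[str] | None:
        if self.variant == "three_aa":
            if motif.aa2 is None:
                return None
            key_aa = motif.aa2 + motif.aa5 + motif.aaLast
        else:
            key_aa = motif.aa5 + motif.aaLast
        for mclass in (motif.mclass, "*"):
            hit = self.rules.get((mclass, key_aa))
            if hit is not None:
                return hit
        return None

    @classmethod
    def from_tsv(cls, path: str | Path, variant: str = "two_aa") -> "CodeTable":
        df = pd.read_csv(path, sep="\t")
        return cls._from_frame(df, variant)

    @classmethod
    def default(cls, variant: str = "two_aa") -> "CodeTable":
        with resources.files("organedit.data").joinpath("ppr_code.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
        return cls._from_frame(df, variant)

    @classmethod
    def _from_frame(cls, df: pd.DataFrame, variant: str) -> "CodeTable":
        rules: dict[tuple[str, str], frozenset[str]] = {}
        for _, row in df[df["variant"] == variant].iterrows():
            bases = str(row["bases"]).strip()
            if bases in ("n.p.", ""):
                continue
            if variant == "three_aa":
                key_aa = f"{row['aa2']}{row['aa5']}{row['aaLast']}"
            else:
                key_aa = f"{row['aa5']}{row['aaLast']}"
            rules[(str(row["mclass"]), key_aa)] = frozenset(rna(bases))
        return cls(rules, variant)


@dataclass(frozen=True)
class CisElement:
    """RNA window around an edited C, spanning upstream_span..downstream_span.

    The default window is -20..+5 (26 nt) with the edited base (a C before
    editing) at offset 0.
    """

    site_name: str
    sequence: str
    edit_index: int = 20  # offset of position 0 within sequence

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", rna(self.sequence))
        if not 0 <= self.edit_index < len(self.sequence):
            raise DataError(f"{self.site_name}: edit_index out of range")
        if self.sequence[self.edit_index] != "C":
            raise DataError(
                f"{self.site_name}: base at the editing position is "
                f"{self.sequence[self.edit_index]}, expected C"
            )

    @property
    def min_offset(self) -> int:
        return -self.edit_index

    @property
    def max_offset(self) -> int:
        return len(self.sequence) - self.edit_index - 1

    def base_at(self, offset: int) -> str:
        if not self.min_offset <= offset <= self.max_offset:
            raise DataError(f"{self.site_name}: offset {offset} outside window")
        return self.sequence[self.edit_index + offset]


def predict_binding(
    protein: PprProtein, code: CodeTable
) -> list[frozenset[str] | None]:
    """Per-motif preferred base sets; ``None`` marks n.p. (not predictable)."""
    return [code.lookup(m) for m in protein.motifs]


def anchor_alignment(
    protein: PprProtein,
    cis: CisElement,
    anchor_offset: int = ANCHOR_OFFSET,
) -> dict[int, int]:
    """Map motif index -> cis-element offset with the last motif at the anchor.

    Motif k (of n) aligns to ``anchor_offset - (n - k)``; 15 motifs anchored
    at -4 therefore cover -18..-4.
    """
    if protein.n_motifs < 1:
        raise ConfigurationError("protein has no motifs")
    n = protein.n_motifs
    mapping = {k: anchor_offset - (n - k) for k in range(1, n + 1)}
    first = mapping[1]
    if first < cis.min_offset or anchor_offset > cis.max_offset:
        raise DataError(
            f"motif footprint {first}..{anchor_offset} extends beyond the cis "
            f"window {cis.min_offset}..{cis.max_offset}"
        )
    return mapping


@dataclass
class Scorecard:
    site_name: str
    verdicts: dict[int, str]  # cis offset -> match | mismatch | n.p. | unaligned
    motif_verdicts: dict[int, str]  # motif index -> verdict
    total_mismatches: int
    evaluable_positions: int


def score_cis_element(
    cis: CisElement,
    prediction: Sequence[frozenset[str] | None],
    anchoring: dict[int, int],
) -> Scorecard:
    """Score one cis-element against a per-motif prediction.

    n.p. and unaligned positions never contribute to the mismatch total.
    """
    offset_to_motif = {off: k for k, off in anchoring.items()}
    verdicts: dict[int, str] = {}
    motif_verdicts: dict[int, str] = {}
    mismatches = 0
    evaluable = 0
    for off in range(cis.min_offset, cis.max_offset + 1):
        k = offset_to_motif.get(off)
        if k is None:
            verdicts[off] = "unaligned"
            continue
        pred = prediction[k - 1]
        if pred is None:
            verdicts[off] = motif_verdicts[k] = "n.p."
            continue
        evaluable += 1
        if cis.base_at(off) in pred:
            verdicts[off] = motif_verdicts[k] = "match"
        else:
            verdicts[off] = motif_verdicts[k] = "mismatch"
            mismatches += 1
    return Scorecard(
        site_name=cis.site_name,
        verdicts=verdicts,
        motif_verdicts=motif_verdicts,
        total_mismatches=mismatches,
        evaluable_positions=evaluable,
    )


def score_table(scorecards: Iterable[Scorecard]) -> pd.DataFrame:
    """Site x motif verdict table with per-site and per-motif mismatch margins."""
    cards = list(scorecards)
    rows = {c.site_name: c.motif_verdicts for c in cards}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df["total_mismatches"] = [c.total_mismatches for c in cards]
    return df


def frequency_matrix(
    elements: Iterable[CisElement], span: tuple[int, int] = (-20, 5)
) -> pd.DataFrame:
    """Per-offset base frequencies (rows A/C/G/U, columns offsets; sum to 1)."""
    elements = list(elements)
    if not elements:
        raise ConfigurationError("no cis-elements supplied")
    lo, hi = span
    for e in elements:
        if lo < e.min_offset or hi > e.max_offset:
            raise DataError(f"{e.site_name}: does not cover span {lo}..{hi}")
    offsets = list(range(lo, hi + 1))
    freqs = pd.DataFrame(0.0, index=list(RNA_BASES), columns=offsets)
    for e in elements:
        for off in offsets:
            b = e.base_at(off)
            if b in RNA_BASES:
                freqs.at[b, off] += 1
    return freqs / len(elements)


def degenerate_consensus(
    freqs: pd.DataFrame, include_threshold: float = 0.25
) -> str:
    """IUPAC consensus: per offset, the code of {base : freq >= threshold}.

    The editing position (offset 0, when present) is fixed to C; an empty
    included set yields N.
    """
    if not 0 < include_threshold < 1:
        raise ConfigurationError("include_threshold must lie in (0, 1)")
    out = []
    for off in freqs.columns:
        if off == 0:
            out.append("C")
            continue
        included = frozenset(
            b for b in RNA_BASES if freqs.at[b, off] >= include_threshold
        )
        out.append(IUPAC_FROM_SET.get(included, "N") if included else "N")
    return "".join(out)


def read_motifs_tsv(path: str | Path, protein_id: str = "protein") -> PprProtein:
    """Motif annotation TSV: columns index, mclass, aa2, aa5, aaLast."""
    df = pd.read_csv(path, sep="\t")
    motifs = [
        PprMotif(
            index=int(r["index"]),
            mclass=str(r["mclass"]),
            aa5=str(r["aa5"]),
            aaLast=str(r["aaLast"]),
            aa2=None if pd.isna(r.get("aa2")) or r.get("aa2") == "-" else str(r["aa2"]),
        )
        for _, r in df.sort_values("index").iterrows()
    ]
    return PprProtein(id=protein_id, motifs=motifs)


def read_cis_fasta(path: str | Path) -> list[CisElement]:
    """Cis-elements from FASTA; header tag ``edit_index=<n>`` (default 20)."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        edit_index = 20
        for token in rec.description.split():
            if token.startswith("edit_index="):
                edit_index = int(token.split("=", 1)[1])
        out.append(
            CisElement(site_name=rec.id, sequence=str(rec.seq), edit_index=edit_index)
        )
    return out
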