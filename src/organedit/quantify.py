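"""Splice-ratio, RPKM and relative-expression quantification.

Splicing of an intron-containing transcript is measured by counting reads
that span either the exon1-exon2 junction of the spliced mRNA or one of the
two exon-intron borders of the unspliced precursor, each against an
explicit junction reference sequence. Counts are normalised to the total
number of mapped organellar reads, and the splice ratio is
normalised-spliced / normalised-unspliced (72% spliced corresponds to a
ratio of roughly 3:1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, DataError
from .genome import OrganelleGenome
from .mapping import AlignParams, Alignment, GenomeIndex, align_read

DEFAULT_MIN_OVERHANG = 10
DEFAULT_JUNCTION_MIN_IDENTITY = 0.85


@dataclass
class JunctionReference:
    """Spliced and unspliced junction sequences for one intron.

    Each sequence records the 0-based index of the first base after its
    junction point (= length of the upstream segment).
    """

    gene: str
    spliced_seq: str
    spliced_junction: int
    unspliced5_seq: str  # exon1-intron border
    unspliced5_junction: int
    unspliced3_seq: str  # intron-exon2 border
    unspliced3_junction: int
    min_overhang: int = DEFAULT_MIN_OVERHANG

    def __post_init__(self) -> None:
        if self.min_overhang < 1:
            raise ConfigurationError("min_overhang must be >= 1")
        for seq, jp, label in (
            (self.spliced_seq, self.spliced_junction, "spliced"),
            (self.unspliced5_seq, self.unspliced5_junction, "unspliced5"),
            (self.unspliced3_seq, self.unspliced3_junction, "unspliced3"),
        ):
            if not self.min_overhang <= jp <= len(seq) - self.min_overhang:
                raise ConfigurationError(
                    f"{label}: junction point not interior by >= min_overhang"
                )


@dataclass
class SpliceCounts:
    spliced: int
    unspliced: int
    total_mapped_organellar: int

    @property
    def norm_spliced(self) -> float:
        return self.spliced / self.total_mapped_organellar

    @property
    def norm_unspliced(self) -> float:
        return self.unspliced / self.total_mapped_organellar

    @property
    def ratio(self) -> float:
        """Spliced:unspliced ratio; NaN (flagged undefined) when unspliced = 0."""
        if self.unspliced == 0:
            return math.nan
        return self.norm_spliced / self.norm_unspliced

    @property
    def fraction_spliced(self) -> float:
        total = self.spliced + self.unspliced
        if total == 0:
            return math.nan
        return self.spliced / total


def _spans_junction(aln: Alignment, junction: int, overhang: int) -> bool:
    start0 = aln.start - 1
    end0 = start0 + aln.aligned_length
    return start0 <= junction - overhang and end0 >= junction + overhang


def splice_ratio(
    reads: Iterable[str],
    junctions: JunctionReference,
    total_mapped: int,
    min_identity: float = DEFAULT_JUNCTION_MIN_IDENTITY,
    params: AlignParams | None = None,
) -> SpliceCounts:
    """Classify reads as spliced or unspliced junction evidence.

    A read counts as spliced (resp. unspliced) iff it aligns across the
    corresponding junction with at least ``min_overhang`` aligned bases on
    both sides. Each read counts at most once: a read spanning both
    unspliced borders is one unspliced observation, and a read matching a
    spliced and an unspliced reference is assigned to the higher-identity
    hit (exact ties are discarded as unassignable).
    """
    if total_mapped <= 0:
        raise ConfigurationError("total_mapped must be positive")
    refs = {
        "spliced": (junctions.spliced_seq, junctions.spliced_junction),
        "unspliced5": (junctions.unspliced5_seq, junctions.unspliced5_junction),
        "unspliced3": (junctions.unspliced3_seq, junctions.unspliced3_junction),
    }
    indexes = {
        name: GenomeIndex(
            OrganelleGenome(id=name, sequence=seq), params or AlignParams()
        )
        for name, (seq, _) in refs.items()
    }
    spliced = unspliced = 0
    for read in reads:
        hits: dict[str, float] = {}
        for name, idx in indexes.items():
            aln = align_read(read, idx)
            if aln is None or aln.identity < min_identity:
                continue
            if _spans_junction(aln, refs[name][1], junctions.min_overhang):
                hits[name] = aln.identity
        if not hits:
            continue
        s_id = hits.get("spliced", -1.0)
        u_id = max(
            (v for k, v in hits.items() if k != "spliced"), default=-1.0
        )
        if s_id > u_id:
            spliced += 1
        elif u_id > s_id:
            unspliced += 1
        # exact tie: unassignable, discarded
    return SpliceCounts(
        spliced=spliced, unspliced=unspliced, total_mapped_organellar=total_mapped
    )


def simulate_junction_reads(
    junctions: JunctionReference,
    n_reads: int,
    spliced_fraction: float,
    read_length: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[str]:
    """Simulate reads that each span one junction of an intron-containing gene.

    Every read comes from an independent transcript copy that is spliced
    with probability ``spliced_fraction``; unspliced copies contribute a
    read over one of their two exon-intron borders (chosen uniformly), so
    the spliced fraction among junction reads is a plain binomial sample of
    the transcript-level fraction. Read placement is uniform among
    positions spanning the junction with at least ``min_overhang`` bases on
    both sides.
    """
    import numpy as np

    if not 0 <= spliced_fraction <= 1:
        raise ConfigurationError("spliced_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    oh = junctions.min_overhang
    refs = {
        "spliced": (junctions.spliced_seq, junctions.spliced_junction),
        "unspliced5": (junctions.unspliced5_seq, junctions.unspliced5_junction),
        "unspliced3": (junctions.unspliced3_seq, junctions.unspliced3_junction),
    }
    reads: list[str] = []
    for _ in range(n_reads):
        if rng.random() < spliced_fraction:
            seq, jp = refs["spliced"]
        else:
            seq, jp = refs["unspliced5" if rng.random() < 0.5 else "unspliced3"]
        lo = max(0, jp + oh - read_length)
        hi = min(len(seq) - read_length, jp - oh)
        if hi < lo:
            raise ConfigurationError("read_length too short to span the junction")
        start = int(rng.integers(lo, hi + 1))
        read = list(seq[start : start + read_length])
        if error_rate > 0:
            for i in np.nonzero(rng.random(read_length) < error_rate)[0]:
                read[i] = rng.choice([b for b in "ACGT" if b != read[i]])
        reads.append("".join(read))
    return reads


def rpkm(mapped_reads: int, feature_length: int, library_total: int) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if feature_length <= 0 or library_total <= 0:
        raise ConfigurationError("feature_length and library_total must be positive")
    return 1e9 * mapped_reads / (feature_length * library_total)


@dataclass
class CtMeasurement:
    sample: str
    gene: str
    replicates: Sequence[float]

    def __post_init__(self) -> None:
        if len(self.replicates) < 1:
            raise DataError(f"{self.sample}/{self.gene}: needs >= 1 Ct replicate")

    @property
    def mean_ct(self) -> float:
        return sum(self.replicates) / len(self.replicates)


def relative_expression(
    target: Iterable[CtMeasurement],
    reference: Iterable[CtMeasurement],
    calibrator_sample: str | None = None,
) -> pd.DataFrame:
    """Delta-delta-Ct fold changes per sample.

    dCt = mean Ct(target) - mean Ct(reference gene); ddCt = dCt(sample) -
    dCt(calibrator); fold = 2^(-ddCt). With no calibrator given, the sample
    with the highest dCt (lowest expression) is used, so the minimum fold
    change is exactly 1.
    """
    t = {m.sample: m for m in target}
    r = {m.sample: m for m in reference}
    missing = set(t) ^ set(r)
    if missing:
        raise DataError(f"samples missing one gene: {sorted(missing)}")
    dct = {s: t[s].mean_ct - r[s].mean_ct for s in t}
    if calibrator_sample is None:
        calibrator_sample = max(dct, key=dct.get)
    elif calibrator_sample not in dct:
        raise DataError(f"unknown calibrator sample {calibrator_sample!r}")
    rows = []
    for s, d in dct.items():
        ddct = d - dct[calibrator_sample]
        rows.append(
            {"sample": s, "dCt": d, "ddCt": ddct, "fold_change": 2.0 ** (-ddct)}
        )
    return pd.DataFrame(rows).set_index("sample")


def read_ct_tsv(path) -> tuple[dict[str, list[CtMeasurement]], None]:
    """Ct table TSV (sample, gene, ct; one row per technical replicate)."""
    df = pd.read_csv(path, sep="\t")
    grouped: dict[str, list[CtMeasurement]] = {}
    for (sample, gene), grp in df.groupby(["sample", "gene"]):
        grouped.setdefault(gene, []).append(
            CtMeasurement(sample=sample, gene=gene, replicates=list(grp["ct"]))
        )
    return grouped, None
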