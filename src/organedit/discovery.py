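"""Candidate editing-site calling, filtering, and off-target tabulation.

The discovery filters mirror a stringent organellar editing screen:

* a SNP is a position where the most frequent non-reference base reaches a
  rate of at least 5% of the strand's coverage (with a configurable
  coverage floor);
* only C-to-T calls on plus-strand transcripts and G-to-A calls on
  minus-strand transcripts survive (both are C->U on the transcript);
* positions at known editing sites or inside tRNA/rRNA features are
  excluded (those RNAs are hypermodified by unrelated enzymes);
* a site is reported as an off-target iff it is edited to at least the
  threshold in one or more factor-expressing libraries while the wild type
  shows (essentially) none.

Editing efficiency is T/(T+C) on the transcript strand (equivalently
A/(A+G) in plus-strand projection of a minus-strand transcript), reported
in percent. The SNP *rate* uses the full strand coverage as denominator;
both numbers are reported because either reading of a "5% rate" is
defensible, and applying the cutoff to both is the stricter choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from Bio.Seq import Seq

from .errors import ConfigurationError, DataError
from .genome import GenomeFeature, KnownEditingSite, OrganelleGenome
from .mapping import BASES, Pileup

DEFAULT_MIN_RATE = 0.05
DEFAULT_MIN_COVERAGE = 20
DEFAULT_THRESHOLD_PCT = 5.0
DEFAULT_WT_CUTOFF_PCT = 1.0

LOCATION_PRIORITY = ("CDS", "intron", "UTR5", "UTR3", "tRNA", "rRNA")


@dataclass
class SnpRecord:
    genome_id: str
    position: int
    strand: str  # transcript strand the call was made on
    ref_base: str  # reference plus-strand base
    alt_base: str
    alt_rate: float  # alt count / total strand coverage
    efficiency: float  # alt / (alt + ref), the editing efficiency
    coverage: int
    snp_class: str  # C_to_T | G_to_A | other
    location_class: str | None = None


def editing_efficiency(t_count: int, c_count: int) -> float:
    """Editing efficiency in percent: 100 * T/(T+C).

    On a minus-strand transcript the same quantity is 100 * A/(A+G) in
    plus-strand projection. Fully edited sites reach 100.
    """
    total = t_count + c_count
    if total <= 0:
        raise ConfigurationError("editing_efficiency undefined for zero counts")
    return 100.0 * t_count / total


def _classify(strand: str, ref: str, alt: str) -> str:
    if strand == "+" and ref == "C" and alt == "T":
        return "C_to_T"
    if strand == "-" and ref == "G" and alt == "A":
        return "G_to_A"
    return "other"


def call_snps(
    pileup: Pileup,
    min_rate: float = DEFAULT_MIN_RATE,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> list[SnpRecord]:
    """Call per-strand SNPs from a pileup.

    One record per (position, transcript strand) where the most frequent
    non-reference base reaches ``min_rate`` of the strand coverage and the
    strand coverage reaches ``min_coverage``. The rate test is inclusive
    (>=).
    """
    if not 0 < min_rate <= 1:
        raise ConfigurationError("min_rate must lie in (0, 1]")
    genome = pileup.genome
    records: list[SnpRecord] = []
    totals = pileup.counts.sum(axis=1)  # (L, 2)
    for si, strand in enumerate("+-"):
        positions = np.nonzero(totals[:, si] >= min_coverage)[0]
        for p in positions:
            cov = int(totals[p, si])
            ref = genome.sequence[p]
            counts = pileup.counts[p, :, si]
            ref_idx = BASES.find(ref)
            order = np.argsort(counts)[::-1]
            alt_idx = next((int(b) for b in order if b != ref_idx), None)
            if alt_idx is None:
                continue
            alt_count = int(counts[alt_idx])
            rate = alt_count / cov
            if rate < min_rate:
                continue
            ref_count = int(counts[ref_idx]) if ref_idx >= 0 else 0
            denom = alt_count + ref_count
            records.append(
                SnpRecord(
                    genome_id=genome.id,
                    position=int(p) + 1,
                    strand=strand,
                    ref_base=ref,
                    alt_base=BASES[alt_idx],
                    alt_rate=rate,
                    efficiency=100.0 * alt_count / denom if denom else 0.0,
                    coverage=cov,
                    snp_class=_classify(strand, ref, BASES[alt_idx]),
                )
            )
    return records


def locate(
    position: int, strand: str, features: Iterable[GenomeFeature]
) -> str:
    """Location class of a stranded site relative to annotated features.

    A same-strand feature assigns its own class (CDS > intron > UTR);
    a site overlapping only opposite-strand features is antisense —
    combined with the intergenic label when the overlapped feature is an
    annotated intergenic interval; no overlap at all is intergenic.
    """
    same = [f for f in features if f.contains(position) and f.strand == strand]
    for cls in LOCATION_PRIORITY:
        if any(f.ftype == cls for f in same):
            return cls
    opposite = [f for f in features if f.contains(position) and f.strand != strand]
    genic = [f for f in opposite if f.ftype not in ("intergenic", "IR")]
    if genic:
        return "antisense"
    if any(f.ftype == "intergenic" for f in opposite):
        return "intergenic_antisense"
    return "intergenic"


def filter_candidates(
    snps: Iterable[SnpRecord],
    known_sites: Iterable[KnownEditingSite],
    features: Iterable[GenomeFeature],
) -> list[SnpRecord]:
    """Keep only C->U-type calls away from known sites and tRNA/rRNA."""
    known = {(s.genome_id, s.position) for s in known_sites}
    features = list(features)
    out = []
    for s in snps:
        if s.snp_class not in ("C_to_T", "G_to_A"):
            continue
        if (s.genome_id, s.position) in known:
            continue
        if any(
            f.contains(s.position) and f.ftype in ("tRNA", "rRNA") for f in features
        ):
            continue
        s.location_class = locate(s.position, s.strand, features)
        out.append(s)
    return out


@dataclass
class OffTargetRecord:
    site_name: str
    genome: str
    position: int
    strand: str
    per_library_editing: dict[str, float]  # library -> percent
    location_class: str | None = None
    impact: str = "-"

    @property
    def max_editing(self) -> float:
        return max(self.per_library_editing.values(), default=0.0)


def discover_offtargets(
    mutant_records: Mapping[str, Iterable[SnpRecord]],
    wt_records: Iterable[SnpRecord],
    threshold: float = DEFAULT_THRESHOLD_PCT,
    wt_cutoff: float = DEFAULT_WT_CUTOFF_PCT,
    site_names: Mapping[tuple[str, int], str] | None = None,
) -> list[OffTargetRecord]:
    """Off-target sites: edited >= threshold in >= 1 mutant library, absent in WT.

    ``wt_records`` should come from an unthresholded (or low-threshold) SNP
    pass over the wild-type library so that sub-threshold wild-type editing
    can still veto a site; a site passes only if the wild-type efficiency is
    below ``wt_cutoff`` percent. Per-library percentages are reported, 0
    when below detection.
    """
    genome_ids = set()
    candidates: dict[tuple[str, int, str], dict[str, float]] = {}
    for lib, records in mutant_records.items():
        for r in records:
            genome_ids.add(r.genome_id)
            key = (r.genome_id, r.position, r.strand)
            candidates.setdefault(key, {})[lib] = r.efficiency
    wt_eff = {
        (r.genome_id, r.position, r.strand): r.efficiency for r in wt_records
    }
    loc = {}
    for records in mutant_records.values():
        for r in records:
            if r.location_class is not None:
                loc[(r.genome_id, r.position, r.strand)] = r.location_class
    libraries = list(mutant_records)
    out: list[OffTargetRecord] = []
    for key in sorted(candidates):
        per_lib = {lib: candidates[key].get(lib, 0.0) for lib in libraries}
        if max(per_lib.values(), default=0.0) < threshold:
            continue
        if wt_eff.get(key, 0.0) >= wt_cutoff:
            continue
        gid, pos, strand = key
        name = (site_names or {}).get((gid, pos), f"{gid}:{pos}{strand}")
        out.append(
            OffTargetRecord(
                site_name=name,
                genome=gid,
                position=pos,
                strand=strand,
                per_library_editing=per_lib,
                location_class=loc.get(key),
            )
        )
    return out


def offtarget_matrix(records: Iterable[OffTargetRecord]) -> pd.DataFrame:
    """Site x library editing-percentage table from off-target records."""
    rows = {r.site_name: r.per_library_editing for r in records}
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)


def filter_matrix(
    table: pd.DataFrame,
    libraries: Iterable[str],
    wt_column: str | None = "WT",
    threshold: float = DEFAULT_THRESHOLD_PCT,
) -> pd.DataFrame:
    """Apply the off-target filter to an editing-percentage table.

    Retains rows edited to at least ``threshold`` percent in at least one of
    ``libraries`` and (if a wild-type column is given) showing zero editing
    there.
    """
    libraries = list(libraries)
    keep = table[libraries].max(axis=1) >= threshold
    if wt_column is not None:
        keep &= table[wt_column] == 0
    return table.loc[keep]


def per_library_counts(
    table: pd.DataFrame,
    libraries: Iterable[str],
    threshold: float = DEFAULT_THRESHOLD_PCT,
) -> dict[str, int]:
    return {lib: int((table[lib] >= threshold).sum()) for lib in libraries}


def classify_affinity(
    table: pd.DataFrame,
    moderate_libs: Iterable[str],
    over_libs: Iterable[str],
    threshold: float = DEFAULT_THRESHOLD_PCT,
) -> dict[str, str]:
    """high: edited >= threshold in a moderate-expression library; else low.

    High-affinity sites are recognised already at moderate factor
    expression; low-affinity sites appear only upon overexpression. Rows
    below threshold everywhere are omitted.
    """
    moderate_libs, over_libs = list(moderate_libs), list(over_libs)
    missing = [c for c in moderate_libs + over_libs if c not in table.columns]
    if missing:
        raise ConfigurationError(f"unknown libraries: {missing}")
    out: dict[str, str] = {}
    for site, row in table.iterrows():
        if row[moderate_libs].max() >= threshold:
            out[site] = "high"
        elif row[over_libs].max() >= threshold:
            out[site] = "low"
    return out


def annotate_impact(
    position: int,
    strand: str,
    genome: OrganelleGenome,
    features: Iterable[GenomeFeature] | None = None,
    require_cds: bool = False,
) -> str:
    """Codon impact of a C->U edit at a stranded position.

    For a site inside a same-strand CDS, returns "X->Y" for the amino-acid
    change (STOP for a stop codon) or "synonymous"; any non-CDS site yields
    "-". Introns annotated inside the CDS are spliced out before codon
    arithmetic.
    """
    features = list(features) if features is not None else list(genome.features)
    cds = [
        f
        for f in features
        if f.ftype == "CDS" and f.strand == strand and f.contains(position)
    ]
    if not cds:
        if require_cds:
            raise DataError(f"position {position}{strand} lies in no CDS")
        return "-"
    f = cds[0]
    introns = [
        i
        for i in features
        if i.ftype == "intron" and i.parent == f.name
    ]
    exonic = [
        p
        for p in range(f.start, f.end + 1)
        if not any(i.contains(p) for i in introns)
    ]
    if position not in exonic:
        return "-"  # intronic position within the gene span
    if strand == "+":
        cds_seq = "".join(genome.sequence[p - 1] for p in exonic)
        idx = exonic.index(position)
    else:
        rev = exonic[::-1]
        cds_seq = "".join(
            str(Seq(genome.sequence[p - 1]).complement()) for p in rev
        )
        idx = rev.index(position)
    if cds_seq[idx] != "C":
        raise DataError(
            f"position {position}{strand}: transcript base is {cds_seq[idx]}, not C"
        )
    codon_i = idx // 3
    codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
    if len(codon) < 3:
        return "-"
    edited = list(codon)
    edited[idx % 3] = "T"
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq("".join(edited)).translate())
    if aa_ref == aa_alt:
        return "synonymous"
    fmt = lambda aa: "STOP" if aa == "*" else aa
    return f"{fmt(aa_ref)}->{fmt(aa_alt)}"


def site_efficiency(
    pileup: Pileup, position: int, strand: str
) -> tuple[float, int]:
    """(efficiency percent, two-allele coverage) at a stranded site."""
    counts = pileup.strand_counts(position, strand)
    if strand == "+":
        t, c = counts["T"], counts["C"]
    else:
        t, c = counts["A"], counts["G"]
    if t + c == 0:
        return 0.0, 0
    return editing_efficiency(t, c), t + c
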