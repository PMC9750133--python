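"""End-to-end discovery pipeline: reference prep -> mapping -> discovery.

The programmatic entry point is :func:`run_discovery`, which takes
in-memory genomes and read libraries; :func:`run_pipeline` wraps it with
file I/O, resolved-configuration output and a run log for shell use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import discovery, mapping, reference
from .errors import ConfigurationError
from .genome import (
    KnownEditingSite,
    OrganelleGenome,
    read_fasta,
    read_gff3,
    read_sites_bed,
    write_fasta,
    write_gff3,
)
from .simulate import ReadPair, read_paired_fastq

logger = logging.getLogger("organedit")

# Wild-type SNPs are called at a permissive rate so that sub-threshold
# wild-type editing can veto a candidate.
WT_SCAN_MIN_RATE = 0.001


@dataclass
class DiscoveryResult:
    offtargets: list[discovery.OffTargetRecord]
    pileups: dict[tuple[str, str], mapping.Pileup]  # (library, genome) -> pileup
    snps: dict[str, list[discovery.SnpRecord]]  # mutant library -> filtered calls
    wt_snps: list[discovery.SnpRecord]


def run_discovery(
    genomes: Sequence[OrganelleGenome],
    mutant_libraries: Mapping[str, Sequence[ReadPair]],
    wt_pairs: Sequence[ReadPair],
    known_sites: Sequence[KnownEditingSite] = (),
    min_rate: float = discovery.DEFAULT_MIN_RATE,
    min_coverage: int = discovery.DEFAULT_MIN_COVERAGE,
    threshold: float = discovery.DEFAULT_THRESHOLD_PCT,
    wt_cutoff: float = discovery.DEFAULT_WT_CUTOFF_PCT,
    collapse_duplicates: bool = False,
    site_names: Mapping[tuple[str, int], str] | None = None,
    align_params: mapping.AlignParams | None = None,
) -> DiscoveryResult:
    """Select organellar pairs, pile up, call, filter and subtract wild type.

    Efficiencies are quantified on uncollapsed reads by default; duplicate
    collapsing (discovery mode) is available but distorts fractions at deep
    uniform coverage.
    """
    ids = [g.id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("duplicate genome ids")
    indexes = [mapping.GenomeIndex(g, align_params) for g in genomes]
    by_id = {g.id: g for g in genomes}

    pileups: dict[tuple[str, str], mapping.Pileup] = {}
    snps: dict[str, list[discovery.SnpRecord]] = {}

    def _library_pileups(name: str, pairs: Sequence[ReadPair]) -> dict[str, mapping.Pileup]:
        selected = mapping.select_organellar_pairs(pairs, indexes)
        out = {}
        for gid, genome in by_id.items():
            sub = [s for s in selected if s.genome_id == gid]
            out[gid] = mapping.build_pileup(sub, genome, collapse_duplicates)
        logger.info("library %s: %d/%d pairs selected", name, len(selected), len(pairs))
        return out

    for lib, pairs in mutant_libraries.items():
        lib_pileups = _library_pileups(lib, pairs)
        records: list[discovery.SnpRecord] = []
        for gid, p in lib_pileups.items():
            pileups[(lib, gid)] = p
            raw = discovery.call_snps(p, min_rate=min_rate, min_coverage=min_coverage)
            records.extend(
                discovery.filter_candidates(raw, known_sites, by_id[gid].features)
            )
        snps[lib] = records

    wt_records: list[discovery.SnpRecord] = []
    wt_pileups = _library_pileups("WT", wt_pairs)
    for gid, p in wt_pileups.items():
        pileups[("WT", gid)] = p
        wt_records.extend(
            discovery.call_snps(p, min_rate=WT_SCAN_MIN_RATE, min_coverage=min_coverage)
        )

    offtargets = discovery.discover_offtargets(
        snps, wt_records, threshold=threshold, wt_cutoff=wt_cutoff,
        site_names=site_names,
    )
    return DiscoveryResult(
        offtargets=offtargets, pileups=pileups, snps=snps, wt_snps=wt_records
    )


@dataclass
class PipelineConfig:
    """File-based configuration for a full discovery run."""

    reference_fasta: str
    output_dir: str
    libraries: dict[str, list[str]]  # name -> [mate1.fastq, mate2.fastq]
    wt_library: list[str] = field(default_factory=list)  # [mate1, mate2]
    reference_gff3: str | None = None
    known_sites_bed: str | None = None
    ir_interval: list[int] | None = None  # [start, end], 1-based inclusive
    ir_flank: int = reference.DEFAULT_IR_FLANK
    circular: bool = False
    min_rate: float = discovery.DEFAULT_MIN_RATE
    min_coverage: int = discovery.DEFAULT_MIN_COVERAGE
    threshold: float = discovery.DEFAULT_THRESHOLD_PCT
    wt_cutoff: float = discovery.DEFAULT_WT_CUTOFF_PCT
    collapse_duplicates: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute reference prep, mapping, discovery; write every intermediate.

    Returns the output directory. Outputs: prepared reference FASTA/GFF3,
    per-library pileup TSVs, filtered SNP TSV, off-target table TSV, the
    resolved configuration, and a run log. Identical config and seed yield
    byte-identical outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "reference_prep"
    try:
        genome = read_fasta(config.reference_fasta, circular=config.circular)
        if config.reference_gff3:
            genome.features = read_gff3(config.reference_gff3)
        sites = (
            read_sites_bed(config.known_sites_bed) if config.known_sites_bed else []
        )
        if config.ir_interval:
            genome = reference.collapse_inverted_repeat(
                genome, tuple(config.ir_interval), flank=config.ir_flank
            )
        genome = reference.mask_known_sites(genome, sites)
        write_fasta(genome, out / "reference.prepared.fasta")
        write_gff3(genome, out / "reference.prepared.gff3")

        stage = "read_mapping"
        libraries = {
            name: read_paired_fastq(m1, m2)
            for name, (m1, m2) in config.libraries.items()
        }
        wt_pairs = (
            read_paired_fastq(*config.wt_library) if config.wt_library else []
        )

        stage = "editing_discovery"
        result = run_discovery(
            [genome],
            libraries,
            wt_pairs,
            known_sites=sites,
            min_rate=config.min_rate,
            min_coverage=config.min_coverage,
            threshold=config.threshold,
            wt_cutoff=config.wt_cutoff,
            collapse_duplicates=config.collapse_duplicates,
        )
        for (lib, gid), pileup in result.pileups.items():
            pileup.to_tsv(out / f"pileup.{lib}.{gid}.tsv")
        _write_snps(result, out / "snps.tsv")
        _write_offtargets(result, list(libraries), out / "offtargets.tsv")

        with open(out / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(asdict(config), fh, sort_keys=True)
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


def _write_snps(result: DiscoveryResult, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "library\tgenome\tposition\tstrand\tref\talt\trate\tefficiency\t"
            "coverage\tclass\tlocation\n"
        )
        for lib, records in result.snps.items():
            for r in records:
                fh.write(
                    f"{lib}\t{r.genome_id}\t{r.position}\t{r.strand}\t{r.ref_base}\t"
                    f"{r.alt_base}\t{r.alt_rate:.4f}\t{r.efficiency:.1f}\t"
                    f"{r.coverage}\t{r.snp_class}\t{r.location_class}\n"
                )


def _write_offtargets(
    result: DiscoveryResult, libraries: list[str], path: Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "site\tgenome\tposition\tstrand\t"
            + "\t".join(libraries)
            + "\tlocation\timpact\n"
        )
        for r in result.offtargets:
            values = "\t".join(
                f"{r.per_library_editing.get(lib, 0.0):.1f}" for lib in libraries
            )
            fh.write(
                f"{r.site_name}\t{r.genome}\t{r.position}\t{r.strand}\t{values}\t"
                f"{r.location_class}\t{r.impact}\n"
            )
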