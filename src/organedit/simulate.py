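"""Synthetic organellar genomes and strand-specific paired-end reads.

The simulator emulates the library design used for organellar editing
discovery: strand-specific paired-end reads (2 x 150 nt, ~250 bp inserts)
drawn from annotated transcription units of a small plastid- or
mitochondrion-like genome. Each simulated transcript copy is independently

* edited: every configured site is converted C->U (written as T on the
  transcript sense) with its per-site Bernoulli fraction;
* spliced: each intron is removed with probability ``spliced_fraction``;
* optionally antisense: the copy is transcribed from the opposite strand
  (antisense copies are neither edited nor spliced);

and per-base substitution errors are applied after editing. Mate 1 carries
the transcript sense; mate 2 is its reverse-complemented opposite end.
Coverage is uniform along the transcript and base qualities are constant
high quality — neither coverage bias nor quality modelling affects the
threshold-based discovery filters this package implements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .errors import ConfigurationError
from .genome import GenomeFeature, OrganelleGenome, revcomp

DEFAULT_READ_LENGTH = 150
DEFAULT_INSERT_MEAN = 250
HIGH_QUALITY_CHAR = "I"  # Phred 40

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


@dataclass
class SimulationSpec:
    """Parameters of one simulated library."""

    genome_id: str
    n_pairs: int
    read_length: int = DEFAULT_READ_LENGTH
    insert_mean: int = DEFAULT_INSERT_MEAN
    insert_sd: float = 25.0
    error_rate: float = 0.0
    editing_fractions: dict[int, float] = field(default_factory=dict)
    spliced_fraction: float = 1.0
    antisense_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [self.error_rate, self.spliced_fraction, self.antisense_fraction]
        probs += list(self.editing_fractions.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("all probabilities must lie in [0, 1]")
        if self.n_pairs < 0:
            raise ConfigurationError("n_pairs must be >= 0")
        if self.read_length > self.insert_mean:
            raise ConfigurationError("read_length must not exceed insert_mean")


@dataclass(frozen=True)
class ReadPair:
    id: str
    mate1_seq: str
    mate2_seq: str
    mate1_qual: str
    mate2_qual: str
    true_origin: tuple[str, str, int]  # (feature name, transcript strand, fragment start)


@dataclass
class ToyGenomeConfig:
    """Layout of a toy genome: background sequence plus stranded features.

    ``editing_sites`` lists (position, transcript_strand, name) triples; the
    generated sequence is forced to carry a C on the transcribed strand at
    each of them (a G on the plus strand for minus-strand sites).
    """

    genome_id: str
    length: int
    features: list[GenomeFeature] = field(default_factory=list)
    editing_sites: list[tuple[int, str, str]] = field(default_factory=list)
    circular: bool = False
    seed: int = 0


def _check_no_overlap(features: list[GenomeFeature]) -> None:
    """Same-strand transcription units must not overlap (introns nest)."""
    units = [f for f in features if f.parent is None]
    for strand in "+-":
        ivs = sorted(
            (f.start, f.end, f.name) for f in units if f.strand == strand
        )
        for (s1, e1, n1), (s2, e2, n2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ConfigurationError(
                    f"features {n1} and {n2} overlap on strand {strand}"
                )
    by_name = {f.name: f for f in features}
    for f in features:
        if f.parent is not None:
            parent = by_name.get(f.parent)
            if parent is None:
                raise ConfigurationError(f"feature {f.name}: unknown parent {f.parent}")
            if f.start < parent.start or f.end > parent.end:
                raise ConfigurationError(
                    f"intron {f.name} extends outside its parent {f.parent}"
                )


def build_toy_genome(config: ToyGenomeConfig) -> OrganelleGenome:
    """Deterministically generate an annotated toy genome from a layout."""
    _check_no_overlap(config.features)
    for f in config.features:
        if f.end > config.length:
            raise ConfigurationError(
                f"feature {f.name} exceeds requested length {config.length}"
            )
    rng = np.random.default_rng(config.seed)
    seq = rng.choice(_BASES, size=config.length)
    for pos, strand, _name in config.editing_sites:
        if not 1 <= pos <= config.length:
            raise ConfigurationError(f"editing site position {pos} out of range")
        seq[pos - 1] = "C" if strand == "+" else "G"
        # avoid an accidental adjacent editable context becoming ambiguous
    return OrganelleGenome(
        id=config.genome_id,
        sequence="".join(seq),
        circular=config.circular,
        features=list(config.features),
    )


def _transcription_units(
    genome: OrganelleGenome,
) -> list[tuple[GenomeFeature, list[GenomeFeature]]]:
    units = [
        f
        for f in genome.features
        if f.parent is None and f.ftype not in ("intergenic", "IR")
    ]
    introns = [f for f in genome.features if f.ftype == "intron"]
    return [
        (u, [i for i in introns if i.parent == u.name]) for u in units
    ]


def simulate_reads(
    genome: OrganelleGenome, spec: SimulationSpec
) -> Iterator[ReadPair]:
    """Yield ``spec.n_pairs`` read pairs from the genome's transcription units.

    Transcription units are the top-level (parentless, non-intergenic)
    features, sampled proportionally to their length. Every read pair comes
    from an independent transcript copy, so per-site T/(T+C) fractions at
    deep coverage are plain binomial samples of the configured editing
    fractions. One seeded generator per call makes runs reproducible.
    """
    units = _transcription_units(genome)
    if not units and spec.n_pairs > 0:
        raise ConfigurationError(f"genome {genome.id} has no transcription units")
    for pos, frac in spec.editing_fractions.items():
        owners = [u for u, _ in units if u.contains(pos)]
        if not owners:
            raise ConfigurationError(
                f"editing position {pos} lies in no transcription unit"
            )
        strand = owners[0].strand
        base = genome.base(pos)
        expected = "C" if strand == "+" else "G"
        if base != expected:
            raise ConfigurationError(
                f"editing position {pos} is {base}, not a C on the transcribed "
                f"strand ({strand})"
            )
    rng = np.random.default_rng(spec.seed)
    weights = np.array([u.length for u, _ in units], dtype=float)
    if weights.sum() > 0:
        weights /= weights.sum()

    for i in range(spec.n_pairs):
        idx = int(rng.choice(len(units), p=weights)) if len(units) > 1 else 0
        unit, introns = units[idx]
        antisense = rng.random() < spec.antisense_fraction

        # Pre-mRNA on the plus strand, with transcript-local bookkeeping of
        # the editable positions.
        pre = list(genome.sequence[unit.start - 1 : unit.end])
        site_local = {
            pos - unit.start: frac
            for pos, frac in spec.editing_fractions.items()
            if unit.contains(pos)
        }
        if not antisense:
            for local, frac in site_local.items():
                if rng.random() < frac:
                    # C->U on the transcript sense; plus-strand projection of a
                    # minus-strand edit is G->A.
                    pre[local] = "T" if unit.strand == "+" else "A"
            keep = np.ones(len(pre), dtype=bool)
            for intr in introns:
                if rng.random() < spec.spliced_fraction:
                    keep[intr.start - unit.start : intr.end - unit.start + 1] = False
            plus_seq = "".join(c for c, k in zip(pre, keep) if k)
        else:
            plus_seq = "".join(pre)

        sense_strand = unit.strand if not antisense else ("-" if unit.strand == "+" else "+")
        transcript = plus_seq if sense_strand == "+" else revcomp(plus_seq)
        tlen = len(transcript)
        insert = int(round(rng.normal(spec.insert_mean, spec.insert_sd)))
        insert = max(spec.read_length, min(insert, tlen))
        start = int(rng.integers(0, tlen - insert + 1))
        frag = transcript[start : start + insert]
        m1 = frag[: spec.read_length]
        m2 = revcomp(frag[-spec.read_length :])
        if spec.error_rate > 0:
            m1 = _apply_errors(m1, spec.error_rate, rng)
            m2 = _apply_errors(m2, spec.error_rate, rng)
        qual = HIGH_QUALITY_CHAR * spec.read_length
        yield ReadPair(
            id=f"{spec.genome_id}_{i}",
            mate1_seq=m1,
            mate2_seq=m2,
            mate1_qual=qual[: len(m1)],
            mate2_qual=qual[: len(m2)],
            true_origin=(unit.name, sense_strand, start),
        )


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for h in hits:
        choices = [b for b in "ACGT" if b != arr[h]]
        arr[h] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def write_paired_fastq(
    pairs: list[ReadPair], path1: str | Path, path2: str | Path
) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.mate1_seq}\n+\n{p.mate1_qual}\n")
            f2.write(f"@{p.id}/2\n{p.mate2_seq}\n+\n{p.mate2_qual}\n")


def read_paired_fastq(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    from Bio import SeqIO

    out = []
    for r1, r2 in zip(
        SeqIO.parse(str(path1), "fastq"), SeqIO.parse(str(path2), "fastq")
    ):
        out.append(
            ReadPair(
                id=r1.id.removesuffix("/1"),
                mate1_seq=str(r1.seq),
                mate2_seq=str(r2.seq),
                mate1_qual="".join(
                    chr(q + 33) for q in r1.letter_annotations["phred_quality"]
                ),
                mate2_qual="".join(
                    chr(q + 33) for q in r2.letter_annotations["phred_quality"]
                ),
                true_origin=("", "+", -1),
            )
        )
    return out
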