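"""Lightweight read alignment and strand-aware pileups.

The aligner is a k-mer seed (default k = 15, indexed at every reference
position) plus ungapped extension. C-to-U editing produces a pure
substitution signal, so indels are deliberately out of scope; the ungapped
model keeps the aligner exactly checkable against an exhaustive
sliding-window mismatch oracle. Reference bases masked to the ambiguity
codes Y (C/T) and R (A/G) match either constituent base without penalty, so
edited and unedited reads score identically at masked known sites.

Strand bookkeeping: alignments record the strand of the *query* on the
reference; the strand-specific library convention (mate 1 carries the
transcript sense) is applied when pairs are selected, and pileup counts are
keyed by the inferred transcript strand of the fragment, with bases always
projected onto the reference plus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError
from .genome import OrganelleGenome, revcomp
from .simulate import ReadPair

# bitmask encoding: a reference code matches a read base iff the bits overlap
_MASKS = {"A": 1, "C": 2, "G": 4, "T": 8, "U": 8, "Y": 10, "R": 5, "N": 15}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
BASES = "ACGT"

DEFAULT_MIN_PAIR_LEN = 100
DEFAULT_MIN_IDENTITY = 0.85
DEFAULT_MIN_READ_COV = 0.5


@dataclass
class AlignParams:
    k: int = 15
    query_step: int = 5  # spacing of seed k-mers sampled from the query


@dataclass
class Alignment:
    read_id: str
    genome_id: str
    start: int  # 1-based reference position of the leftmost aligned base
    strand: str  # strand of the query on the reference
    matches: int
    aligned_length: int
    read_length: int
    proj_seq: str  # query projected onto the reference plus strand
    clip_left: int  # bases of proj_seq clipped off the reference start
    n_best: int = 1  # number of loci sharing the best score
    fragment_strand: str | None = None  # transcript strand of the fragment

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_length if self.aligned_length else 0.0

    @property
    def aligned_fraction(self) -> float:
        return self.aligned_length / self.read_length if self.read_length else 0.0


class GenomeIndex:
    """Seed index + encoded reference for one genome.

    Circular genomes are indexed over their doubled sequence; reported
    positions are reduced modulo the genome length.
    """

    def __init__(self, genome: OrganelleGenome, params: AlignParams | None = None):
        self.genome = genome
        self.params = params or AlignParams()
        seq = genome.sequence * 2 if genome.circular else genome.sequence
        self.ref_len = genome.length
        self._seq = seq
        self._mask = np.fromiter(
            (_MASKS[b] for b in seq), dtype=np.uint8, count=len(seq)
        )
        k = self.params.k
        index: dict[str, list[int]] = {}
        limit = len(seq) - k + 1
        if genome.circular:
            limit = min(limit, genome.length)  # one seed per circular position
        for i in range(max(limit, 0)):
            kmer = seq[i : i + k]
            if any(c not in "ACGT" for c in kmer):
                continue  # masked/ambiguous seeds are skipped; extension still scores them
            index.setdefault(kmer, []).append(i)
        self._index = index

    def _encode(self, seq: str) -> np.ndarray:
        return np.fromiter(
            (_MASKS.get(b, 15) for b in seq), dtype=np.uint8, count=len(seq)
        )

    def _candidates(self, query: str) -> set[int]:
        k, step = self.params.k, self.params.query_step
        starts: set[int] = set()
        for q in range(0, max(len(query) - k, 0) + 1, step):
            for p in self._index.get(query[q : q + k], ()):
                starts.add(p - q)
        return starts

    def _score(self, query_mask: np.ndarray, start: int) -> tuple[int, int, int]:
        """(matches, aligned_length, clip_left) of an ungapped placement."""
        n = len(query_mask)
        lo = max(start, 0)
        hi = min(start + n, len(self._mask))
        if hi <= lo:
            return 0, 0, 0
        qlo = lo - start
        m = int(
            np.count_nonzero(
                self._mask[lo:hi] & query_mask[qlo : qlo + (hi - lo)]
            )
        )
        return m, hi - lo, qlo


def align_read(
    read: str,
    genome: OrganelleGenome | GenomeIndex,
    params: AlignParams | None = None,
    read_id: str = "read",
) -> Alignment | None:
    """Best ungapped alignment of a read over both strands, or ``None``.

    The highest match count wins; ties are broken by leftmost reference
    start, then plus strand. ``n_best`` records how many distinct loci share
    the best score so multi-mapping reads can be excluded downstream.
    """
    if not read:
        raise ConfigurationError("empty read")
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome, params)
    g = index.genome
    queries = ((read, "+"), (revcomp(read), "-"))
    hits: dict[tuple[int, str], tuple[int, int, int, str]] = {}
    for query, strand in queries:
        qmask = index._encode(query)
        for s in index._candidates(query):
            key_start = s % index.ref_len if g.circular else s
            key = (key_start, strand)
            if key in hits:
                continue
            m, alen, clip = index._score(qmask, s)
            if alen:
                hits[key] = (m, alen, clip, query)
    if not hits:
        return None
    best_m = max(v[0] for v in hits.values())
    best = [(k, v) for k, v in hits.items() if v[0] == best_m]
    best.sort(key=lambda kv: (kv[0][0], 0 if kv[0][1] == "+" else 1))
    (start, strand), (m, alen, clip, query) = best[0]
    return Alignment(
        read_id=read_id,
        genome_id=g.id,
        start=start + clip + 1,
        strand=strand,
        matches=m,
        aligned_length=alen,
        read_length=len(read),
        proj_seq=query,
        clip_left=clip,
        n_best=len(best),
    )


@dataclass
class SelectedPair:
    pair: ReadPair
    genome_id: str
    mate1_aln: Alignment | None
    mate2_aln: Alignment | None


def _passes(aln: Alignment | None, min_identity: float, min_read_cov: float) -> bool:
    return (
        aln is not None
        and aln.identity >= min_identity
        and aln.aligned_fraction > min_read_cov
    )


def select_organellar_pairs(
    pairs: Iterable[ReadPair],
    genomes: Sequence[OrganelleGenome | GenomeIndex],
    min_len: int = DEFAULT_MIN_PAIR_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_read_cov: float = DEFAULT_MIN_READ_COV,
    params: AlignParams | None = None,
    mate1_sense: bool = True,
) -> list[SelectedPair]:
    """Apply the organellar read-pair selection rule.

    A pair is kept iff both mates are strictly longer than ``min_len`` and at
    least one mate aligns to one of the references with identity >=
    ``min_identity`` over more than ``min_read_cov`` of its length. By the
    default library dialect mate 1 carries the transcript sense, so the
    fragment's transcript strand is mate 1's alignment strand (or the
    opposite of mate 2's); ``mate1_sense=False`` selects the opposite
    dialect.
    """
    if not 0 < min_identity <= 1 or not 0 <= min_read_cov < 1:
        raise ConfigurationError("selection thresholds out of range")
    indexes = [
        g if isinstance(g, GenomeIndex) else GenomeIndex(g, params) for g in genomes
    ]
    selected: list[SelectedPair] = []
    for pair in pairs:
        if len(pair.mate1_seq) <= min_len or len(pair.mate2_seq) <= min_len:
            continue
        best: SelectedPair | None = None
        best_matches = -1
        for idx in indexes:
            a1 = align_read(pair.mate1_seq, idx, read_id=pair.id + "/1")
            a2 = align_read(pair.mate2_seq, idx, read_id=pair.id + "/2")
            if not (_passes(a1, min_identity, min_read_cov) or _passes(a2, min_identity, min_read_cov)):
                continue
            score = max(a.matches for a in (a1, a2) if a is not None)
            if score > best_matches:
                best_matches = score
                best = SelectedPair(pair, idx.genome.id, a1, a2)
        if best is None:
            continue
        a1, a2 = best.mate1_aln, best.mate2_aln
        flip = {"+": "-", "-": "+"}
        if a1 is not None:
            a1.fragment_strand = a1.strand if mate1_sense else flip[a1.strand]
        if a2 is not None:
            a2.fragment_strand = flip[a2.strand] if mate1_sense else a2.strand
        # only mates that individually satisfy the alignment thresholds
        # contribute to pileups
        if not _passes(a1, min_identity, min_read_cov):
            best.mate1_aln = None
        if not _passes(a2, min_identity, min_read_cov):
            best.mate2_aln = None
        selected.append(best)
    return selected


@dataclass
class PileupColumn:
    genome_id: str
    position: int  # 1-based
    counts: dict[tuple[str, str], int]  # (base, transcript strand) -> count

    @property
    def coverage(self) -> int:
        return sum(self.counts.values())


class Pileup:
    """Per-position, per-transcript-strand base counts for one genome."""

    def __init__(self, genome: OrganelleGenome):
        self.genome = genome
        # axes: position (0-based), base (ACGT), transcript strand (+,-)
        self.counts = np.zeros((genome.length, 4, 2), dtype=np.int64)

    def add_alignment(self, aln: Alignment, read_seq_for_dedup: str | None = None) -> None:
        strand_idx = 0 if (aln.fragment_strand or aln.strand) == "+" else 1
        start0 = aln.start - 1
        L = self.genome.length
        for i, base in enumerate(
            aln.proj_seq[aln.clip_left : aln.clip_left + aln.aligned_length]
        ):
            bi = _BASE_INDEX.get(base)
            if bi is None:
                continue
            pos = (start0 + i) % L if self.genome.circular else start0 + i
            self.counts[pos, bi, strand_idx] += 1

    def column(self, position: int) -> PileupColumn:
        c = self.counts[position - 1]
        return PileupColumn(
            genome_id=self.genome.id,
            position=position,
            counts={
                (BASES[b], s): int(c[b, si])
                for b in range(4)
                for si, s in enumerate("+-")
                if c[b, si]
            },
        )

    def strand_counts(self, position: int, strand: str) -> dict[str, int]:
        si = 0 if strand == "+" else 1
        c = self.counts[position - 1, :, si]
        return {BASES[b]: int(c[b]) for b in range(4)}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("genome\tpos\tA+\tC+\tG+\tT+\tA-\tC-\tG-\tT-\n")
            covered = np.nonzero(self.counts.sum(axis=(1, 2)))[0]
            for p in covered:
                plus = self.counts[p, :, 0]
                minus = self.counts[p, :, 1]
                fh.write(
                    f"{self.genome.id}\t{p + 1}\t"
                    + "\t".join(str(int(x)) for x in plus)
                    + "\t"
                    + "\t".join(str(int(x)) for x in minus)
                    + "\n"
                )


def build_pileup(
    selected: Iterable[SelectedPair | Alignment],
    genome: OrganelleGenome,
    collapse_duplicates: bool = False,
) -> Pileup:
    """Accumulate per-position base counts from selected pairs or alignments.

    In discovery mode (``collapse_duplicates=True``) identical read sequences
    are counted once, mimicking duplicate collapsing of discovery libraries;
    quantification uses every read. Reads aligning equally well to more than
    one locus are discarded.
    """
    pileup = Pileup(genome)
    seen: set[str] = set()

    def _add(aln: Alignment | None, raw_seq: str) -> None:
        if aln is None or aln.genome_id != genome.id or aln.n_best > 1:
            return
        if collapse_duplicates:
            if raw_seq in seen:
                return
            seen.add(raw_seq)
        pileup.add_alignment(aln)

    for item in selected:
        if isinstance(item, Alignment):
            _add(item, item.proj_seq)
        else:
            _add(item.mate1_aln, item.pair.mate1_seq)
            _add(item.mate2_aln, item.pair.mate2_seq)
    return pileup


def write_alignments_tsv(
    selected: Iterable[SelectedPair], path: str | Path
) -> None:
    """Minimal SAM-like TSV of mate alignments."""
    with open(path, "w") as fh:
        fh.write(
            "read_id\tgenome\tstart\tstrand\tfragment_strand\tidentity\taligned_fraction\tn_best\n"
        )
        for sp in selected:
            for aln in (sp.mate1_aln, sp.mate2_aln):
                if aln is None:
                    continue
                fh.write(
                    f"{aln.read_id}\t{aln.genome_id}\t{aln.start}\t{aln.strand}\t"
                    f"{aln.fragment_strand}\t{aln.identity:.4f}\t"
                    f"{aln.aligned_fraction:.4f}\t{aln.n_best}\n"
                )
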