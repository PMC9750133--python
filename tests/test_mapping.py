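"""Built-in aligner, pair selection and pileups."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from organedit import (
    GenomeIndex,
    KnownEditingSite,
    OrganelleGenome,
    align_read,
    build_pileup,
    mask_known_sites,
    revcomp,
    select_organellar_pairs,
)
from organedit.mapping import AlignParams
from organedit.simulate import ReadPair

from conftest import random_genome, simple_library

_IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "Y": "CT", "R": "AG", "N": "ACGT"}


def brute_force_best(read: str, genome: OrganelleGenome):
    """Exhaustive sliding-window match count over both strands (interior
    placements only); the independent oracle for the seed-and-extend path."""
    best = (-1, None, None)
    for query, strand in ((read, "+"), (revcomp(read), "-")):
        for s in range(genome.length - len(query) + 1):
            m = sum(
                q in _IUPAC[r]
                for q, r in zip(query, genome.sequence[s : s + len(query)])
            )
            if m > best[0]:
                best = (m, s + 1, strand)
    return best


def test_exact_read_aligns_perfectly(plus_toy_genome):
    read = plus_toy_genome.sequence[200:350]
    aln = align_read(read, plus_toy_genome)
    assert aln.identity == 1.0
    assert aln.aligned_fraction == 1.0
    assert (aln.start, aln.strand) == (201, "+")


def test_reverse_complement_same_start_minus_strand(plus_toy_genome):
    read = plus_toy_genome.sequence[200:350]
    aln = align_read(revcomp(read), plus_toy_genome)
    assert (aln.start, aln.strand) == (201, "-")


def test_single_substitution_identity(plus_toy_genome):
    read = list(plus_toy_genome.sequence[200:350])
    read[70] = "A" if read[70] != "A" else "G"
    aln = align_read("".join(read), plus_toy_genome)
    assert aln.matches == 149
    assert aln.identity == pytest.approx(149 / 150)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(seed=st.integers(0, 5000), n_mismatch=st.integers(0, 5))
def test_aligner_matches_brute_force_oracle(seed, n_mismatch):
    """Seed-and-extend equals the exhaustive sliding-window oracle for reads
    with up to 5 substitutions on small genomes."""
    rng = np.random.default_rng(seed)
    genome = random_genome(1500, seed + 70_000)
    start = int(rng.integers(0, genome.length - 150))
    read = list(genome.sequence[start : start + 150])
    for i in rng.choice(150, size=n_mismatch, replace=False):
        read[i] = rng.choice([b for b in "ACGT" if b != read[i]])
    read = "".join(read)
    if rng.random() < 0.5:
        read = revcomp(read)
    aln = align_read(read, genome)
    m, s, strand = brute_force_best(read, genome)
    assert aln.matches == m
    if aln.n_best == 1:
        assert (aln.start, aln.strand) == (s, strand)


def test_masked_reference_matches_both_alleles(plus_toy_genome):
    """A read carrying the edited T at a Y-masked position aligns with the
    same score as the unedited C read (no bias for or against editing)."""
    site = KnownEditingSite("cp_toy", 391, "+", "s")
    masked = mask_known_sites(plus_toy_genome, [site])
    read_c = plus_toy_genome.sequence[300:450]
    read_t = read_c[:90] + "T" + read_c[91:]  # position 391 at offset 90
    assert align_read(read_c, masked).identity == 1.0
    assert align_read(read_t, masked).identity == 1.0


def test_multimapping_read_flagged():
    block = "ACGTTGCATGCAAGCTTGGCACTGGCCGTCGTTTTACA" * 4
    genome = OrganelleGenome(id="dup", sequence=block + "T" * 30 + block)
    aln = align_read(block[:150], genome)
    assert aln.n_best == 2
    assert aln.start == 1  # tie broken leftmost


def _pair(m1, m2, pid="p"):
    return ReadPair(pid, m1, m2, "I" * len(m1), "I" * len(m2), ("", "+", 0))


def test_pair_selection_rules(plus_toy_genome):
    g = plus_toy_genome
    good1, good2 = g.sequence[100:250], revcomp(g.sequence[300:450])
    junk = "ACGT" * 38  # 152 nt of repetitive non-genome sequence
    # both mates exactly 100 nt: rejected (strictly longer required)
    assert select_organellar_pairs([_pair(good1[:100], good2[:100])], [g]) == []
    # one alignable mate suffices
    kept = select_organellar_pairs([_pair(good1, junk)], [g])
    assert len(kept) == 1
    assert kept[0].mate2_aln is None  # junk mate excluded from pileups
    # neither mate reaches the identity floor
    assert select_organellar_pairs([_pair(junk, junk)], [g]) == []


def test_selection_monotone_in_identity(plus_toy_genome):
    pairs = simple_library(plus_toy_genome, 80, error_rate=0.08, seed=4)
    kept = {
        thr: len(select_organellar_pairs(pairs, [plus_toy_genome], min_identity=thr))
        for thr in (0.80, 0.90, 0.97)
    }
    assert kept[0.80] >= kept[0.90] >= kept[0.97]


def test_fragment_strand_follows_mate1(minus_toy_genome):
    pairs = simple_library(minus_toy_genome, 30, seed=5)
    for sp in select_organellar_pairs(pairs, [minus_toy_genome]):
        if sp.mate1_aln:
            assert sp.mate1_aln.fragment_strand == "-"
        if sp.mate2_aln:
            assert sp.mate2_aln.fragment_strand == "-"


def test_pileup_single_read_and_conservation(plus_toy_genome):
    read = plus_toy_genome.sequence[200:350]
    aln = align_read(read, plus_toy_genome)
    aln.fragment_strand = "+"
    pileup = build_pileup([aln], plus_toy_genome)
    col = pileup.column(250)
    assert col.coverage == 1
    assert col.counts == {(plus_toy_genome.base(250), "+"): 1}
    totals = pileup.counts.sum(axis=(1, 2))
    assert totals[200:350].sum() == 150  # sum of base counts = coverage


def test_duplicate_collapse(plus_toy_genome):
    read = plus_toy_genome.sequence[200:350]
    alns = []
    for _ in range(2):
        a = align_read(read, plus_toy_genome)
        a.fragment_strand = "+"
        alns.append(a)
    assert build_pileup(alns, plus_toy_genome, collapse_duplicates=True).column(250).coverage == 1
    assert build_pileup(alns, plus_toy_genome, collapse_duplicates=False).column(250).coverage == 2


def test_error_free_pileup_has_no_nonreference_bases(plus_toy_genome):
    pairs = simple_library(plus_toy_genome, 60, seed=6)
    selected = select_organellar_pairs(pairs, [plus_toy_genome])
    pileup = build_pileup(selected, plus_toy_genome)
    for p in range(plus_toy_genome.length):
        counts = pileup.counts[p].sum(axis=1)
        for b, n in zip("ACGT", counts):
            if n and b != plus_toy_genome.sequence[p]:
                raise AssertionError(f"non-reference base {b} at {p + 1}")
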