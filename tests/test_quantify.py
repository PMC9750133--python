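"""Splice-ratio, RPKM and delta-delta-Ct quantification."""

import math

import numpy as np
import pytest

from organedit import (
    ConfigurationError,
    CtMeasurement,
    DataError,
    JunctionReference,
    SimulationSpec,
    ToyGenomeConfig,
    build_toy_genome,
    relative_expression,
    rpkm,
    simulate_reads,
    splice_ratio,
)
from organedit.genome import GenomeFeature


@pytest.fixture(scope="module")
def junction_setup():
    """Toy intron-containing gene + junction references built from it."""
    cfg = ToyGenomeConfig(
        genome_id="jx",
        length=400,
        features=[
            GenomeFeature("petB_like", "CDS", 21, 350, "+"),
            GenomeFeature("i1", "intron", 141, 230, "+", parent="petB_like"),
        ],
        seed=21,
    )
    g = build_toy_genome(cfg)
    ex1 = g.sequence[20:140]
    intron = g.sequence[140:230]
    ex2 = g.sequence[230:350]
    j = JunctionReference(
        gene="petB_like",
        spliced_seq=ex1 + ex2,
        spliced_junction=len(ex1),
        unspliced5_seq=ex1 + intron,
        unspliced5_junction=len(ex1),
        unspliced3_seq=intron + ex2,
        unspliced3_junction=len(intron),
    )
    return g, j


def test_splice_ratio_three_to_one(junction_setup):
    g, j = junction_setup
    spliced_read = j.spliced_seq[j.spliced_junction - 60 : j.spliced_junction + 60]
    unspliced_read = j.unspliced5_seq[
        j.unspliced5_junction - 60 : j.unspliced5_junction + 60
    ]
    counts = splice_ratio([spliced_read] * 75 + [unspliced_read] * 25, j, 1000)
    assert counts.spliced == 75 and counts.unspliced == 25
    assert counts.ratio == pytest.approx(3.0)
    assert counts.fraction_spliced == pytest.approx(0.75)
    assert counts.norm_spliced == pytest.approx(0.075)


def test_splice_ratio_zero_unspliced_flagged(junction_setup):
    g, j = junction_setup
    read = j.spliced_seq[j.spliced_junction - 40 : j.spliced_junction + 40]
    counts = splice_ratio([read] * 10, j, 100)
    assert counts.fraction_spliced == 1.0
    assert math.isnan(counts.ratio)


def test_splice_ratio_requires_positive_total(junction_setup):
    _, j = junction_setup
    with pytest.raises(ConfigurationError):
        splice_ratio([], j, 0)


def test_non_junction_read_not_counted(junction_setup):
    g, j = junction_setup
    exon_only = j.spliced_seq[: j.spliced_junction - 15]  # never crosses
    counts = splice_ratio([exon_only], j, 10)
    assert counts.spliced == counts.unspliced == 0


def test_simulated_splice_fraction_recovery(junction_setup):
    """Junction classification recovers the simulated spliced fraction
    within 3 binomial SE."""
    from organedit.quantify import simulate_junction_reads

    g, j = junction_setup
    frac = 0.72
    reads = simulate_junction_reads(j, 2000, frac, read_length=100, seed=77)
    counts = splice_ratio(reads, j, total_mapped=len(reads))
    n = counts.spliced + counts.unspliced
    assert n >= 1000
    se = math.sqrt(frac * (1 - frac) / n)
    assert abs(counts.fraction_spliced - frac) <= 3 * se
    # ratio and fraction are mutually consistent
    f = counts.fraction_spliced
    assert counts.ratio == pytest.approx(f / (1 - f))


def test_junction_reference_overhang_validation():
    with pytest.raises(ConfigurationError):
        JunctionReference(
            gene="g", spliced_seq="ACGTACGT", spliced_junction=2,
            unspliced5_seq="ACGTACGTACGTACGTACGTACGT", unspliced5_junction=12,
            unspliced3_seq="ACGTACGTACGTACGTACGTACGT", unspliced3_junction=12,
        )


@pytest.mark.parametrize(
    "reads, length, total, expected",
    [(10, 1000, 10**6, 10.0), (0, 1000, 10**6, 0.0), (10, 1000, 2 * 10**6, 5.0)],
)
def test_rpkm(reads, length, total, expected):
    assert rpkm(reads, length, total) == expected


def test_rpkm_invalid_inputs():
    with pytest.raises(ConfigurationError):
        rpkm(1, 0, 100)
    with pytest.raises(ConfigurationError):
        rpkm(1, 100, 0)


def _ct(sample, gene, values):
    return CtMeasurement(sample=sample, gene=gene, replicates=values)


def test_relative_expression_hand_computed():
    target = [
        _ct("s1", "tg", [20.0, 20.2, 19.8]),
        _ct("s2", "tg", [18.0]),
        _ct("s3", "tg", [22.0]),
    ]
    ref = [
        _ct("s1", "act", [15.0]),
        _ct("s2", "act", [15.0]),
        _ct("s3", "act", [15.0]),
    ]
    df = relative_expression(target, ref)
    # calibrator auto-selected as max dCt (s3); folds = 2^-(dCt - 7)
    assert df.loc["s3", "fold_change"] == pytest.approx(1.0)
    assert df.loc["s2", "fold_change"] == pytest.approx(2.0 ** (7 - 3))
    assert df.loc["s1", "fold_change"] == pytest.approx(2.0 ** (7 - 5))
    assert df.fold_change.min() == pytest.approx(1.0)


def test_relative_expression_explicit_calibrator_and_ddct_sign():
    target = [_ct("a", "tg", [20.0]), _ct("b", "tg", [19.0])]
    ref = [_ct("a", "act", [15.0]), _ct("b", "act", [15.0])]
    df = relative_expression(target, ref, calibrator_sample="a")
    assert df.loc["a", "fold_change"] == pytest.approx(1.0)
    assert df.loc["b", "ddCt"] == pytest.approx(-1.0)
    assert df.loc["b", "fold_change"] == pytest.approx(2.0)


def test_relative_expression_missing_gene():
    with pytest.raises(DataError):
        relative_expression([_ct("a", "tg", [20.0])], [_ct("b", "act", [15.0])])
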