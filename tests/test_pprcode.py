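"""PPR code lookup, anchoring, cis-element scoring and consensus building."""

import numpy as np
import pytest

from organedit import (
    CisElement,
    CodeTable,
    ConfigurationError,
    DataError,
    PprMotif,
    PprProtein,
    anchor_alignment,
    degenerate_consensus,
    frequency_matrix,
    predict_binding,
    score_cis_element,
)
from organedit.pprcode import QED1_MOTIF_CLASSES, rna, score_table


def protein_of(classes, aa=("T", "N")):
    motifs = [
        PprMotif(index=i + 1, mclass=c, aa5=aa[0], aaLast=aa[1])
        for i, c in enumerate(classes)
    ]
    return PprProtein(id="p", motifs=motifs)


@pytest.fixture(scope="module")
def code():
    return CodeTable.default()


@pytest.mark.parametrize(
    "mclass, aa5, aaLast, expected",
    [
        ("S1", "T", "N", {"A"}),
        ("L1", "V", "N", {"A", "U"}),
        ("SS", "T", "D", {"G"}),
        ("P1", "N", "S", {"C"}),
        ("P1", "N", "D", {"U"}),
    ],
)
def test_code_lookups(code, mclass, aa5, aaLast, expected):
    assert code.lookup(PprMotif(1, mclass, aa5, aaLast)) == frozenset(expected)


def test_unknown_combination_is_np(code):
    assert code.lookup(PprMotif(1, "P1", "W", "W")) is None


def test_predict_binding_pure_lookup(code):
    """Rule insertion order never changes predictions."""
    rules = dict(code.rules)
    shuffled = CodeTable(dict(reversed(list(rules.items()))))
    p = protein_of(QED1_MOTIF_CLASSES)
    assert predict_binding(p, code) == predict_binding(p, shuffled)


def test_anchoring_fifteen_motifs():
    p = protein_of(QED1_MOTIF_CLASSES)
    cis = CisElement("x", "A" * 20 + "C" + "A" * 5)
    anchoring = anchor_alignment(p, cis)
    assert anchoring[15] == -4
    assert anchoring[1] == -18
    assert anchoring[9] == -10  # SS motif 9 pairs with position -10
    assert anchoring[7] == -12  # L1 motif 7 pairs with position -12


def test_anchoring_single_motif():
    p = protein_of(["P1"])
    cis = CisElement("x", "A" * 20 + "C" + "A" * 5)
    assert anchor_alignment(p, cis) == {1: -4}


def test_anchoring_footprint_overflow():
    p = protein_of(["P1"] * 30)
    cis = CisElement("x", "A" * 20 + "C" + "A" * 5)
    with pytest.raises(DataError):
        anchor_alignment(p, cis)


def test_scorecard_perfect_and_single_violation(code):
    p = protein_of(QED1_MOTIF_CLASSES)  # TN everywhere: predicts A
    perfect = CisElement("hit", "A" * 20 + "C" + "A" * 5)
    anchoring = anchor_alignment(p, perfect)
    pred = predict_binding(p, code)
    sc = score_cis_element(perfect, pred, anchoring)
    assert sc.total_mismatches == 0
    assert sc.evaluable_positions == 15

    seq = list("A" * 20 + "C" + "A" * 5)
    seq[20 - 10] = "G"  # offset -10, aligned to motif 9
    sc2 = score_cis_element(CisElement("miss", "".join(seq)), pred, anchoring)
    assert sc2.total_mismatches == 1
    assert sc2.verdicts[-10] == "mismatch"
    assert sc2.verdicts[0] == "unaligned"  # edit position itself is outside footprint


def test_scorecard_brute_force_agreement(code):
    """Per-position verdicts equal an exhaustive independent comparison."""
    rng = np.random.default_rng(7)
    p = protein_of(QED1_MOTIF_CLASSES)
    pred = predict_binding(p, code)
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGU"), size=26))
        seq = seq[:20] + "C" + seq[21:]
        cis = CisElement("r", seq)
        anchoring = anchor_alignment(p, cis)
        sc = score_cis_element(cis, pred, anchoring)
        expected = sum(
            cis.base_at(off) not in pred[k - 1]
            for k, off in anchoring.items()
            if pred[k - 1] is not None
        )
        assert sc.total_mismatches == expected


def test_all_np_code_flags_zero_evaluable():
    p = protein_of(["P1"] * 3)
    empty = CodeTable({})
    cis = CisElement("x", "A" * 20 + "C" + "A" * 5)
    sc = score_cis_element(cis, predict_binding(p, empty), anchor_alignment(p, cis))
    assert sc.total_mismatches == 0
    assert sc.evaluable_positions == 0


def test_score_table_marginals(code):
    """Row totals equal the sum of per-motif mismatch verdicts (the
    row/column marginal consistency of a match/mismatch table)."""
    rng = np.random.default_rng(11)
    p = protein_of(QED1_MOTIF_CLASSES)
    pred = predict_binding(p, code)
    cards = []
    for i in range(8):
        seq = "".join(rng.choice(list("ACGU"), size=26))
        cis = CisElement(f"s{i}", seq[:20] + "C" + seq[21:])
        cards.append(score_cis_element(cis, pred, anchor_alignment(p, cis)))
    table = score_table(cards)
    motif_cols = [c for c in table.columns if c != "total_mismatches"]
    per_motif = (table[motif_cols] == "mismatch").sum()
    assert per_motif.sum() == table["total_mismatches"].sum()
    for card in cards:
        row = table.loc[card.site_name]
        assert (row[motif_cols] == "mismatch").sum() == row["total_mismatches"]


def test_cis_element_requires_c_at_edit_position():
    with pytest.raises(DataError):
        CisElement("bad", "A" * 26)


def test_frequency_matrix_trivial_and_counting_oracle():
    a = CisElement("a", "A" * 20 + "C" + "A" * 5)
    b = CisElement("b", "A" * 20 + "C" + "A" * 5)
    freqs = frequency_matrix([a, b], span=(-20, 5))
    assert (freqs.loc["A", [-20, -1, 5]] == 1.0).all()
    assert freqs[0].tolist() == [0.0, 1.0, 0.0, 0.0]  # all C at the edit

    rng = np.random.default_rng(3)
    elements = []
    for i in range(24):
        seq = "".join(rng.choice(list("ACGU"), size=26))
        elements.append(CisElement(f"e{i}", seq[:20] + "C" + seq[21:]))
    freqs = frequency_matrix(elements, span=(-20, 5))
    assert np.allclose(freqs.sum(axis=0), 1.0)
    for off in (-17, -3, 2):
        tally = [e.base_at(off) for e in elements]
        for base in "ACGU":
            assert freqs.at[base, off] == pytest.approx(tally.count(base) / 24)


@pytest.mark.parametrize(
    "column_freqs, threshold, expected",
    [
        ({"A": 1.0}, 0.25, "A"),
        ({"A": 0.5, "U": 0.5}, 0.25, "W"),
        ({"A": 0.25, "C": 0.25, "G": 0.25, "U": 0.25}, 0.2, "N"),
        ({"A": 0.1, "C": 0.1, "G": 0.1, "U": 0.1}, 0.5, "N"),  # empty set -> N
        ({"A": 0.4, "G": 0.4, "U": 0.2}, 0.3, "R"),
    ],
)
def test_degenerate_consensus_codes(column_freqs, threshold, expected):
    import pandas as pd

    freqs = pd.DataFrame(0.0, index=list("ACGU"), columns=[-1])
    for base, f in column_freqs.items():
        freqs.at[base, -1] = f
    assert degenerate_consensus(freqs, threshold) == expected


def test_degenerate_consensus_edit_position_fixed_to_c():
    import pandas as pd

    freqs = pd.DataFrame(0.25, index=list("ACGU"), columns=[-1, 0, 1])
    assert degenerate_consensus(freqs, 0.2)[1] == "C"


def test_consensus_threshold_bounds():
    import pandas as pd

    freqs = pd.DataFrame(0.25, index=list("ACGU"), columns=[0])
    with pytest.raises(ConfigurationError):
        degenerate_consensus(freqs, 1.5)
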