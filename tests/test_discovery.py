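"""SNP calling, filtering, off-target tabulation and impact annotation."""

import pandas as pd
import pytest

from organedit import (
    ConfigurationError,
    DataError,
    KnownEditingSite,
    OrganelleGenome,
    Pileup,
    annotate_impact,
    call_snps,
    classify_affinity,
    discover_offtargets,
    editing_efficiency,
    filter_candidates,
    filter_matrix,
    per_library_counts,
)
from organedit.discovery import SnpRecord
from organedit.genome import GenomeFeature
from organedit.mapping import _BASE_INDEX


def make_pileup(genome, column_counts):
    """column_counts: {(pos, strand): {base: count}}"""
    p = Pileup(genome)
    for (pos, strand), counts in column_counts.items():
        si = 0 if strand == "+" else 1
        for base, n in counts.items():
            p.counts[pos - 1, _BASE_INDEX[base], si] = n
    return p


@pytest.mark.parametrize(
    "t, c, expected",
    [(40, 60, 40.0), (100, 0, 100.0), (0, 50, 0.0), (1, 3, 25.0)],
)
def test_editing_efficiency(t, c, expected):
    assert editing_efficiency(t, c) == expected


def test_editing_efficiency_scale_invariant():
    assert editing_efficiency(7, 13) == editing_efficiency(70, 130)


def test_editing_efficiency_zero_denominator():
    with pytest.raises(ConfigurationError):
        editing_efficiency(0, 0)


def test_snp_rate_threshold_is_inclusive():
    g = OrganelleGenome(id="g", sequence="C" * 50)
    below = make_pileup(g, {(10, "+"): {"C": 96, "T": 4}})
    at = make_pileup(g, {(10, "+"): {"C": 95, "T": 5}})
    assert call_snps(below, min_coverage=20) == []
    records = call_snps(at, min_coverage=20)
    assert len(records) == 1
    assert records[0].alt_rate == 0.05
    assert records[0].snp_class == "C_to_T"


def test_snp_min_coverage():
    g = OrganelleGenome(id="g", sequence="C" * 50)
    thin = make_pileup(g, {(10, "+"): {"C": 10, "T": 5}})
    assert call_snps(thin, min_coverage=20) == []


def test_empty_pileup_no_calls(plus_toy_genome):
    assert call_snps(Pileup(plus_toy_genome)) == []


def test_minus_strand_g_to_a_call():
    g = OrganelleGenome(id="g", sequence="G" * 50)
    p = make_pileup(g, {(25, "-"): {"G": 60, "A": 40}})
    (rec,) = call_snps(p, min_coverage=20)
    assert rec.snp_class == "G_to_A"
    assert rec.strand == "-"
    assert rec.efficiency == 40.0


def _snp(pos, strand="+", ref="C", alt="T", eff=50.0, gid="g"):
    return SnpRecord(
        genome_id=gid, position=pos, strand=strand, ref_base=ref, alt_base=alt,
        alt_rate=eff / 100, efficiency=eff, coverage=100,
        snp_class="C_to_T" if (ref, alt) == ("C", "T") and strand == "+"
        else ("G_to_A" if (ref, alt) == ("G", "A") and strand == "-" else "other"),
    )


def test_filter_candidates_exclusions():
    feats = [
        GenomeFeature("rrn", "rRNA", 100, 200, "+"),
        GenomeFeature("cds", "CDS", 300, 400, "+"),
        GenomeFeature("ig", "intergenic", 500, 600, "-"),
    ]
    known = [KnownEditingSite("g", 350, "+", "known1")]
    snps = [
        _snp(150),              # inside rRNA: dropped
        _snp(350),              # known site: dropped
        _snp(320),              # CDS: kept
        _snp(450),              # intergenic (no feature): kept
        _snp(330, strand="-", ref="G", alt="A"),   # antisense of CDS: kept
        _snp(340, ref="A", alt="G", strand="+"),   # wrong type: dropped
    ]
    out = filter_candidates(snps, known, feats)
    assert [(s.position, s.location_class) for s in out] == [
        (320, "CDS"),
        (450, "intergenic"),
        (330, "antisense"),
    ]


def test_discover_offtargets_wt_subtraction():
    mutant = {"lib1": [_snp(100, eff=30.0)], "lib2": [_snp(100, eff=55.0), _snp(200, eff=10.0)]}
    wt = [_snp(200, eff=10.0)]  # edited in wild type: excluded
    out = discover_offtargets(mutant, wt)
    assert len(out) == 1
    assert out[0].position == 100
    assert out[0].per_library_editing == {"lib1": 30.0, "lib2": 55.0}


def test_discover_offtargets_threshold_and_empty():
    mutant = {"lib": [_snp(100, eff=3.0)]}
    assert discover_offtargets(mutant, []) == []
    assert discover_offtargets({"lib": []}, []) == []


def test_discovery_threshold_monotone(fixtures):
    t2 = fixtures.table2
    libs = [c for c in t2.columns if c.endswith(("#6", "#1", "#3"))]
    sizes = [len(filter_matrix(t2, libs, threshold=thr)) for thr in (5, 10, 20, 40)]
    assert sizes == sorted(sizes, reverse=True)


def test_matrix_filter_drops_wild_type_edited_rows(fixtures):
    t2 = fixtures.table2.copy()
    t2.loc["ndhB-291", "WT"] = 10.0
    filt = filter_matrix(t2, ["UBQ::At-QED1#1"])
    assert "ndhB-291" not in filt.index


def test_classify_affinity_examples(fixtures):
    t2 = fixtures.table2
    classes = classify_affinity(
        t2,
        moderate_libs=["HPL::At-QED1#6", "HPL::At-QED1#1"],
        over_libs=["UBQ::At-QED1#3", "UBQ::At-QED1#1"],
    )
    assert classes["petB_intr-mid"] == "high"
    assert classes["ccsA-182"] == "low"
    assert classes["ccmC-83"] == "high"  # edited at 10.6% in one moderate line
    assert classify_affinity(t2.iloc[0:0], ["HPL::At-QED1#6"], ["UBQ::At-QED1#1"]) == {}


def test_classify_affinity_unknown_library(fixtures):
    with pytest.raises(ConfigurationError):
        classify_affinity(fixtures.table2, ["nope"], ["UBQ::At-QED1#1"])


@pytest.mark.parametrize(
    "cds_seq, offset, expected",
    [
        ("ATGTCATGA", 4, "S->L"),       # TCA -> TTA
        ("ATGCAATGA", 3, "Q->STOP"),    # CAA -> TAA
        ("ATGTTCTGA", 5, "synonymous"), # TTC -> TTT
        ("ATGCGATGA", 3, "R->STOP"),    # CGA -> TGA
    ],
)
def test_annotate_impact_plus_strand(cds_seq, offset, expected):
    g = OrganelleGenome(
        id="g", sequence="TT" + cds_seq + "TT",
        features=[GenomeFeature("cds", "CDS", 3, 2 + len(cds_seq), "+")],
    )
    assert annotate_impact(3 + offset, "+", g) == expected


def test_annotate_impact_minus_strand():
    # minus-strand CDS: plus-strand sequence is revcomp of ATG TCA TGA
    from organedit import revcomp

    cds = revcomp("ATGTCATGA")
    g = OrganelleGenome(
        id="g", sequence="AA" + cds + "AA",
        features=[GenomeFeature("cds", "CDS", 3, 11, "-")],
    )
    # transcript index 4 (the C of TCA) maps to plus-strand position 11 - 4
    assert annotate_impact(7, "-", g) == "S->L"


def test_annotate_impact_noncoding_and_error():
    g = OrganelleGenome(id="g", sequence="ACGTACGTT")
    assert annotate_impact(2, "+", g) == "-"
    with pytest.raises(DataError):
        annotate_impact(2, "+", g, require_cds=True)


def test_annotate_impact_spliced_cds():
    # exon1 ATG, intron GGGG, exon2 TCATGA; edit in exon2 crosses the intron
    seq = "ATG" + "GGGG" + "TCATGA"
    g = OrganelleGenome(
        id="g", sequence=seq,
        features=[
            GenomeFeature("cds", "CDS", 1, 13, "+"),
            GenomeFeature("i1", "intron", 4, 7, "+", parent="cds"),
        ],
    )
    assert annotate_impact(9, "+", g) == "S->L"
    assert annotate_impact(5, "+", g) == "-"  # intronic
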