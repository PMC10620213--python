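"""Evaluation statistics against independent oracles (statsmodels, brute force)."""
import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.contingency_tables import Table2x2
from statsmodels.stats.proportion import proportions_ztest

from trioprio.evaluate import (
    compute_or_ci,
    compute_ppv,
    concordance,
    detections_from_calls,
    diagnostic_yield,
    percent,
    round_half_up,
    summary_table,
    threshold_sweep,
    two_proportion_z,
    venn_counts,
)
from trioprio.lgd import LgdConfig
from trioprio.models import Detection, DetectionSet, GeneList, InheritanceCall, ScorePanel

from .conftest import mk_variant


def det(i, gene="GX", proband=None, inheritance="de_novo"):
    return Detection(
        variant_key=("1", 1000 + i, "A", "G"),
        proband_id=proband or f"P{i}",
        gene=gene,
        inheritance=inheritance,
        consequence_group="missense",
    )


def ds(tool, dets):
    return DetectionSet.from_iterable(tool, dets)


GENES = GeneList(frozenset({"GA", "GB", "GC"}))


# ---------------------------------------------------------------------------
# Concordance / Venn
# ---------------------------------------------------------------------------


def test_concordance_identical_and_disjoint():
    a = ds("A", [det(i) for i in range(5)])
    b = ds("B", [det(i) for i in range(5)])
    assert concordance(a, b) == 100.0
    c = ds("C", [det(i + 100) for i in range(5)])
    assert concordance(a, c) == 0.0


def test_concordance_reproduces_printed_pairwise_agreement():
    # 220- and 199-member sets sharing 164 detections: 164/255 -> 64.3%
    a = ds("A", [det(i) for i in range(220)])
    b = ds("B", [det(i) for i in range(164)] + [det(1000 + i) for i in range(35)])
    assert round_half_up(concordance(a, b)) == 64.3


def test_concordance_of_two_empty_sets_is_an_error():
    with pytest.raises(ValueError):
        concordance(ds("A", []), ds("B", []))


def test_venn_three_identical_singletons():
    sets = [ds(t, [det(0)]) for t in "ABC"]
    res = venn_counts(sets)
    assert res.union == 1
    assert res.regions[frozenset("ABC")] == 1
    assert sum(res.regions.values()) == res.union


def test_venn_regions_partition_the_union():
    rng = np.random.default_rng(9)
    pool = [det(i) for i in range(120)]
    sets = [
        ds(t, [d for d in pool if rng.random() < p])
        for t, p in (("A", 0.5), ("B", 0.4), ("C", 0.3))
    ]
    res = venn_counts(sets)
    assert sum(res.regions.values()) == res.union
    assert res.union == len(set().union(*(s.pair_keys() for s in sets)))


def test_venn_pairwise_regions_exclude_triple():
    a = ds("A", [det(0), det(1)])
    b = ds("B", [det(0), det(1), det(2)])
    c = ds("C", [det(1), det(3)])
    res = venn_counts([a, b, c])
    assert res.regions[frozenset("AB")] == 1      # det(0)
    assert res.regions[frozenset("ABC")] == 1     # det(1)
    assert res.regions[frozenset("B")] == 1       # det(2)
    assert res.regions[frozenset("C")] == 1       # det(3)
    assert res.union == 4


# ---------------------------------------------------------------------------
# PPV / OR / yield
# ---------------------------------------------------------------------------


def test_ppv_counts_listed_genes():
    members = [det(i, gene="GA") for i in range(2)] + [det(10 + i, gene="ZZ") for i in range(6)]
    assert compute_ppv(ds("A", members), GENES) == 0.25
    assert compute_ppv(ds("A", [det(0, gene="GB")]), GENES) == 1.0
    with pytest.raises(ValueError):
        compute_ppv(ds("A", []), GENES)


def test_or_ci_direct_evaluation():
    detected = [det(i, gene="GA") for i in range(20)] + [det(100 + i, gene="ZZ") for i in range(80)]
    undetected = [det(1000 + i, gene="GB") for i in range(10)] + [
        det(2000 + i, gene="YY") for i in range(90)
    ]
    s = ds("A", detected)
    background = [(d.variant_key, d.proband_id, d.gene) for d in detected + undetected]
    res = compute_or_ci(s, background, GENES)
    assert res.counts == ((20, 80), (10, 90))
    assert res.odds_ratio == pytest.approx(2.25)
    assert res.ppv == pytest.approx(0.2)
    assert not res.continuity_corrected


def test_or_ci_symmetric_table_spans_one():
    detected = [det(i, gene="GA") for i in range(25)] + [det(100 + i, gene="ZZ") for i in range(25)]
    undetected = [det(1000 + i, gene="GB") for i in range(25)] + [
        det(2000 + i, gene="YY") for i in range(25)
    ]
    s = ds("A", detected)
    bg = [(d.variant_key, d.proband_id, d.gene) for d in detected + undetected]
    res = compute_or_ci(s, bg, GENES)
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.ci_low < 1.0 < res.ci_high


def test_or_ci_zero_cell_haldane_correction():
    detected = [det(i, gene="ZZ") for i in range(30)]  # a = 0
    undetected = [det(1000 + i, gene="GB") for i in range(10)] + [
        det(2000 + i, gene="YY") for i in range(60)
    ]
    s = ds("A", detected)
    bg = [(d.variant_key, d.proband_id, d.gene) for d in detected + undetected]
    res = compute_or_ci(s, bg, GENES)
    assert res.continuity_corrected
    assert np.isfinite(res.odds_ratio) and res.odds_ratio > 0


def test_or_ci_degenerate_margin_is_error():
    detected = [det(i, gene="GA") for i in range(5)]
    s = ds("A", detected)
    bg = [(d.variant_key, d.proband_id, d.gene) for d in detected]  # no undetected
    with pytest.raises(ValueError, match="degenerate"):
        compute_or_ci(s, bg, GENES)


def test_or_ci_matches_statsmodels_on_random_tables():
    rng = np.random.default_rng(31)
    for _ in range(25):
        a, b, c, d = (int(x) for x in rng.integers(1, 80, size=4))
        detected = [det(i, gene="GA") for i in range(a)] + [
            det(200 + i, gene="ZZ") for i in range(b)
        ]
        undetected = [det(1000 + i, gene="GB") for i in range(c)] + [
            det(3000 + i, gene="YY") for i in range(d)
        ]
        s = ds("A", detected)
        bg = [(x.variant_key, x.proband_id, x.gene) for x in detected + undetected]
        res = compute_or_ci(s, bg, GENES)
        t = Table2x2(np.array([[a, b], [c, d]]))
        assert res.odds_ratio == pytest.approx(t.oddsratio)
        # statsmodels uses the exact normal quantile where the Woolf CI
        # here uses the conventional 1.96, hence the loose tolerance
        lo, hi = t.oddsratio_confint(alpha=0.05)
        assert res.ci_low == pytest.approx(lo, rel=1e-3)
        assert res.ci_high == pytest.approx(hi, rel=1e-3)


def test_diagnostic_yield_counts_probands_once():
    members = [
        det(0, gene="GA", proband="P1"),
        det(1, gene="GB", proband="P1"),  # same proband, second hit
        det(2, gene="GA", proband="P2"),
        det(3, gene="ZZ", proband="P3"),  # unlisted gene does not qualify
    ]
    assert diagnostic_yield(ds("A", members), GENES, 10) == pytest.approx(20.0)
    three = [det(i, gene="GA", proband=f"P{i}") for i in range(3)]
    assert diagnostic_yield(ds("A", three), GENES, 10) == pytest.approx(30.0)


# ---------------------------------------------------------------------------
# Two-proportion Z
# ---------------------------------------------------------------------------


def test_equal_proportions_give_z_zero_p_one():
    res = two_proportion_z(10, 100, 30, 300)
    assert res.z == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_swapping_groups_negates_z():
    r1 = two_proportion_z(40, 100, 25, 120)
    r2 = two_proportion_z(25, 120, 40, 100)
    assert r1.z == pytest.approx(-r2.z)
    assert r1.p == pytest.approx(r2.p)


def test_degenerate_pooled_proportion_flagged():
    res = two_proportion_z(0, 50, 0, 80)
    assert res.degenerate and res.p == 1.0


def test_z_matches_statsmodels_pooled_test():
    rng = np.random.default_rng(41)
    for _ in range(20):
        n1, n2 = (int(x) for x in rng.integers(20, 500, size=2))
        x1 = int(rng.integers(1, n1))
        x2 = int(rng.integers(1, n2))
        mine = two_proportion_z(x1, n1, x2, n2)
        z_sm, p_sm = proportions_ztest([x1, x2], [n1, n2])
        assert mine.z == pytest.approx(z_sm)
        assert mine.p == pytest.approx(p_sm)


# ---------------------------------------------------------------------------
# Summary table
# ---------------------------------------------------------------------------


def test_summary_table_percentages_and_stars():
    members = [det(i, inheritance="de_novo") for i in range(39)] + [
        det(100 + i, inheritance="autosomal_recessive") for i in range(181)
    ]
    s = ds("InterVar", members)
    table = summary_table(
        [s],
        background_counts={"de_novo": 43_052, "autosomal_recessive": 70_948},
        background_total=1_213_319,
        categorizer=lambda m: m.inheritance,
    )
    dn = table[table.category == "de_novo"].iloc[0]
    assert dn["count"] == 39
    assert dn["percent"] == 17.7  # 39/220 rendered half-up at one decimal
    assert bool(dn["significant"])  # 17.7% vs 3.55% background


def test_summary_table_zero_count_category():
    s = ds("A", [det(0, inheritance="de_novo")])
    table = summary_table(
        [s], {"de_novo": 10, "x_linked_male": 5}, 1000, lambda m: m.inheritance
    )
    row = table[table.category == "x_linked_male"].iloc[0]
    assert row["count"] == 0 and row["percent"] == 0.0 and not row["significant"]


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------


def make_pair(i, votes, gene):
    """Missense variant engineered to receive exactly `votes` votes."""
    damaging = dict(sift=0.01, polyphen2=0.99, cadd_phred=30.0, revel=0.9, mcap=0.5, mpc=3.0)
    benign = dict(sift=0.9, polyphen2=0.01, cadd_phred=5.0, revel=0.1, mcap=0.001, mpc=0.1)
    names = list(damaging)
    vals = {n: (damaging[n] if j < votes else benign[n]) for j, n in enumerate(names)}
    v = mk_variant(pos=5000 + i, gene=gene, scores=ScorePanel(**vals))
    call = InheritanceCall("de_novo", v.trio.proband_id, v.key)
    return v, call


def test_sweep_detection_counts_nest_and_ppv_monotone_on_constructed_cohort():
    # higher thresholds prune exactly the unlisted genes -> PPV non-decreasing
    pairs = []
    i = 0
    for votes in range(1, 7):
        gene = "GA" if votes >= 4 else "ZZ"
        for _ in range(5):
            pairs.append(make_pair(i, votes, gene))
            i += 1
    genes = GeneList(frozenset({"GA"}))
    res = threshold_sweep(pairs, genes, n_probands=1)
    counts = [p.n_detected for p in res.points]
    assert counts == sorted(counts, reverse=True)
    ppvs = [p.ppv for p in res.points]
    assert all(b >= a for a, b in zip(ppvs, ppvs[1:]))


def test_sweep_perfectly_anticorrelated_points():
    # each threshold step loses one listed-gene proband and gains PPV linearly
    pairs = []
    i = 0
    for votes in range(1, 7):
        n_listed = votes  # higher-vote variants concentrate in listed genes
        for j in range(6):
            gene = "GA" if j < n_listed else "ZZ"
            v, c = make_pair(i, votes, gene)
            c = InheritanceCall("de_novo", f"P{i}", v.key)
            pairs.append((v, c))
            i += 1
    genes = GeneList(frozenset({"GA"}))
    res = threshold_sweep(pairs, genes, n_probands=36)
    assert res.pearson_r is not None
    assert res.pearson_r == pytest.approx(
        stats.pearsonr(
            [p.ppv for p in res.points], [p.yield_percent for p in res.points]
        ).statistic
    )


def test_sweep_correlation_omitted_with_too_few_points():
    pairs = [make_pair(0, 6, "GA")]
    res = threshold_sweep(pairs, GeneList(frozenset({"GA"})), 1, ks=[5, 6])
    assert res.pearson_r is None


# ---------------------------------------------------------------------------
# Rounding helpers
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("num,den,expected", [
    (39, 220, 17.7),
    (102, 187, 54.5),
    (113, 220, 51.4),
    (55, 372, 14.8),
])
def test_percent_half_up_matches_printed_style(num, den, expected):
    assert percent(num, den) == expected


def test_round_half_up_breaks_ties_upward():
    assert round_half_up(14.45, 1) == 14.5
    assert round_half_up(2.725, 2) == 2.73
    assert round_half_up(0.3485, 3) == 0.349
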