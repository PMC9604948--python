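"""Run-level summaries, odds ratios, grade tests, correlation, ANOVA."""

import math


import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from morphokin.stats import (
    CleavageOutcomeModel,
    anova_f,
    arcsine_sqrt,
    contingency_analysis,
    grade_distribution_test,
    pairwise_t,
    pearson_correlation,
    run_level_summary,
)


# ---------------------------------------------------------------------------
# run-level proportions

def _df(pairs):
    """pairs: list of (run_id, flag) -> per-embryo frame."""
    return pd.DataFrame({"run_id": [p[0] for p in pairs],
                         "hit": [p[1] for p in pairs]})


def test_two_run_mean_sem():
    """Runs at 40% and 60% -> mean 50, SEM = sd/sqrt(2) = 10."""
    df = _df([("a", 1), ("a", 1), ("a", 0), ("a", 0), ("a", 0),
              ("b", 1), ("b", 1), ("b", 1), ("b", 0), ("b", 0)])
    s = run_level_summary(df, numerator=df["hit"] == 1)
    assert s.per_run_pct == {"a": 40.0, "b": 60.0}
    assert s.mean_pct == pytest.approx(50.0)
    assert s.sem_pct == pytest.approx(10.0)
    assert (s.pooled_numer, s.pooled_denom) == (5, 10)


def test_identical_runs_sem_zero():
    df = _df([("a", 1), ("a", 0), ("b", 1), ("b", 0)])
    s = run_level_summary(df, numerator=df["hit"] == 1)
    assert s.sem_pct == 0.0


def test_arcsine_channel_endpoints():
    df = _df([("a", 1), ("a", 1), ("b", 0), ("b", 0)])
    s = run_level_summary(df, numerator=df["hit"] == 1)
    assert s.per_run_arcsine["a"] == pytest.approx(math.pi / 2)
    assert s.per_run_arcsine["b"] == pytest.approx(0.0)
    assert s.transform_used == "arcsine_sqrt"


def test_empty_denominator_run_excluded_with_warning():
    df = pd.DataFrame({"run_id": ["a", "a", "b"],
                       "hit": [True, False, False],
                       "eligible": [True, True, False]})
    with pytest.warns(UserWarning, match="empty denominator"):
        s = run_level_summary(df, numerator=df["hit"] & df["eligible"],
                              denominator=df["eligible"])
    assert list(s.per_run_pct) == ["a"]


def test_no_eligible_runs_errors():
    df = pd.DataFrame({"run_id": ["a"], "hit": [False], "eligible": [False]})
    with pytest.raises(ValueError):
        with pytest.warns(UserWarning):
            run_level_summary(df, numerator=df["hit"] & df["eligible"],
                              denominator=df["eligible"])


def test_arcsine_domain():
    with pytest.raises(ValueError):
        arcsine_sqrt(1.2)


# ---------------------------------------------------------------------------
# odds ratios / contingency

def table_2x2(a, b, c, d, labels=("x", "ref")):
    return pd.DataFrame({labels[0]: [a, b], labels[1]: [c, d]},
                        index=["success", "failure"])


def test_or_cross_product_async_vs_sync():
    """81/271 vs 65/431 blastocyst outcome: OR = (81*366)/(190*65)."""
    res = contingency_analysis(table_2x2(81, 190, 65, 366, ("async", "sync")),
                               reference="sync")
    o, lo, hi = res.odds_ratios["async"]
    assert o == pytest.approx(81 * 366 / (190 * 65))
    assert hi == pytest.approx(3.48, abs=0.01)  # Wald upper bound
    assert lo < o < hi


def test_or_direct_vs_sync():
    res = contingency_analysis(table_2x2(24, 169, 65, 366, ("direct", "sync")),
                               reference="sync")
    assert res.odds_ratios["direct"][0] == pytest.approx(0.7996, abs=5e-4)


def test_or_symmetric_table_is_null():
    res = contingency_analysis(table_2x2(1, 1, 1, 1), reference="ref")
    assert res.odds_ratios["x"][0] == pytest.approx(1.0)
    assert res.chi2 == pytest.approx(0.0)
    assert res.chi2_p == pytest.approx(1.0)


def test_or_inversion_property():
    rng = np.random.default_rng(2)
    for _ in range(20):
        a, b, c, d = rng.integers(1, 40, size=4)
        ab = contingency_analysis(table_2x2(a, b, c, d), reference="ref")
        ba = contingency_analysis(
            pd.DataFrame({"ref": [c, d], "x": [a, b]}, index=["success", "failure"]),
            reference="x")
        assert ab.odds_ratios["x"][0] * ba.odds_ratios["ref"][0] == pytest.approx(1.0)


def test_zero_cell_haldane_anscombe():
    """0/27 outcomes: +0.5 to all cells of that comparison, flagged."""
    res = contingency_analysis(table_2x2(0, 27, 65, 366, ("reverse", "sync")),
                               reference="sync")
    assert res.continuity_applied == ("reverse",)
    expected = (0.5 * 366.5) / (27.5 * 65.5)
    assert res.odds_ratios["reverse"][0] == pytest.approx(expected)


def test_reference_all_zero_errors():
    with pytest.raises(ValueError):
        contingency_analysis(table_2x2(5, 5, 0, 0), reference="ref")


def test_negative_counts_error():
    with pytest.raises(ValueError):
        contingency_analysis(np.array([[1, -2], [3, 4]]), reference="level0")


def test_or_matches_saturated_logistic():
    """Cross-product ORs equal the fitted saturated logistic model."""
    import statsmodels.api as sm

    succ = {"sync": 65, "async": 81, "direct": 24}
    tot = {"sync": 431, "async": 271, "direct": 193}
    res = CleavageOutcomeModel(succ, tot, reference="sync").fit()

    rows, ys = [], []
    for j, lv in enumerate(["sync", "async", "direct"]):
        for y, n in ((1, succ[lv]), (0, tot[lv] - succ[lv])):
            for _ in range(n):
                rows.append([1.0, 1.0 * (j == 1), 1.0 * (j == 2)])
                ys.append(y)
    fit = sm.Logit(np.array(ys), np.array(rows)).fit(disp=0)
    assert math.exp(fit.params[1]) == pytest.approx(res.odds_ratios["async"][0], rel=1e-5)
    assert math.exp(fit.params[2]) == pytest.approx(res.odds_ratios["direct"][0], rel=1e-5)
    assert fit.bse[1] == pytest.approx(res.bse["async"], rel=1e-4)


def test_fisher_equals_hypergeometric_enumeration():
    """Two-sided Fisher p = sum of hypergeometric probabilities <= observed,
    on all 2x2 tables with margins <= 15."""
    rng = np.random.default_rng(4)
    for _ in range(60):
        m1 = int(rng.integers(1, 16))   # row margin (successes)
        m2 = int(rng.integers(1, 16))   # row margin (failures)
        n1 = int(rng.integers(1, m1 + m2))  # column margin
        a_lo, a_hi = max(0, n1 - m2), min(m1, n1)
        a = int(rng.integers(a_lo, a_hi + 1))
        table = [[a, m1 - a], [n1 - a, m2 - (n1 - a)]]
        res = contingency_analysis(
            pd.DataFrame(np.array(table), index=["success", "failure"],
                         columns=["x", "ref"]),
            reference="ref")
        pmf = [sps.hypergeom.pmf(k, m1 + m2, m1, n1) for k in range(a_lo, a_hi + 1)]
        p_obs = sps.hypergeom.pmf(a, m1 + m2, m1, n1)
        manual = sum(p for p in pmf if p <= p_obs * (1 + 1e-7))
        assert res.fisher_p == pytest.approx(manual, abs=1e-9)


def test_chi2_2x2_equals_squared_z():
    from statsmodels.stats.proportion import proportions_ztest

    res = contingency_analysis(table_2x2(30, 70, 45, 55), reference="ref")
    z, _ = proportions_ztest([30, 45], [100, 100])
    assert res.chi2 == pytest.approx(z**2)


def test_summary_renders():
    res = CleavageOutcomeModel({"sync": 65, "async": 81}, {"sync": 431, "async": 271},
                               reference="sync").fit()
    text = res.summary()
    assert "reference level: sync" in text
    assert "async" in text and "OR" in text


# ---------------------------------------------------------------------------
# grade distributions

def test_identical_grade_distributions_null():
    counts = pd.DataFrame({"good": [30, 60], "fair": [10, 20], "poor": [10, 20]},
                          index=["g1", "g2"])
    out = grade_distribution_test(counts)
    assert out["chi2"] == pytest.approx(0.0)


def test_grade_chi2_hand_computed():
    counts = pd.DataFrame({"good": [30, 10], "fair": [10, 10], "poor": [0, 10]},
                          index=["g1", "g2"])
    t = counts.to_numpy(dtype=float)
    expected = np.outer(t.sum(1), t.sum(0)) / t.sum()
    chi2_hand = ((t - expected) ** 2 / expected).sum()
    out = grade_distribution_test(counts)
    assert out["chi2"] == pytest.approx(chi2_hand)
    # pairwise block: one pair x three grades, each a Fisher p in (0, 1]
    assert len(out["pairwise"]) == 3
    assert ((out["pairwise"]["fisher_p"] > 0) & (out["pairwise"]["fisher_p"] <= 1)).all()


def test_single_grade_degenerate_group_is_finite():
    counts = pd.DataFrame({"good": [20, 5], "fair": [0, 5], "poor": [0, 5]},
                          index=["g1", "g2"])
    out = grade_distribution_test(counts)
    assert np.isfinite(out["chi2"])


def test_empty_group_excluded_with_warning():
    counts = pd.DataFrame({"good": [10, 0, 5], "fair": [5, 0, 5]},
                          index=["g1", "empty", "g3"])
    with pytest.warns(UserWarning, match="empty"):
        out = grade_distribution_test(counts)
    assert list(out["table"].index) == ["g1", "g3"]


# ---------------------------------------------------------------------------
# correlation / ANOVA

def test_correlation_perfect_lines():
    assert pearson_correlation([0, 1, 2], [1, 3, 5]).r == pytest.approx(1.0)
    assert pearson_correlation([0, 1, 2], [0, -1, -2]).r == pytest.approx(-1.0)


def test_correlation_covariance_oracle():
    x, y = np.array([1, 2, 3, 4.0]), np.array([1, 3, 2, 5.0])
    r_hand = (((x - x.mean()) * (y - y.mean())).sum()
              / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
    assert pearson_correlation(x, y).r == pytest.approx(r_hand)


def test_correlation_constant_errors():
    with pytest.raises(ValueError):
        pearson_correlation([1, 1, 1], [1, 2, 3])


def test_anova_identical_groups():
    assert anova_f([[1, 2, 3], [1, 2, 3]]) == (0.0, 1.0)


def test_anova_hand_computed():
    f, p = anova_f([[1, 2, 3], [4, 5, 6]])
    assert f == pytest.approx(13.5)
    ref = sps.f_oneway([1, 2, 3], [4, 5, 6])
    assert f == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)


def test_anova_degenerate_df_errors():
    with pytest.raises(ValueError):
        anova_f([[1.0], [2.0]])


def test_pairwise_t_matches_scipy():
    groups = {"a": [1.0, 2, 3], "b": [4.0, 5, 6], "c": [2.0, 2, 2.5]}
    out = pairwise_t(groups)
    assert len(out) == 3
    row = out[(out.group_a == "a") & (out.group_b == "b")].iloc[0]
    ref = sps.ttest_ind(groups["a"], groups["b"])
    assert row.t == pytest.approx(ref.statistic)
    assert row.p == pytest.approx(ref.pvalue)
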