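import math

import numpy as np
import pytest
from scipy import stats

from bleedvalidate.accuracy import (
    TypedContingency,
    build_contingency,
    category_ppv,
    clopper_pearson,
    diagnostic_metrics,
    likelihood_ratio_ci,
    round_half_up,
)
from bleedvalidate.codesets import Category


def cp_bisection_oracle(ks, ns, alpha=0.05, iters=60):
    """Independent Clopper-Pearson oracle: bisection on binomial tails.

    The lower bound solves P(X >= k | p) = alpha/2 (0 at k=0); the upper
    solves P(X <= k | p) = alpha/2 (1 at k=n).
    """
    ks = np.asarray(ks, dtype=float)
    ns = np.asarray(ns, dtype=float)

    def solve(tail_prob, target):
        lo, hi = np.zeros_like(ks), np.ones_like(ks)
        for _ in range(iters):
            mid = 0.5 * (lo + hi)
            too_big = tail_prob(mid) > target
            hi = np.where(too_big, mid, hi)
            lo = np.where(too_big, lo, mid)
        return 0.5 * (lo + hi)

    lower = solve(lambda p: stats.binom.sf(ks - 1, ns, p), alpha / 2)
    upper = solve(lambda p: 1.0 - stats.binom.cdf(ks, ns, p), 1.0 - alpha / 2)
    lower = np.where(ks == 0, 0.0, lower)
    upper = np.where(ks == ns, 1.0, upper)
    return lower, upper


def _table(tp, fp, fn, tn):
    return TypedContingency(
        {
            (Category.ICH, "MAJOR"): tp,
            (Category.ICH, "NOT_MAJOR"): fp,
            (Category.NONE, "MAJOR"): fn,
            (Category.NONE, "NOT_MAJOR"): tn,
        }
    )


@pytest.mark.parametrize(
    "k, n, lo, hi, nd",
    [
        (482, 736, 0.619, 0.689, 3),
        (141, 197, 0.65, 0.78, 2),
    ],
)
def test_clopper_pearson_reference_values(k, n, lo, hi, nd):
    lower, upper = clopper_pearson(k, n)
    assert round(lower, nd) == lo
    assert round(upper, nd) == hi


def test_clopper_pearson_boundary_cases():
    assert clopper_pearson(0, 10)[0] == 0.0
    assert clopper_pearson(10, 10)[1] == 1.0
    lo, hi = clopper_pearson(3, 7)
    assert lo <= 3 / 7 <= hi


@pytest.mark.parametrize("k, n, alpha", [(-1, 5, 0.05), (6, 5, 0.05), (2, 0, 0.05), (2, 5, 0.0)])
def test_clopper_pearson_domain_errors(k, n, alpha):
    with pytest.raises(ValueError):
        clopper_pearson(k, n, alpha)


def test_clopper_pearson_matches_bisection_oracle_small_grid():
    ks, ns = zip(*[(k, n) for n in range(1, 41) for k in range(n + 1)])
    lo_o, hi_o = cp_bisection_oracle(ks, ns)
    for k, n, lo_exp, hi_exp in zip(ks, ns, lo_o, hi_o):
        lo, hi = clopper_pearson(k, n)
        assert lo == pytest.approx(lo_exp, abs=1e-9)
        assert hi == pytest.approx(hi_exp, abs=1e-9)


def test_clopper_pearson_matches_statsmodels():
    from statsmodels.stats.proportion import proportion_confint

    for k, n in [(482, 736), (0, 10), (10, 10), (7, 19), (1, 1)]:
        lo, hi = clopper_pearson(k, n)
        lo_sm, hi_sm = proportion_confint(k, n, alpha=0.05, method="beta")
        assert lo == pytest.approx(float(lo_sm), abs=1e-12, rel=1e-9)
        assert hi == pytest.approx(float(hi_sm), abs=1e-12, rel=1e-9)


def test_exact_interval_coverage_at_p07_n50():
    """Over 2000 simulated binomials (p=0.7, n=50) the exact interval must
    cover the truth in at least 93% of draws (exact intervals are
    conservative)."""
    p, n = 0.7, 50
    intervals = [clopper_pearson(k, n) for k in range(n + 1)]
    rng = np.random.default_rng(20140101)
    draws = rng.binomial(n, p, size=2000)
    covered = sum(intervals[k][0] <= p <= intervals[k][1] for k in draws)
    assert covered / 2000 >= 0.93


def test_contingency_from_fixture_matches_published_cells(table2_pipeline):
    _, _, table, _ = table2_pipeline
    assert (table.positives(Category.ICH), table.negatives(Category.ICH)) == (281, 12)
    assert (table.positives(Category.GI), table.negatives(Category.GI)) == (141, 56)
    assert (table.positives(Category.OTHER), table.negatives(Category.OTHER)) == (60, 87)
    assert (table.positives(Category.NONE), table.negatives(Category.NONE)) == (254, 15121)
    assert table.tp + table.fn == 736
    assert table.fp + table.tn == 15276
    assert table.n == 16012


def test_contingency_rejects_mismatched_id_sets():
    with pytest.raises(ValueError, match="differ"):
        build_contingency({"a": Category.ICH}, {"b": "MAJOR"})


def test_contingency_trivial_tables():
    empty = build_contingency({}, {})
    assert empty.n == 0
    one = build_contingency({"a": Category.ICH}, {"a": "MAJOR"})
    assert (one.tp, one.fp, one.fn, one.tn) == (1, 0, 0, 0)


def test_fixture_accuracy_report_matches_published_metrics(table2_pipeline):
    report = table2_pipeline[3]
    assert report.se.as_percent() == (65.5, 61.9, 68.9)
    assert report.sp.as_percent() == (99.0, 98.8, 99.1)
    assert report.npv.as_percent() == (98.3, 98.1, 98.5)
    p, lo, _ = report.ppv.as_percent()
    assert (p, lo) == (75.7, 72.1)
    assert 100 * report.ppv.upper == pytest.approx(78.9, abs=0.06)
    assert round_half_up(report.lr_pos.point, 1) == 64.5
    assert round_half_up(report.lr_neg.point, 2) == 0.35


def test_per_category_ppv(table2_pipeline):
    table = table2_pipeline[2]
    ich = category_ppv(table, Category.ICH)
    assert (ich.k, ich.n) == (281, 293)
    assert round_half_up(100 * ich.point, 0) == 96
    gi = category_ppv(table, Category.GI)
    assert (gi.k, gi.n) == (141, 197)
    with pytest.raises(ValueError):
        category_ppv(table, Category.NONE)


def test_perfect_classifier_metrics():
    report = diagnostic_metrics(_table(tp=30, fp=0, fn=0, tn=70))
    assert report.se.point == 1.0 and report.sp.point == 1.0
    assert report.ppv.point == 1.0 and report.npv.point == 1.0
    assert report.lr_pos is None and "lr_positive" in report.not_applicable
    assert report.lr_neg.point == 0.0 and report.lr_neg.adjusted


def test_no_information_test_has_unit_likelihood_ratios():
    lr_pos, lr_neg = likelihood_ratio_ci(_table(tp=50, fp=50, fn=50, tn=50))
    assert lr_pos.point == pytest.approx(1.0)
    assert lr_neg.point == pytest.approx(1.0)


def test_lr_interval_matches_hand_computed_lognormal():
    tp, fp, fn, tn = 482, 155, 254, 15121
    lr_pos, _ = likelihood_ratio_ci(_table(tp, fp, fn, tn))
    se_log = math.sqrt(1 / tp - 1 / (tp + fn) + 1 / fp - 1 / (fp + tn))
    point = (tp / (tp + fn)) / (fp / (fp + tn))
    z = stats.norm.ppf(0.975)
    assert lr_pos.point == pytest.approx(point)
    assert lr_pos.lower == pytest.approx(point * math.exp(-z * se_log))
    assert lr_pos.upper == pytest.approx(point * math.exp(z * se_log))
    assert not lr_pos.adjusted


def test_zero_false_positives_gives_flagged_finite_interval():
    lr_pos, _ = likelihood_ratio_ci(_table(tp=30, fp=0, fn=10, tn=60))
    assert lr_pos.adjusted
    assert math.isinf(lr_pos.point)
    assert math.isfinite(lr_pos.lower) and math.isfinite(lr_pos.upper)


def test_scaling_all_cells_preserves_points_and_narrows_cis(table2_pipeline):
    table = table2_pipeline[2]
    big = diagnostic_metrics(table.scaled(10))
    base = diagnostic_metrics(table)
    for name in ("se", "sp", "ppv", "npv"):
        small, large = getattr(base, name), getattr(big, name)
        assert large.point == pytest.approx(small.point)
        assert (large.upper - large.lower) < (small.upper - small.lower)


def test_more_true_positives_never_lower_se_or_ppv():
    prev = diagnostic_metrics(_table(tp=10, fp=5, fn=20, tn=100))
    for tp in range(11, 40):
        cur = diagnostic_metrics(_table(tp=tp, fp=5, fn=20, tn=100))
        assert cur.se.point >= prev.se.point
        assert cur.ppv.point >= prev.ppv.point
        prev = cur


def test_empty_margins_reported_not_applicable_never_zero():
    report = diagnostic_metrics(_table(tp=0, fp=0, fn=0, tn=50))
    assert report.se is None and "sensitivity" in report.not_applicable
    assert report.ppv is None and "ppv" in report.not_applicable
    assert report.sp.point == 1.0


def test_round_half_up():
    assert round_half_up(45.75, 1) == 45.8
    assert round_half_up(0.345, 2) == 0.35
    assert round_half_up(96.5, 0) == 97
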