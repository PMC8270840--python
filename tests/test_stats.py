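"""Fracture-association statistics: oracles and invariants."""

import numpy as np
import pytest
from scipy import stats as sps

from opporscreen import (
    binormal_auc,
    bland_altman,
    delong_test,
    group_compare,
    logistic_or,
    pooled_mean,
    r_squared,
    roc_auc,
    sens_spec_at,
    standardize,
)
from opporscreen.errors import (
    DegeneratePredictorError,
    SeparationError,
    UndefinedStatisticError,
)


def pairwise_auc(outcome, scores):
    """Exhaustive concordance-pair oracle: fraction of (positive,
    negative) pairs ranked correctly, ties counted 1/2."""
    outcome = np.asarray(outcome, bool)
    pos, neg = scores[outcome], scores[~outcome]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# Standardisation


def test_standardize_location_invariance(rng):
    x = rng.normal(50, 8, 40)
    np.testing.assert_allclose(standardize(x), standardize(x + 17.3), atol=1e-12)


def test_standardize_mean_is_zero_and_hand_values():
    z = standardize([1.0, 2.0, 3.0], risk_direction="higher")
    np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])  # sample SD = 1
    zr = standardize([1.0, 2.0, 3.0], risk_direction="lower")
    np.testing.assert_allclose(zr, [1.0, 0.0, -1.0])


def test_standardize_zero_variance_rejected():
    with pytest.raises(DegeneratePredictorError):
        standardize([5.0, 5.0, 5.0])


# ---------------------------------------------------------------------------
# ROC / AUC


def test_auc_perfect_separation():
    outcome = [True] * 3 + [False] * 3
    scores = [3.0, 2.5, 2.0, 1.0, 0.5, 0.0]  # risk-oriented
    assert roc_auc(outcome, scores).auc == 1.0


def test_auc_orientation():
    """Fractured at {1,2}, non-fractured at {3,4}: risk orientation
    (lower measure = higher risk) yields AUC 1, the raw measure 0."""
    outcome = np.array([True, True, False, False])
    measure = np.array([1.0, 2.0, 3.0, 4.0])
    assert roc_auc(outcome, measure).auc == 0.0
    assert roc_auc(outcome, standardize(measure, "lower")).auc == 1.0


def test_auc_ten_point_example_matches_pair_count(rng):
    outcome = np.array([True] * 4 + [False] * 6)
    scores = np.array([2.1, 0.4, 1.8, 0.4, 0.9, 0.4, -0.3, 1.8, -1.0, 0.2])
    curve = roc_auc(outcome, scores)
    assert curve.auc == pytest.approx(pairwise_auc(outcome, scores), abs=1e-12)


@pytest.mark.parametrize("n,tie_levels", [(8, None), (23, None), (50, 6)])
def test_auc_mann_whitney_identity_random(n, tie_levels, rng):
    """AUC equals the exhaustive-pairs concordance count, with and
    without ties, for n <= 50."""
    outcome = rng.random(n) < 0.4
    outcome[0], outcome[1] = True, False  # ensure both classes
    scores = rng.normal(size=n)
    if tie_levels:
        scores = np.round(scores * tie_levels) / tie_levels
    assert roc_auc(outcome, scores).auc == pytest.approx(
        pairwise_auc(outcome, scores), abs=1e-12
    )


def test_auc_invariant_under_monotone_transform(rng):
    outcome = rng.random(40) < 0.5
    outcome[:2] = [True, False]
    scores = rng.normal(size=40)
    a = roc_auc(outcome, scores).auc
    b = roc_auc(outcome, np.exp(scores)).auc
    c = roc_auc(outcome, 3.0 * scores - 7.0).auc
    assert a == b == c


def test_roc_curve_shape_invariants(rng):
    outcome = rng.random(60) < 0.4
    outcome[:2] = [True, False]
    curve = roc_auc(outcome, rng.normal(size=60))
    assert 0.0 <= curve.auc <= 1.0
    order = np.argsort(curve.specificity)
    sens_sorted = curve.sensitivity[order]
    assert (np.diff(sens_sorted) <= 1e-12).all()  # sens falls as spec rises
    assert 0.0 <= curve.ci[0] <= curve.auc <= curve.ci[1] <= 1.0


def test_auc_single_class_rejected():
    with pytest.raises(UndefinedStatisticError):
        roc_auc([True, True], [1.0, 2.0])


def test_empirical_auc_approaches_binormal_closed_form(rng):
    """Gaussian groups at the published trabecular parameters: the
    empirical AUC converges to Phi(dmu / sqrt(s1^2 + s0^2))."""
    n = 4000
    frac = rng.normal(62.8, 27.5, n)
    nofrac = rng.normal(113.5, 34.3, n)
    outcome = np.r_[np.ones(n, bool), np.zeros(n, bool)]
    scores = standardize(np.r_[frac, nofrac], "lower")
    expected = binormal_auc(62.8, 27.5, 113.5, 34.3)
    assert roc_auc(outcome, scores).auc == pytest.approx(expected, abs=0.015)


# ---------------------------------------------------------------------------
# DeLong


def test_delong_self_comparison_p_one(rng):
    outcome = rng.random(30) < 0.5
    outcome[:2] = [True, False]
    scores = rng.normal(size=30)
    res = delong_test(outcome, scores, scores)
    assert res["difference"] == 0.0
    assert res["p"] == 1.0


def test_delong_rank_invariance(rng):
    outcome = rng.random(30) < 0.5
    outcome[:2] = [True, False]
    a = rng.normal(size=30)
    res = delong_test(outcome, a, np.tanh(a))  # strictly monotone transform
    assert res["difference"] == pytest.approx(0.0, abs=1e-12)
    assert res["p"] == pytest.approx(1.0)


def test_delong_symmetry(rng):
    outcome = rng.random(40) < 0.45
    outcome[:2] = [True, False]
    a, b = rng.normal(size=40), rng.normal(size=40)
    ab = delong_test(outcome, a, b)
    ba = delong_test(outcome, b, a)
    assert ab["p"] == pytest.approx(ba["p"], abs=1e-12)
    assert ab["difference"] == pytest.approx(-ba["difference"], abs=1e-12)


def test_delong_variance_against_bootstrap_oracle():
    """The structural-components variance of a single AUC matches a
    10^4-replicate stratified bootstrap within 10%."""
    rng = np.random.default_rng(7)
    m = n = 25
    pos = rng.normal(1.0, 1.0, m)
    neg = rng.normal(0.0, 1.0, n)
    outcome = np.r_[np.ones(m, bool), np.zeros(n, bool)]
    curve = roc_auc(outcome, np.r_[pos, neg])

    B = 10_000
    pos_b = pos[rng.integers(0, m, (B, m))]
    neg_b = neg[rng.integers(0, n, (B, n))]
    cmp = (pos_b[:, :, None] > neg_b[:, None, :]) + 0.5 * (
        pos_b[:, :, None] == neg_b[:, None, :]
    )
    boot_var = cmp.mean(axis=(1, 2)).var(ddof=1)
    assert curve.auc_var == pytest.approx(boot_var, rel=0.10)


def test_delong_discriminates_unequal_aucs(rng):
    """A strongly informative score vs pure noise on many subjects
    gives a small p."""
    n = 150
    outcome = np.r_[np.ones(n, bool), np.zeros(n, bool)]
    good = np.r_[rng.normal(1.5, 1, n), rng.normal(0, 1, n)]
    noise = rng.normal(size=2 * n)
    assert delong_test(outcome, good, noise)["p"] < 1e-4


# ---------------------------------------------------------------------------
# Sensitivity / specificity


def test_sens_spec_extremes():
    outcome = np.array([True, True, False, False])
    values = np.array([70.0, 90.0, 110.0, 130.0])
    assert sens_spec_at(outcome, values, 50.0) == (0.0, 100.0)
    assert sens_spec_at(outcome, values, 200.0) == (100.0, 0.0)


def test_sens_spec_hand_count():
    """4 fractured at {70,75,90,150}, cutoff 80: two below -> 50%."""
    outcome = np.array([True] * 4 + [False] * 4)
    values = np.array([70.0, 75.0, 90.0, 150.0, 85.0, 120.0, 60.0, 140.0])
    sens, spec = sens_spec_at(outcome, values, 80.0)
    assert sens == pytest.approx(50.0)
    assert spec == pytest.approx(75.0)  # 3 of 4 non-fractured at/above 80


def test_sens_spec_direction_above():
    outcome = np.array([True, False])
    values = np.array([10.0, 1.0])
    assert sens_spec_at(outcome, values, 5.0, direction="above") == (100.0, 100.0)


# ---------------------------------------------------------------------------
# Logistic odds ratios


def grid_search_logit(y, x, span=6.0, iters=4, width=41):
    """Independent likelihood oracle: nested grid search over
    (intercept, slope) maximising the Bernoulli log-likelihood."""
    b0, b1, half = 0.0, 0.0, span
    for _ in range(iters):
        g0 = np.linspace(b0 - half, b0 + half, width)
        g1 = np.linspace(b1 - half, b1 + half, width)
        eta = g0[:, None, None] + g1[None, :, None] * x[None, None, :]
        ll = np.sum(y * eta - np.log1p(np.exp(eta)), axis=2)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        b0, b1 = g0[i], g1[j]
        half = half * 2.0 / (width - 1) * 2
    return b0, b1


def test_logistic_or_matches_grid_oracle():
    """Six-row fit agrees with the brute-force likelihood grid to 1e-3."""
    y = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
    x = np.array([-1.2, -0.3, 0.5, -0.4, 0.8, 1.5])
    res = logistic_or(y.astype(bool), x)
    _, b1 = grid_search_logit(y, x)
    assert res.coef == pytest.approx(b1, abs=1e-3)


def test_logistic_or_null_case(rng):
    """Independent predictor: OR near 1 and CI covering 1."""
    n = 4000
    x = rng.normal(size=n)
    y = rng.random(n) < 0.4
    res = logistic_or(y, x)
    assert res.odds_ratio == pytest.approx(1.0, abs=0.1)
    assert res.ci[0] < 1.0 < res.ci[1]
    assert not res.adjusted


def test_logistic_or_median_unbiased_under_null():
    """Crude ORs on balanced null cohorts are median-unbiased at 1."""
    rng = np.random.default_rng(21)
    above = 0
    reps = 200
    for _ in range(reps):
        x = rng.normal(size=80)
        y = np.r_[np.ones(40, bool), np.zeros(40, bool)]
        above += logistic_or(y, x).odds_ratio > 1.0
    # sign test at ~4 sigma: 0.5 +/- 4*sqrt(0.25/200)
    assert 0.36 < above / reps < 0.64


def test_logistic_or_ci_coverage():
    """Wald 95% CIs cover the generating coefficient about 95% of the
    time over 500 simulated cohorts."""
    rng = np.random.default_rng(1)
    beta0, beta1 = -0.5, np.log(2.0)
    covered = 0
    reps = 500
    for _ in range(reps):
        x = rng.normal(size=150)
        p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * x)))
        y = rng.random(150) < p
        if y.all() or not y.any():
            continue
        try:
            res = logistic_or(y, x)
        except SeparationError:
            continue
        covered += res.ci[0] <= np.exp(beta1) <= res.ci[1]
    assert covered / reps == pytest.approx(0.95, abs=0.03)


def test_logistic_or_adjustment_covariates(table1_cohort):
    z = standardize(table1_cohort["trabecular_vbmd"], "lower")
    crude = logistic_or(table1_cohort["fracture"], z)
    adj = logistic_or(
        table1_cohort["fracture"], z, table1_cohort[["age", "sex"]]
    )
    assert adj.adjusted and adj.covariates == ("age", "sex")
    assert crude.odds_ratio > 1.0  # lower density, higher fracture odds
    assert adj.odds_ratio > 1.0


def test_logistic_perfect_separation_flagged():
    y = np.array([False] * 5 + [True] * 5)
    x = np.r_[np.linspace(-2, -1, 5), np.linspace(1, 2, 5)]
    with pytest.raises(SeparationError):
        logistic_or(y, x)


def test_logistic_single_class_rejected():
    with pytest.raises(UndefinedStatisticError):
        logistic_or(np.ones(6, bool), np.arange(6.0))


# ---------------------------------------------------------------------------
# Group comparison, agreement, pooling


def test_group_compare_identical_groups(rng):
    import pandas as pd

    x = rng.normal(100, 10, 30)
    table = pd.DataFrame(
        {
            "fracture": [True] * 30 + [False] * 30,
            "sex": ["F"] * 20 + ["M"] * 10 + ["F"] * 20 + ["M"] * 10,
            "trabecular_vbmd": np.r_[x, x],
        }
    )
    out = group_compare(table, ("trabecular_vbmd",))
    trow = out[out["variable"] == "trabecular_vbmd"].iloc[0]
    assert trow["statistic"] == pytest.approx(0.0, abs=1e-12)
    srow = out[out["variable"] == "women_n"].iloc[0]
    assert srow["statistic"] == pytest.approx(0.0, abs=1e-12)  # equal margins


def test_group_compare_on_simulated_cohort(table1_cohort):
    out = group_compare(
        table1_cohort, ("age", "trabecular_vbmd", "integral_vbmd")
    )
    assert set(out["test"]) == {"t", "chi2"}
    trab = out[out["variable"] == "trabecular_vbmd"].iloc[0]
    assert trab["p"] < 1e-6  # 50 mg/cm^3 group separation at n=192


def test_summary_t_test_on_published_age_summaries():
    """Ages 64.3 +/- 8.6 (n=44) vs 72.0 +/- 9.3 (n=148) differ at
    p < 0.001."""
    t, p = sps.ttest_ind_from_stats(64.3, 8.6, 44, 72.0, 9.3, 148)
    assert p < 0.001


def test_bland_altman_and_r_squared():
    a = np.array([1.0, 1.1, 0.9, 1.3, 0.8])
    b = a + 0.05
    ba = bland_altman(a, b)
    assert ba["bias"] == pytest.approx(-0.05)
    assert ba["loa_low"] == pytest.approx(-0.05)  # constant offset, zero SD
    assert r_squared(a, b) == pytest.approx(1.0)
    same = bland_altman(a, a)
    assert same["bias"] == 0.0


def test_bland_altman_hand_example():
    a = np.array([10.0, 12.0, 11.0, 9.0, 13.0])
    b = np.array([9.0, 13.0, 10.0, 9.5, 12.0])
    ba = bland_altman(a, b)
    assert ba["bias"] == pytest.approx(np.mean(a - b))
    with pytest.raises(UndefinedStatisticError):
        bland_altman(a, b[:3])


def test_pooled_mean_weighted():
    assert pooled_mean([64.3, 72.0], [44, 148]) == pytest.approx(70.235, abs=1e-3)
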