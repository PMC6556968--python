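"""Matching-weight differential machinery against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_h
from scipy import stats

import telomark as tm
from telomark import psm
from telomark.psm import balance_report


# --------------------------------------------------------------------- logistic

def _newton_logistic(X, z, tol=1e-10, max_iter=200):
    """Independent Newton-Raphson solve of the logistic score equations."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        mu = 1 / (1 + np.exp(-(X @ beta)))
        W = np.diag(mu * (1 - mu))
        step = np.linalg.solve(X.T @ W @ X, X.T @ (z - mu))
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def test_propensity_constant_covariates_give_group_proportion():
    cov = pd.DataFrame({"a": np.ones(10)})
    z = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
    m = psm.fit_propensity(cov, z)
    assert np.allclose(m.scores, 0.3, atol=1e-6)


def test_propensity_null_covariates_have_near_zero_coefficients():
    rng = np.random.default_rng(0)
    cov = pd.DataFrame(rng.standard_normal((2000, 3)), columns=list("abc"))
    z = rng.integers(0, 2, 2000)
    m = psm.fit_propensity(cov, z)
    assert np.abs(m.coefficients[["a", "b", "c"]]).max() < 0.15


def test_propensity_matches_newton_oracle_on_toy():
    cov = pd.DataFrame({"x": [0, 0, 0, 0, 1, 1, 1, 1]})
    z = np.array([0, 0, 1, 0, 1, 1, 0, 1])
    m = psm.fit_propensity(cov, z)
    X = np.column_stack([np.ones(8), cov["x"]])
    expect = _newton_logistic(X, z)
    assert np.allclose(m.coefficients.to_numpy(), expect, atol=1e-8)
    # cross-check against statsmodels
    import statsmodels.api as sm

    sm_fit = sm.Logit(z, X).fit(disp=0)
    assert np.allclose(m.coefficients.to_numpy(), sm_fit.params, atol=1e-6)


def test_propensity_separation_completes_with_clipped_scores():
    cov = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0, 10.0, 11.0, 12.0, 13.0]})
    z = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    m = psm.fit_propensity(cov, z)
    assert not m.converged or np.isfinite(m.coefficients).all()
    assert (m.scores > 0).all() and (m.scores < 1).all()


def test_propensity_singular_design_names_columns():
    cov = pd.DataFrame({"a": [1.0, 2, 3, 4, 5, 6], "b": [2.0, 4, 6, 8, 10, 12]})
    z = np.array([0, 1, 0, 1, 0, 1])
    with pytest.raises(np.linalg.LinAlgError, match="collinear"):
        psm.fit_propensity(cov, z)


def test_propensity_missing_covariates_rejected():
    cov = pd.DataFrame({"a": [1.0, np.nan, 3, 4]})
    with pytest.raises(ValueError, match="missing"):
        psm.fit_propensity(cov, np.array([0, 1, 0, 1]))


# --------------------------------------------------------------- matching weights

@pytest.mark.parametrize("e, z, expected", [
    (0.5, 1, 1.0), (0.5, 0, 1.0),
    (0.8, 1, 0.25), (0.8, 0, 1.0),
    (0.2, 0, 0.25), (0.2, 1, 1.0),
])
def test_matching_weight_closed_form(e, z, expected):
    w = psm.matching_weights(np.array([e, 0.5]), np.array([z, 1 - z]))
    assert w[0] == pytest.approx(expected)


def test_matching_weights_reject_boundary_scores():
    with pytest.raises(ValueError):
        psm.matching_weights(np.array([0.0, 0.5]), np.array([1, 0]))


def test_matching_weights_bounded_by_one():
    rng = np.random.default_rng(4)
    e = rng.uniform(0.01, 0.99, 500)
    z = rng.integers(0, 2, 500)
    w = psm.matching_weights(e, z)
    assert (w > 0).all() and (w <= 1).all()


# ------------------------------------------------------- standardized difference

def test_standardized_difference_zero_and_hundred():
    h = np.sqrt(2) / 2
    x = np.array([2 - h, 2 + h, 1 - h, 1 + h])
    z = np.array([1, 1, 0, 0])
    assert psm.standardized_difference(x, z) == pytest.approx(100.0)
    assert psm.standardized_difference(np.array([1., 2, 1, 2]),
                                       np.array([1, 1, 0, 0])) == pytest.approx(0.0)


def test_standardized_difference_zero_variance_flag():
    x = np.array([1.0, 1, 2, 2])
    z = np.array([1, 1, 0, 0])
    assert psm.standardized_difference(x, z) == np.inf


def test_standardized_difference_weighted_matches_hand_computation():
    """Explicit weighted-moment oracle on a 4-sample toy with weights from
    the matching-weight formula."""
    x = np.array([1.0, 3.0, 2.0, 6.0])
    z = np.array([1, 1, 0, 0])
    e = np.array([0.8, 0.5, 0.5, 0.2])
    w = psm.matching_weights(e, z)         # [0.25, 1, 1, 0.25]
    # hand computation, reliability-weight variance (denominator V1 - V2/V1)
    def moments(vals, wts):
        m = (wts * vals).sum() / wts.sum()
        den = wts.sum() - (wts ** 2).sum() / wts.sum()
        return m, (wts * (vals - m) ** 2).sum() / den
    m1, v1 = moments(x[:2], w[:2])
    m0, v0 = moments(x[2:], w[2:])
    expect = 100 * abs(m1 - m0) / np.sqrt((v1 + v0) / 2)
    assert psm.standardized_difference(x, z, w) == pytest.approx(expect, rel=1e-12)


# ------------------------------------------------------------------ MW estimator

def test_mw_estimator_uniform_weights_is_mean_difference():
    y = np.array([5.0, 3.0, 2.0, 1.0])
    z = np.array([1, 1, 0, 0])
    w = np.ones(4)
    assert psm.mw_estimator(y, z, w) == pytest.approx(4.0 - 1.5)


def test_mw_estimator_worked_example():
    y = np.array([3.0, 1.0, 4.0, 2.0])
    z = np.array([1, 1, 0, 0])
    w = np.array([1.0, 0.5, 1.0, 1.0])
    assert psm.mw_estimator(y, z, w) == pytest.approx(3.5 / 1.5 - 3.0)


def test_mw_estimator_zero_outcome_and_zero_weight_group():
    z = np.array([1, 1, 0, 0])
    assert psm.mw_estimator(np.zeros(4), z, np.ones(4)) == 0.0
    with pytest.raises(ValueError, match="zero weight"):
        psm.mw_estimator(np.ones(4), z, np.array([0.0, 0, 1, 1]))


def test_mw_estimator_equals_brute_force_on_random_toys():
    """dMW == brute-force two-term weighted mean difference, 100 random toys."""
    rng = np.random.default_rng(12)
    for _ in range(100):
        n = int(rng.integers(4, 40))
        z = rng.integers(0, 2, n)
        if z.sum() in (0, n):
            continue
        y = rng.standard_normal(n)
        w = rng.uniform(0.05, 1.0, n)
        num1 = sum(w[i] * z[i] * y[i] for i in range(n))
        den1 = sum(w[i] * z[i] for i in range(n))
        num0 = sum(w[i] * (1 - z[i]) * y[i] for i in range(n))
        den0 = sum(w[i] * (1 - z[i]) for i in range(n))
        assert psm.mw_estimator(y, z, w) == pytest.approx(num1 / den1 - num0 / den0)


# ------------------------------------------------------------------ WLS per feature

def test_weighted_feature_test_uniform_weights_equals_pooled_t_test():
    rng = np.random.default_rng(3)
    Y = rng.standard_normal((20, 30))
    z = np.array([1] * 15 + [0] * 15)
    res = psm.weighted_feature_test(Y, z, np.ones(30))
    t = stats.ttest_ind(Y[:, z == 1], Y[:, z == 0], axis=1)
    assert np.allclose(res["p"].to_numpy(), t.pvalue, atol=1e-10)


def test_weighted_feature_test_constant_feature_flagged():
    Y = np.vstack([np.ones(10), np.arange(10.0)])
    z = np.array([1] * 5 + [0] * 5)
    res = psm.weighted_feature_test(Y, z, np.ones(10))
    assert res["p"].iloc[0] == 1.0 and bool(res["degenerate"].iloc[0])
    assert res["p"].iloc[1] < 1.0


def test_weighted_feature_test_matches_normal_equations_oracle():
    """Explicit (X'WX)^-1 X'WY + t-tail oracle on a weighted 10-sample toy."""
    rng = np.random.default_rng(8)
    y = rng.standard_normal(10)
    z = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1, 0])
    w = rng.uniform(0.2, 1.0, 10)
    X = np.column_stack([np.ones(10), z])
    W = np.diag(w)
    beta = np.linalg.inv(X.T @ W @ X) @ X.T @ W @ y
    resid = y - X @ beta
    sigma2 = (w * resid ** 2).sum() / (10 - 2)
    se = np.sqrt(sigma2 * np.linalg.inv(X.T @ W @ X)[1, 1])
    p_expect = 2 * stats.t.sf(abs(beta[1] / se), 8)
    res = psm.weighted_feature_test(y[None, :], z, w)
    assert res["coef"].iloc[0] == pytest.approx(beta[1], rel=1e-10)
    assert res["p"].iloc[0] == pytest.approx(p_expect, rel=1e-10)


# ------------------------------------------------------------------------- BH FDR

def _bh_bruteforce(p):
    """Step-up procedure written out longhand."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * n / rank)
        q[i] = val
        prev = val
    return q


def test_bh_examples():
    assert psm.bh_fdr([0.02])[0] == pytest.approx(0.02)
    assert np.allclose(psm.bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)


@given(st_h.lists(st_h.floats(0, 1), min_size=1, max_size=60))
@settings(max_examples=100, deadline=None)
def test_bh_matches_bruteforce_and_is_monotone(pvals):
    q = psm.bh_fdr(pvals)
    assert np.allclose(q, _bh_bruteforce(pvals), atol=1e-12)
    order = np.argsort(pvals, kind="stable")
    assert (np.diff(q[order]) >= -1e-12).all()


def test_bh_permutation_invariance():
    rng = np.random.default_rng(1)
    p = rng.uniform(size=50)
    perm = rng.permutation(50)
    assert np.allclose(psm.bh_fdr(p)[perm], psm.bh_fdr(p[perm]))


# ---------------------------------------------------------------- permutation test

def test_permutation_p_bounds_and_null_feature():
    rng = np.random.default_rng(5)
    cov = pd.DataFrame({"c": rng.standard_normal(20)})
    z = np.array([1, 0] * 10)
    Y = np.vstack([np.zeros(20), rng.standard_normal(20)])
    p = psm.permutation_test(Y, z, cov, n_perm=99, seed=2)
    assert p.iloc[0] == pytest.approx(1.0)          # |d_obs| = 0 ties every shuffle
    assert (p >= 1 / 100).all() and (p <= 1).all()


def test_permutation_matches_exhaustive_enumeration():
    """Sampled permutation p agrees with exact enumeration over all 6!
    assignments of the observed (label, weight) pairs on a 6-sample toy."""
    from itertools import permutations

    y = np.array([3.1, 2.7, 2.9, 1.0, 1.2, 0.8])
    z = np.array([1, 1, 1, 0, 0, 0])
    cov = pd.DataFrame({"c": [0.1, -0.2, 0.3, 0.15, -0.1, 0.05]})
    m = psm.fit_propensity(cov, z)
    w = psm.matching_weights(m.scores, z)
    d_obs = abs(psm.mw_estimator(y, z, w))
    hits = total = 0
    for idx in permutations(range(6)):
        idx = list(idx)
        d = abs(psm.mw_estimator(y, z[idx], w[idx]))
        total += 1
        hits += d >= d_obs - 1e-12
    exact = hits / total
    p = psm.permutation_test(y[None, :], z, cov, n_perm=2000, seed=0).iloc[0]
    se = np.sqrt(exact * (1 - exact) / 2000) + 1e-3
    assert p == pytest.approx(exact, abs=3 * se + 1 / 2001)


# --------------------------------------------------------------- significance calls

def test_significant_features_strict_conjunction():
    res = pd.DataFrame({
        "fdr_q": [0.05, 0.01, 0.01, 0.04],
        "perm_p": [0.01, 0.2, 0.01, 0.04],
        "delta_mw": [1.0, 1.0, -2.0, 3.0],
    }, index=list("abcd"))
    out = psm.significant_features(res)
    assert list(out.index) == ["c", "d"]
    assert out.loc["c", "direction"] == "low-specific"
    assert out.loc["d", "direction"] == "high-specific"


def test_recovery_of_planted_features(planted_cohort):
    """Planted 1.5 SD features recovered with high sensitivity and low
    false-discovery proportion (set-comparison oracle against truth)."""
    co = planted_cohort
    z = co.clinical.group
    model = tm.MatchingWeightDifferential(co.layers["mrna"], z,
                                          co.clinical.covariates)
    res = model.fit(n_perm=200, seed=3)
    called = set(res.significant.index)
    truth_diff = set(co.truth.differential["mrna"])
    associated = co.truth.group_associated("mrna")
    sens = len(called & truth_diff) / len(truth_diff)
    fdp = len(called - associated) / max(len(called), 1)
    assert sens >= 0.8
    assert fdp <= 0.1


# -------------------------------------------------------------------- resampling

def test_resampling_full_cohort_gives_r_one():
    """With equal groups and min_per_group one below the group size, every
    resample is the full cohort, so r must be exactly 1."""
    rng = np.random.default_rng(2)
    n = 70
    z = np.array([1, 0] * (n // 2))
    cov = pd.DataFrame({"c": rng.standard_normal(n)})
    Y = rng.standard_normal((12, n))
    rs = psm.resampling_robustness(Y, z, cov, n_resamples=3,
                                   min_per_group=n // 2 - 1, seed=0)
    assert np.allclose(rs, 1.0)


def test_resampling_bounds_and_determinism(planted_cohort):
    co = planted_cohort
    z = co.clinical.group
    a = psm.resampling_robustness(co.layers["mrna"], z, co.clinical.covariates,
                                  n_resamples=5, seed=9)
    b = psm.resampling_robustness(co.layers["mrna"], z, co.clinical.covariates,
                                  n_resamples=5, seed=9)
    assert np.allclose(a, b)
    assert (np.abs(a) <= 1.0).all()
    # strong planted effects make resampled effect vectors highly correlated
    assert a.min() > 0.8


def test_resampling_small_group_error():
    rng = np.random.default_rng(0)
    cov = pd.DataFrame({"c": rng.standard_normal(40)})
    z = np.array([1] * 20 + [0] * 20)
    with pytest.raises(ValueError, match="exceed"):
        psm.resampling_robustness(rng.standard_normal((3, 40)), z, cov,
                                  min_per_group=30)


# ------------------------------------------------------------------------ balance

def test_balance_is_restored_by_weighting(planted_cohort):
    co = planted_cohort
    z = co.clinical.group
    m = psm.fit_propensity(co.clinical.covariates, z)
    w = psm.matching_weights(m.scores, z)
    rep = balance_report(co.clinical.covariates, z, w)
    assert (rep.table["before"] > rep.table["after"]).all()
    assert rep.balanced(threshold=10.0)
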