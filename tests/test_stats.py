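"""Oracles for the screening and logistic-modeling layer.

statsmodels serves as the independent maximum-likelihood oracle; 2x2
closed forms and hand-computed pooled t statistics check the rest.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from thymoshape.stats import (ContingencyTable2x2, SeparationError,
                              association_test, backward_stepwise,
                              likelihood_ratio_test, logistic_fit,
                              odds_ratio_wald, two_sample_t,
                              univariate_screen, vif)

CYSTIC = ContingencyTable2x2(a=16, b=14, c=3, d=20)


# ---------------------------------------------------------------------------
# 2x2 odds ratio

def test_cystic_change_odds_ratio_published_values():
    """Cross-product OR of the cystic-change table: 7.619 (1.861-31.196)."""
    res = odds_ratio_wald(CYSTIC)
    assert res.or_ == pytest.approx(7.619, abs=5e-4)
    assert res.ci_low == pytest.approx(1.861, abs=5e-4)
    assert res.ci_high == pytest.approx(31.196, abs=5e-3)


def test_balanced_table_or_one_symmetric_ci():
    res = odds_ratio_wald(ContingencyTable2x2(10, 10, 10, 10))
    assert res.or_ == pytest.approx(1.0)
    assert res.ci_low * res.ci_high == pytest.approx(1.0)


def test_unit_table_ci_closed_form():
    res = odds_ratio_wald(ContingencyTable2x2(1, 1, 1, 1))
    assert res.se_log_or == pytest.approx(2.0)
    z = sps.norm.ppf(0.975)
    assert res.ci_low == pytest.approx(math.exp(-2 * z))
    assert res.ci_high == pytest.approx(math.exp(2 * z))


def test_zero_cell_haldane_correction():
    res = odds_ratio_wald(ContingencyTable2x2(5, 5, 0, 10))
    assert res.corrected
    assert np.isfinite(res.or_) and res.or_ > 1


def test_empty_margin_rejected():
    with pytest.raises(ValueError, match="margin"):
        odds_ratio_wald(ContingencyTable2x2(0, 5, 0, 5))


@given(a=st.integers(1, 30), b=st.integers(1, 30),
       c=st.integers(1, 30), d=st.integers(1, 30))
@settings(deadline=None, max_examples=200, derandomize=True)
def test_odds_ratio_invariants_hold_for_all_positive_tables(a, b, c, d):
    res = odds_ratio_wald(ContingencyTable2x2(a, b, c, d))
    assert res.ci_low <= res.or_ <= res.ci_high
    assert res.or_ == pytest.approx((a * d) / (b * c))
    assert res.or_ == pytest.approx(math.exp(res.log_or))
    # swapping factor presence/absence inverts the OR
    swapped = odds_ratio_wald(ContingencyTable2x2(b, a, d, c))
    assert swapped.or_ == pytest.approx(1.0 / res.or_)
    assert swapped.ci_low == pytest.approx(1.0 / res.ci_high)


# ---------------------------------------------------------------------------
# association tests

def test_cystic_table_uses_chi_square():
    # expected counts: min = 19*23/53 = 8.2 >= 5 -> Pearson without
    # continuity correction; chi2 = 9.19 by hand on the margins
    stat, p, name = association_test(CYSTIC)
    arr = CYSTIC.as_array()
    expected = arr.sum(1, keepdims=True) @ arr.sum(0, keepdims=True) \
        / arr.sum()
    chi2_hand = (((arr - expected) ** 2) / expected).sum()
    assert name == "chi2"
    assert stat == pytest.approx(chi2_hand)
    assert stat == pytest.approx(9.19, abs=0.05)
    assert p < 0.01


def test_no_association_statistic_zero():
    stat, p, name = association_test(ContingencyTable2x2(5, 5, 5, 5))
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_small_expected_counts_fire_fisher():
    # expected min = 10*10/20 = 5? rows (1,9) cols (10,10): min expected
    # cell = 10*10/20 = 5 -> use (1,9,9,1): expected all 5 -> not < 5;
    # shrink to force Fisher
    _, _, name = association_test(ContingencyTable2x2(1, 6, 6, 1))
    assert name == "fisher"
    _, p_scipy = sps.fisher_exact([[1, 6], [6, 1]])
    stat, p, _ = association_test(ContingencyTable2x2(1, 6, 6, 1))
    assert p == pytest.approx(p_scipy)


# ---------------------------------------------------------------------------
# t-test

def test_t_identical_groups():
    x = np.arange(10.0)
    t, p = two_sample_t(x, x)
    assert t == 0.0 and p == pytest.approx(1.0)


def test_t_separated_groups():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 30)
    _, p = two_sample_t(x, x + 10)
    assert p < 1e-10


def test_t_matches_pooled_textbook_formula():
    x = np.array([4.0, 5.0, 6.0, 7.0, 8.0])
    y = np.array([5.5, 6.5, 7.5, 8.5, 10.5])
    sp2 = (x.var(ddof=1) * 4 + y.var(ddof=1) * 4) / 8
    t_hand = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / 5 + 1 / 5))
    t, p = two_sample_t(x, y)
    assert t == pytest.approx(t_hand)
    assert p == pytest.approx(2 * sps.t.sf(abs(t_hand), 8))


# ---------------------------------------------------------------------------
# univariate screen

def test_screen_reproduces_printed_significance(cystic_cohort):
    cohort = cystic_cohort.copy()
    # calcification 4/23 vs 7/30 (printed p = 0.738)
    calc = np.zeros(53, int)
    calc[:4] = 1
    calc[23:30] = 1
    cohort["calcification"] = calc
    screen = univariate_screen(cohort, ["cystic_change", "calcification"])
    p = screen.set_index("variable")["p"]
    assert p["cystic_change"] < 0.05
    assert p["calcification"] > 0.5


def test_screen_constant_variable_flagged(cystic_cohort):
    cohort = cystic_cohort.assign(always_zero=0)
    screen = univariate_screen(cohort, ["always_zero"])
    assert bool(screen.loc[0, "flagged"])
    assert screen.loc[0, "p"] == 1.0


def test_screen_type_one_error_rate_under_label_shuffle(cystic_cohort):
    """Shuffled labels produce ~alpha false positives, none extreme."""
    rng = np.random.default_rng(42)
    cohort = cystic_cohort.copy()
    cohort["age"] = rng.normal(54, 13, len(cohort))
    hits, total = 0, 0
    for _ in range(200):
        shuffled = cohort.copy()
        shuffled["label"] = rng.permutation(cohort["label"].to_numpy())
        screen = univariate_screen(shuffled, ["age"])
        p = screen["p"].iloc[0]
        assert p > 0.001
        hits += p < 0.05
        total += 1
    assert hits / total == pytest.approx(0.05, abs=0.04)


# ---------------------------------------------------------------------------
# logistic regression

def _cohort_design(table: ContingencyTable2x2):
    y = np.r_[np.ones(table.a + table.b), np.zeros(table.c + table.d)]
    x = np.r_[np.ones(table.a), np.zeros(table.b),
              np.ones(table.c), np.zeros(table.d)]
    return pd.DataFrame({"factor": x}), y


def test_single_binary_predictor_equals_cross_product_or():
    X, y = _cohort_design(CYSTIC)
    fit = logistic_fit(X, y)
    assert fit.odds_ratios["factor"] == pytest.approx(7.619, abs=5e-4)
    wald = odds_ratio_wald(CYSTIC)
    ci = fit.wald_ci.loc["factor"]
    assert ci.ci_low == pytest.approx(wald.ci_low, rel=1e-4)
    assert ci.ci_high == pytest.approx(wald.ci_high, rel=1e-4)


def test_or_equals_cross_product_on_random_tables():
    rng = np.random.default_rng(5)
    for _ in range(50):
        cells = rng.integers(2, 25, size=4)
        table = ContingencyTable2x2(*map(int, cells))
        X, y = _cohort_design(table)
        fit = logistic_fit(X, y)
        expected = (cells[0] * cells[3]) / (cells[1] * cells[2])
        assert fit.odds_ratios["factor"] == pytest.approx(expected,
                                                          rel=1e-6)
        wald = odds_ratio_wald(table)
        assert fit.se["factor"] == pytest.approx(wald.se_log_or, rel=1e-6)


def test_intercept_only_closed_form():
    y = np.r_[np.ones(30), np.zeros(23)]
    X = pd.DataFrame(index=range(53))
    from thymoshape.stats import _fit_subset
    fit = _fit_subset(X, y, [], "raise")
    assert fit.coef["intercept"] == pytest.approx(math.log(30 / 23))


def test_logistic_matches_statsmodels_oracle():
    import statsmodels.api as sm
    rng = np.random.default_rng(8)
    n = 120
    X = pd.DataFrame({
        "x1": rng.normal(size=n),
        "x2": (rng.random(n) < 0.4).astype(float),
        "x3": rng.normal(10, 3, n),
    })
    eta = -0.5 + 0.8 * X.x1 + 1.2 * X.x2 - 0.1 * X.x3
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    fit = logistic_fit(X, y)
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    assert fit.coef["intercept"] == pytest.approx(ref.params["const"],
                                                  rel=1e-5, abs=1e-7)
    for c in X.columns:
        assert fit.coef[c] == pytest.approx(ref.params[c], rel=1e-5)
        assert fit.se[c] == pytest.approx(ref.bse[c], rel=1e-4)
    assert fit.loglik == pytest.approx(ref.llf, rel=1e-8)
    assert fit.converged


def test_null_covariates_give_small_z():
    rng = np.random.default_rng(15)
    n = 200
    X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
    y = (rng.random(n) < 0.5).astype(float)
    fit = logistic_fit(X, y)
    assert np.abs(fit.zvalues[list("abc")]).max() < 3.5
    null_dev = -2 * _null_loglik(y)
    assert fit.deviance == pytest.approx(null_dev, abs=12)


def _null_loglik(y):
    p = y.mean()
    return float(np.sum(y * math.log(p) + (1 - y) * math.log(1 - p)))


def test_perfect_separation_detected():
    x = np.r_[np.zeros(20), np.ones(20)]
    y = x.copy()
    with pytest.raises(SeparationError, match="separation"):
        logistic_fit(pd.DataFrame({"x": x}), y)


def test_constant_column_rejected():
    y = np.r_[np.ones(10), np.zeros(10)]
    with pytest.raises(ValueError, match="constant"):
        logistic_fit(pd.DataFrame({"x": np.ones(20)}), y)


# ---------------------------------------------------------------------------
# LRT and stepwise

def test_lrt_identical_models_zero():
    X, y = _cohort_design(CYSTIC)
    fit = logistic_fit(X, y)
    lr, df, p = likelihood_ratio_test(fit, fit)
    assert (lr, df, p) == (0.0, 0, 1.0)


def test_lrt_equals_deviance_difference():
    rng = np.random.default_rng(2)
    n = 150
    X = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
    y = (rng.random(n) < 1 / (1 + np.exp(-(X.x1 * 2)))).astype(float)
    full = logistic_fit(X, y)
    reduced = logistic_fit(X[["x2"]], y)
    lr, df, p = likelihood_ratio_test(full, reduced)
    assert df == 1
    assert lr == pytest.approx(reduced.deviance - full.deviance, abs=1e-8)
    assert p < 0.001  # strong planted effect dropped


def test_lrt_non_nested_rejected():
    rng = np.random.default_rng(3)
    X = pd.DataFrame(rng.normal(size=(60, 2)), columns=["a", "b"])
    y = (rng.random(60) < 0.5).astype(float)
    with pytest.raises(ValueError, match="nested"):
        likelihood_ratio_test(logistic_fit(X[["a"]], y),
                              logistic_fit(X[["b"]], y))


def _planted_effect_cohort(seed, n=200, beta=math.log(7)):
    rng = np.random.default_rng(seed)
    cystic = (rng.random(n) < 0.4).astype(float)
    noise = rng.normal(size=n)
    eta = -beta / 2 + beta * cystic
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return pd.DataFrame({"cystic": cystic, "noise": noise}), y


def test_stepwise_retains_planted_effect_drops_noise():
    X, y = _planted_effect_cohort(0)
    res = backward_stepwise(X, y)
    assert res.selected == ["cystic"]
    assert any(t["action"] == "remove" and t["variable"] == "noise"
               for t in res.trace)


def test_stepwise_single_significant_candidate_kept():
    X, y = _planted_effect_cohort(1)
    res = backward_stepwise(X[["cystic"]], y)
    assert res.selected == ["cystic"]
    assert res.trace == []


def test_stepwise_null_candidates_usually_intercept_only():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        X = pd.DataFrame(rng.normal(size=(200, 2)), columns=["u", "v"])
        y = (rng.random(200) < 0.5).astype(float)
        res = backward_stepwise(X, y)
        hits += res.intercept_only
    assert hits >= 15  # ~ (1 - p_remove)^2 of seeds keep nothing


def test_stepwise_threshold_extremes():
    X, y = _planted_effect_cohort(4)
    full = backward_stepwise(X, y, p_remove=1.0 - 1e-9)
    assert set(full.selected) == {"cystic", "noise"}
    none = backward_stepwise(X, y, p_remove=1e-12, p_enter=1e-12)
    assert none.intercept_only


def test_stepwise_empty_candidates_flagged():
    y = np.r_[np.ones(10), np.zeros(10)]
    res = backward_stepwise(pd.DataFrame(index=range(20)), y)
    assert res.intercept_only
    assert res.fit.variables == []


# ---------------------------------------------------------------------------
# VIF

def test_vif_orthogonal_predictors_one():
    n = 64
    X = pd.DataFrame({
        "a": np.tile([1.0, -1.0], n // 2),
        "b": np.repeat([1.0, -1.0], n // 2),
    })
    assert vif(X).max() == pytest.approx(1.0, abs=1e-10)


def test_vif_near_collinear_explodes():
    rng = np.random.default_rng(1)
    x1 = rng.normal(size=100)
    X = pd.DataFrame({"x1": x1, "x2": x1 + rng.normal(0, 1e-4, 100)})
    assert vif(X).max() > 10


def test_vif_correlated_gaussians_closed_form():
    """Three rho=0.5 equicorrelated Gaussians: R2_j = 1/3, VIF = 1.5."""
    rng = np.random.default_rng(9)
    cov = np.full((3, 3), 0.5) + 0.5 * np.eye(3)
    X = pd.DataFrame(rng.multivariate_normal(np.zeros(3), cov, 2000),
                     columns=["a", "b", "c"])
    # oracle: R2 from explicit least squares of a on (b, c)
    A = np.column_stack([np.ones(2000), X[["b", "c"]]])
    coef, *_ = np.linalg.lstsq(A, X["a"], rcond=None)
    resid = X["a"] - A @ coef
    r2 = 1 - resid.var() / X["a"].var()
    assert vif(X)["a"] == pytest.approx(1 / (1 - r2), rel=1e-6)
    assert vif(X)["a"] == pytest.approx(1.5, abs=0.15)


def test_vif_exact_collinearity_reported_infinite():
    x = np.arange(50.0)
    X = pd.DataFrame({"x": x, "two_x": 2 * x})
    assert np.isinf(vif(X)).all()
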