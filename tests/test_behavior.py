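"""SUR, Shapley R², turning point, and domain regressions."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from narraging.behavior import (SUR, compare_group_coefficients,
                                estimate_turning_point,
                                fit_domain_regressions, shapley_r2)
from narraging.cohort import COGNITIVE_DOMAINS


def make_sur_data(n=200, rho=0.6, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.standard_normal((n, 3)), columns=["a", "b", "c"])
    cov = np.array([[1.0, rho], [rho, 1.0]])
    E = rng.multivariate_normal([0, 0], cov, size=n)
    y1 = 1.0 + 0.8 * X["a"] - 0.4 * X["b"] + E[:, 0]
    y2 = -0.5 + 0.2 * X["a"] + 0.6 * X["c"] + E[:, 1]
    Y = pd.DataFrame({"y1": y1, "y2": y2})
    return Y, X


def test_sur_equals_ols_with_identical_designs():
    """With a shared design SUR collapses to equation-wise OLS exactly."""
    Y, X = make_sur_data(rho=0.6)
    fit = SUR(Y, X).fit()
    for e, col in enumerate(Y.columns):
        ols = sm.OLS(Y[col], sm.add_constant(X)).fit()
        np.testing.assert_allclose(fit.params[e], ols.params.to_numpy(),
                                   atol=1e-8)


def test_sur_reduces_to_ols_under_zero_cross_correlation():
    Y, X = make_sur_data(rho=0.0, seed=3)
    fit = SUR(Y, X).fit()
    ols0 = sm.OLS(Y["y1"], sm.add_constant(X)).fit()
    np.testing.assert_allclose(fit.params[0], ols0.params.to_numpy(), atol=1e-8)
    # residual covariance estimate is symmetric PSD
    w = np.linalg.eigvalsh(fit.resid_cov)
    assert w.min() > -1e-12


def test_sur_wald_equals_brute_force_quadratic_form():
    """Cross-equation Wald chi2 equals the explicitly assembled quadratic
    form c' beta (c' V c)^-1 beta' c on a 2-equation toy system."""
    Y, X = make_sur_data(n=120, rho=0.5, seed=9)
    fit = SUR(Y, X).fit()
    k = len(fit.param_names)
    for param in ("a", "b", "c"):
        j = fit.param_names.index(param)
        c = np.zeros(2 * k)
        c[j], c[k + j] = 1.0, -1.0
        beta = fit.params.reshape(-1)
        chi2_brute = (c @ beta) ** 2 / (c @ fit.cov_params @ c)
        chi2, p = fit.wald_cross_equation(param)
        assert chi2 == pytest.approx(chi2_brute, rel=1e-10)
        assert 0 <= p <= 1


def test_sur_singular_design_names_columns():
    Y, X = make_sur_data(n=50)
    X["dup"] = X["a"] * 2.0
    with pytest.raises(np.linalg.LinAlgError, match="dup|a"):
        SUR(Y, X)


def test_group_coefficient_contrast_detects_slope_shift():
    rng = np.random.default_rng(4)
    n = 400
    g = (rng.random(n) < 0.5).astype(int)
    x = rng.standard_normal(n)
    y = 1.0 + (0.2 + 0.8 * g) * x + 0.5 * rng.standard_normal(n)
    tab = compare_group_coefficients(y, pd.DataFrame({"x": x}), g).set_index("param")
    assert tab.loc["x", "p"] < 1e-4


def test_shapley_shares_sum_and_special_cases():
    rng = np.random.default_rng(5)
    n = 300
    X = pd.DataFrame(rng.standard_normal((n, 5)),
                     columns=["v1", "v2", "v3", "v4", "v5"])
    y = 0.6 * X["v1"] - 0.3 * X["v4"] + rng.standard_normal(n)
    dec = shapley_r2(y, X)
    # decomposition identity
    assert dec.shares.sum() == pytest.approx(dec.full_r2, abs=1e-10)
    # permutation invariance of predictor ordering
    dec2 = shapley_r2(y, X[["v4", "v2", "v5", "v1", "v3"]])
    for c in X.columns:
        assert dec2.shares[c] == pytest.approx(dec.shares[c], abs=1e-12)
    # single predictor: share equals the simple-regression R^2
    dec1 = shapley_r2(y, X[["v1"]])
    r2 = sm.OLS(y, sm.add_constant(X["v1"])).fit().rsquared
    assert dec1.shares["v1"] == pytest.approx(r2, abs=1e-12)


def test_shapley_orthogonal_predictors_get_individual_r2():
    rng = np.random.default_rng(6)
    n = 256
    a = np.tile([1.0, -1.0], n // 2)
    b = np.repeat([1.0, -1.0], n // 2)  # exactly orthogonal to a
    y = 0.5 * a + 0.25 * b + 0.1 * rng.standard_normal(n)
    X = pd.DataFrame({"a": a, "b": b})
    dec = shapley_r2(y, X)
    for c in ("a", "b"):
        r2 = sm.OLS(y, sm.add_constant(X[c])).fit().rsquared
        assert dec.shares[c] == pytest.approx(r2, abs=1e-10)


def test_turning_point_recovery_at_72():
    rng = np.random.default_rng(8)
    age = rng.uniform(50, 90, 600)
    y = -0.02 * age - 0.25 * np.maximum(age - 72.0, 0) + 0.15 * rng.standard_normal(600)
    tp = estimate_turning_point(age, y, n_boot=100, seed=0)
    assert tp.found
    assert abs(tp.age - 72.0) <= 1.0
    assert tp.ci[0] <= tp.age <= tp.ci[1]


def test_turning_point_absent_for_linear_trend():
    rng = np.random.default_rng(101)
    age = rng.uniform(50, 90, 500)
    y = -0.05 * age + 0.3 * rng.standard_normal(500)
    tp = estimate_turning_point(age, y, n_boot=50, seed=0)
    assert not tp.found
    assert tp.age is None


def test_turning_point_bootstrap_deterministic_and_affine_equivariant():
    rng = np.random.default_rng(10)
    age = rng.uniform(50, 90, 300)
    y = -0.03 * age - 0.2 * np.maximum(age - 70.0, 0) + 0.2 * rng.standard_normal(300)
    tp1 = estimate_turning_point(age, y, n_boot=60, seed=5)
    tp2 = estimate_turning_point(age, y, n_boot=60, seed=5)
    assert tp1.ci == tp2.ci and tp1.age == tp2.age
    tp3 = estimate_turning_point(age, 3.0 * y + 10.0, n_boot=60, seed=5)
    assert tp3.age == pytest.approx(tp1.age, abs=1e-9)


def test_domain_regression_exact_recovery(recovery_cohort):
    cohort, _ = recovery_cohort
    ph = cohort.phenotype
    y = 2.0 + 0.5 * ph["mem"] - 0.3 * ph["flu"]
    X = ph[["mem", "flu"]].astype(float)
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    np.testing.assert_allclose(fit.params.to_numpy(), [2.0, 0.5, -0.3], atol=1e-8)


def test_verbal_fluency_dominates_micro_regression(recovery_cohort):
    cohort, _ = recovery_cohort
    doms = [d for d in COGNITIVE_DOMAINS if d != "mmse"]
    tab = fit_domain_regressions(cohort, "micro_score", doms)
    t = tab.drop(index="const")["t"].abs()
    assert t.idxmax() == "flu"
    assert tab.loc["flu", "p"] < 1e-10


def test_ols_p_matches_permutation_p_on_fixture():
    """Analytic coefficient p agrees with a brute-force permutation p within
    Monte-Carlo error on a 50-subject fixture."""
    rng = np.random.default_rng(12)
    n = 50
    x = rng.standard_normal(n)
    y = 0.35 * x + rng.standard_normal(n)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    p_ols = fit.pvalues[1]
    t_obs = abs(fit.tvalues[1])
    B = 3000
    count = 0
    for _ in range(B):
        yp = y[rng.permutation(n)]
        f = sm.OLS(yp, sm.add_constant(x)).fit()
        count += abs(f.tvalues[1]) >= t_obs
    p_perm = (1 + count) / (1 + B)
    assert abs(p_perm - p_ols) < 0.04
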