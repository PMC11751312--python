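"""Behavioural-level analyses.

* Multiple regression of narrative scores on cognitive-domain scores.
* Seemingly unrelated regression (SUR, Zellner feasible GLS) of macro and
  micro equations with cross-equation Wald tests per predictor.
* Exact Shapley-Owen decomposition of a regression's R² over predictors.
* Nonlinear aging trajectory with a change-point ("turning point")
  estimator: a penalized-spline smooth describes the trend, and the
  change point itself is the breakpoint of the best-fitting continuous
  two-segment (hinge) model over a candidate-age grid, declared only when
  the slope change is significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._stats import rng_for
from .cohort import COGNITIVE_DOMAINS, Cohort

__all__ = ["SUR", "SURFit", "shapley_r2", "ShapleyDecomposition",
           "estimate_turning_point", "TurningPoint", "fit_domain_regressions",
           "compare_group_coefficients"]


# ---------------------------------------------------------------------------
# Seemingly unrelated regression
# ---------------------------------------------------------------------------

class SUR:
    """Zellner feasible-GLS SUR for equations sharing one observation set.

    Parameters
    ----------
    endog : (n, g) DataFrame, one column per equation response.
    exog : (n, k) DataFrame of predictors (same design in every equation;
        an intercept is appended).
    """

    def __init__(self, endog: pd.DataFrame, exog: pd.DataFrame,
                 add_const: bool = True):
        if len(endog) != len(exog):
            raise ValueError("endog and exog must share observations")
        self.endog = endog.reset_index(drop=True)
        X = exog.reset_index(drop=True).astype(float)
        if add_const:
            X = sm.add_constant(X)
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            # name the offending columns for the caller
            bad = []
            cols = X.to_numpy()
            for c in range(X.shape[1]):
                others = np.delete(cols, c, axis=1)
                if np.linalg.matrix_rank(others) == rank:
                    bad.append(X.columns[c])
            raise np.linalg.LinAlgError(
                f"singular design; linearly dependent columns include {bad}")
        self.exog = X

    def fit(self) -> "SURFit":
        Y = self.endog.to_numpy(dtype=float)
        X = self.exog.to_numpy(dtype=float)
        n, g = Y.shape
        k = X.shape[1]
        # stage 1: equation-wise OLS residuals -> cross-equation covariance
        beta_ols, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta_ols
        sigma = resid.T @ resid / n
        sigma_inv = np.linalg.inv(sigma)
        # stage 2: joint GLS with Omega = Sigma (x) I_n
        XtX = X.T @ X
        XtY = X.T @ Y
        A = np.kron(sigma_inv, XtX)
        b = (XtY @ sigma_inv).T.reshape(-1)   # stacked by equation
        beta = np.linalg.solve(A, b).reshape(g, k)
        cov = np.linalg.inv(A)                # (g*k) x (g*k), equation-major
        return SURFit(model=self, params=beta, cov_params=cov,
                      resid_cov=sigma, equation_names=list(self.endog.columns),
                      param_names=list(self.exog.columns))


@dataclass
class SURFit:
    model: SUR = field(repr=False)
    params: np.ndarray               # (g, k)
    cov_params: np.ndarray = field(repr=False)
    resid_cov: np.ndarray
    equation_names: list[str]
    param_names: list[str]

    def coef(self, equation: str, param: str) -> float:
        e = self.equation_names.index(equation)
        p = self.param_names.index(param)
        return float(self.params[e, p])

    def _flat_index(self, equation: str, param: str) -> int:
        e = self.equation_names.index(equation)
        p = self.param_names.index(param)
        return e * len(self.param_names) + p

    def wald_cross_equation(self, param: str,
                            equations: tuple[str, str] | None = None,
                            ) -> tuple[float, float]:
        """Wald chi2 (df=1) for H0: the coefficient of ``param`` is equal
        across the two equations."""
        eqs = equations or tuple(self.equation_names[:2])
        i0 = self._flat_index(eqs[0], param)
        i1 = self._flat_index(eqs[1], param)
        c = np.zeros(self.params.size)
        c[i0], c[i1] = 1.0, -1.0
        delta = float(c @ self.params.reshape(-1))
        var = float(c @ self.cov_params @ c)
        chi2 = delta ** 2 / var
        return chi2, float(stats.chi2.sf(chi2, df=1))

    def wald_table(self, params=None) -> pd.DataFrame:
        params = params or [p for p in self.param_names if p != "const"]
        rows = []
        for p in params:
            chi2, pv = self.wald_cross_equation(p)
            rows.append({"param": p, "chi2": chi2, "p": pv})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Seemingly unrelated regression (Zellner FGLS)", "=" * 46]
        for e, eq in enumerate(self.equation_names):
            lines.append(f"[{eq}]")
            for p, name in enumerate(self.param_names):
                se = np.sqrt(self.cov_params[e * len(self.param_names) + p,
                                             e * len(self.param_names) + p])
                lines.append(f"  {name:>8s}  {self.params[e, p]: .4f}  (se {se:.4f})")
        lines.append("cross-equation Wald tests:")
        for _, row in self.wald_table().iterrows():
            lines.append(f"  {row['param']:>8s}  chi2 = {row['chi2']:.2f}, "
                         f"p = {row['p']:.4g}")
        return "\n".join(lines)


def compare_group_coefficients(y: np.ndarray, X: pd.DataFrame,
                               group: np.ndarray) -> pd.DataFrame:
    """Wald chi2 per predictor for coefficient differences between two
    subject groups (e.g. middle-aged vs older, split at the turning point).

    Implemented as group-interaction OLS: a significant interaction term is
    the large-sample equivalent of the cross-group coefficient contrast.
    """
    group = np.asarray(group).astype(int)
    if set(np.unique(group)) - {0, 1}:
        raise ValueError("group must be binary 0/1")
    X = X.reset_index(drop=True).astype(float)
    cols = {c: X[c].to_numpy() for c in X.columns}
    design = {"const": np.ones(len(X)), "group": group.astype(float)}
    for c in X.columns:
        design[c] = cols[c]
        design[f"{c}:group"] = cols[c] * group
    D = pd.DataFrame(design)
    fit = sm.OLS(np.asarray(y, dtype=float), D).fit()
    rows = []
    for c in X.columns:
        t = fit.tvalues[f"{c}:group"]
        chi2 = float(t ** 2)
        rows.append({"param": c, "chi2": chi2,
                     "p": float(stats.chi2.sf(chi2, df=1))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Shapley R^2 decomposition
# ---------------------------------------------------------------------------

@dataclass
class ShapleyDecomposition:
    shares: pd.Series
    full_r2: float

    def summary(self) -> str:
        lines = ["Shapley R^2 decomposition", "=" * 30]
        for name, v in self.shares.items():
            lines.append(f"  {name:>8s}  {v: .4f}")
        lines.append(f"  {'total':>8s}  {self.full_r2: .4f}")
        return "\n".join(lines)


def _subset_r2(y: np.ndarray, X: np.ndarray, cols: tuple[int, ...],
               cache: dict) -> float:
    if cols in cache:
        return cache[cols]
    if not cols:
        cache[cols] = 0.0
        return 0.0
    Z = np.column_stack([np.ones(len(y)), X[:, list(cols)]])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / tss
    cache[cols] = r2
    return r2


def shapley_r2(y, X: pd.DataFrame) -> ShapleyDecomposition:
    """Exact Shapley-Owen allocation of the regression R² to predictors.

    Enumerates all 2^p predictor subsets (p <= 12) and averages each
    predictor's marginal R² contribution over orderings.  Shares sum to the
    full-model R² by construction.  Collinear predictors are handled by the
    least-squares pseudo-inverse.
    """
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    p = len(names)
    if p > 12:
        raise ValueError("exact Shapley enumeration limited to 12 predictors")
    Xv = X.to_numpy(dtype=float)
    cache: dict = {}
    from math import factorial
    shares = np.zeros(p)
    idx = tuple(range(p))
    for j in range(p):
        others = tuple(i for i in idx if i != j)
        for size in range(p):
            w = factorial(size) * factorial(p - size - 1) / factorial(p)
            for S in combinations(others, size):
                gain = _subset_r2(y, Xv, tuple(sorted(S + (j,))), cache) \
                    - _subset_r2(y, Xv, S, cache)
                shares[j] += w * gain
    full = _subset_r2(y, Xv, idx, cache)
    return ShapleyDecomposition(shares=pd.Series(shares, index=names),
                                full_r2=full)


# ---------------------------------------------------------------------------
# Turning point
# ---------------------------------------------------------------------------

@dataclass
class TurningPoint:
    found: bool
    age: float | None
    slope_change: float | None
    p_value: float
    ci: tuple[float, float] | None
    curve_ages: np.ndarray = field(repr=False)
    curve_values: np.ndarray = field(repr=False)

    def summary(self) -> str:
        if not self.found:
            return f"No turning point detected (slope-change p = {self.p_value:.3g})"
        lo, hi = self.ci
        return (f"Turning point at {self.age:.1f} years "
                f"(bootstrap 95% CI [{lo:.1f}, {hi:.1f}]), "
                f"slope change {self.slope_change:+.3f}/yr, p = {self.p_value:.3g}")


def _best_hinge(age: np.ndarray, y: np.ndarray, grid: np.ndarray):
    """Best continuous two-segment fit: returns (breakpoint, sse, slope_change)."""
    best = (np.nan, np.inf, 0.0)
    ones = np.ones_like(age)
    for c in grid:
        h = np.maximum(age - c, 0.0)
        Z = np.column_stack([ones, age, h])
        beta = np.linalg.solve(Z.T @ Z, Z.T @ y)
        sse = float(((y - Z @ beta) ** 2).sum())
        if sse < best[1]:
            best = (float(c), sse, float(beta[2]))
    return best


def estimate_turning_point(age, y, n_boot: int = 200, seed: int = 0,
                           grid_step: float = 0.25, alpha: float = 0.05,
                           ) -> TurningPoint:
    """Change-point of an age trajectory.

    A penalized regression spline (GCV-like smoothing chosen by the
    underlying GAM machinery) provides the smooth trend; the change point is
    the breakpoint of the best continuous hinge model over a grid spanning
    the inner age range, declared found only when the slope-change term is
    significant (F-test against the single-slope model).  The bootstrap
    percentile interval resamples subjects.
    """
    age = np.asarray(age, dtype=float)
    y = np.asarray(y, dtype=float)
    if age.size < 30:
        raise ValueError("need a reasonably sized sample for a change point")
    lo, hi = np.quantile(age, [0.10, 0.90])
    grid = np.arange(lo, hi + grid_step / 2, grid_step)

    c_hat, sse1, slope_change = _best_hinge(age, y, grid)
    # sup-F statistic of the hinge term vs the plain linear fit; because the
    # breakpoint is chosen to maximise F, significance is calibrated by a
    # residual-permutation null rather than the fixed-breakpoint F reference
    Z0 = np.column_stack([np.ones_like(age), age])
    b0, *_ = np.linalg.lstsq(Z0, y, rcond=None)
    lin_pred = Z0 @ b0
    resid = y - lin_pred
    sse0 = float((resid ** 2).sum())
    df2 = age.size - 3

    def sup_f(yy: np.ndarray) -> tuple[float, float, float]:
        c, sse, _ = _best_hinge(age, yy, grid)
        s0 = float(((yy - Z0 @ np.linalg.lstsq(Z0, yy, rcond=None)[0]) ** 2).sum())
        return (s0 - sse) / max(sse / df2, 1e-300), c, sse

    F_obs = (sse0 - sse1) / max(sse1 / df2, 1e-300)
    rng0 = rng_for(seed, "supf-null")
    n_null = 200
    F_null = np.empty(n_null)
    for b in range(n_null):
        y_null = lin_pred + resid[rng0.permutation(age.size)]
        F_null[b], _, _ = sup_f(y_null)
    p = float((1 + np.sum(F_null >= F_obs - 1e-12)) / (1 + n_null))

    # smooth trend for inspection / plotting
    from statsmodels.gam.api import BSplines, GLMGam
    xs = np.linspace(age.min(), age.max(), 200)
    try:
        bs = BSplines(age[:, None], df=[6], degree=[3])
        gam = GLMGam(y, exog=np.ones((age.size, 1)), smoother=bs,
                     alpha=np.array([1.0])).fit()
        curve = gam.predict(np.ones((xs.size, 1)), exog_smooth=xs[:, None])
    except Exception:  # pragma: no cover - spline failure on degenerate input
        curve = np.interp(xs, np.sort(age), y[np.argsort(age)])

    if p >= alpha:
        return TurningPoint(found=False, age=None, slope_change=None,
                            p_value=p, ci=None, curve_ages=xs,
                            curve_values=np.asarray(curve))

    rng = rng_for(seed, "turning-point")
    boots = np.empty(n_boot)
    n = age.size
    for b in range(n_boot):
        take = rng.integers(0, n, size=n)
        boots[b], _, _ = _best_hinge(age[take], y[take], grid)
    ci = (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))
    return TurningPoint(found=True, age=c_hat, slope_change=slope_change,
                        p_value=p, ci=ci, curve_ages=xs,
                        curve_values=np.asarray(curve))


# ---------------------------------------------------------------------------
# Multiple regression of narrative scores on cognitive domains
# ---------------------------------------------------------------------------

def fit_domain_regressions(cohort: Cohort, response: str,
                           predictors=None, covariates=None) -> pd.DataFrame:
    """OLS of a narrative score on cognitive-domain scores.

    Returns the coefficient table (coef, se, t, p) with optional age/sex
    covariates.
    """
    predictors = list(predictors) if predictors is not None else list(COGNITIVE_DOMAINS)
    y = cohort.score(response)
    X = cohort.phenotype[predictors].astype(float).copy()
    if covariates:
        for c in covariates:
            if c == "sex":
                X["sex"] = (cohort.phenotype["sex"] == "F").astype(float)
            else:
                X[c] = cohort.score(c)
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    return pd.DataFrame({"coef": fit.params, "se": fit.bse,
                         "t": fit.tvalues, "p": fit.pvalues})
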