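"""Structural validation of the narrative-aging FC pattern.

Two complementary checks of whether compensatory regions have a structural
substrate:

* Structural covariance network (SCN) aging: within each age window the
  gray-matter volumes of hub and target nodes are correlated across
  subjects; each hub-target pair's covariance trend over window mean age is
  FDR-screened, and the contrast Ms = mean significant trend among
  compensatory targets minus among declining targets is tested by permuting
  the target labels.  (The contrast-of-means construction of Ms is this
  package's concrete reading of an under-specified statistic.)
* White-matter regression: over hub-target pairs, the (log1p, standardised)
  mean fiber count predicts the pair's FC aging trend with a CV-tuned ridge
  model; performance is the predicted-vs-actual correlation on held-out
  pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import RidgeCV

from ._stats import bh_fdr, columnwise_corr, rng_for
from .aging import age_trend_statistic, make_windows
from .cohort import Cohort

__all__ = ["SCNAnalysis", "SCNResults", "wm_predicts_fc_aging", "WMRegressionResult"]


class SCNAnalysis:
    """Model object: GMV covariance aging trends for hub-target pairs.

    ``target_labels`` maps target node -> {"compensatory", "declining"}.
    """

    def __init__(self, cohort: Cohort, hub_nodes, target_labels: dict[int, str],
                 window_size: int = 30, mode: str = "sliding", step: int = 1,
                 n_perm: int = 500, alpha: float = 0.05, seed: int = 0,
                 pooled_null: bool = True):
        if cohort.gmv is None:
            raise ValueError("cohort has no GMV data")
        self.cohort = cohort
        self.hubs = np.asarray(sorted(set(int(v) for v in hub_nodes)))
        self.target_labels = {int(k): v for k, v in target_labels.items()}
        self.targets = np.asarray(sorted(self.target_labels))
        bad = set(self.target_labels.values()) - {"compensatory", "declining"}
        if bad:
            raise ValueError(f"unknown target labels: {bad}")
        self.window_size = window_size
        self.mode = mode
        self.step = step
        self.n_perm = n_perm
        self.alpha = alpha
        self.seed = seed
        self.pooled_null = pooled_null
        self.pairs = [(int(h), int(t)) for h in self.hubs for t in self.targets
                      if h != t]

    def _pair_window_cov(self, ages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(n_windows, n_pairs) across-subject GMV correlation per window."""
        gmv = self.cohort.gmv
        ws = make_windows(ages, self.window_size, self.mode, self.step)
        hub_pos = {h: k for k, h in enumerate(self.hubs)}
        tgt_pos = {t: k for k, t in enumerate(self.targets)}
        out = np.empty((ws.n_windows, len(self.pairs)))
        for w, members in enumerate(ws.windows):
            n = members.size
            H = gmv[np.ix_(members, self.hubs)]
            T = gmv[np.ix_(members, self.targets)]
            Hs = (H - H.mean(0)) / np.where((sh := H.std(0, ddof=1)) == 0, np.nan, sh)
            Ts = (T - T.mean(0)) / np.where((st := T.std(0, ddof=1)) == 0, np.nan, st)
            C = (Hs.T @ Ts) / (n - 1)
            out[w] = [C[hub_pos[h], tgt_pos[t]] for h, t in self.pairs]
        return out, ws.mean_ages

    def _trends(self, ages: np.ndarray) -> np.ndarray:
        C, ma = self._pair_window_cov(ages)
        return age_trend_statistic(C, ma)

    def fit(self) -> "SCNResults":
        ages = self.cohort.ages
        trend = self._trends(ages)
        rng = rng_for(self.seed, "scn-perm")
        null = np.empty((self.n_perm, trend.size))
        for b in range(self.n_perm):
            null[b] = self._trends(rng.permutation(ages))
        if self.pooled_null:
            pool = np.sort(np.abs(null).ravel())
            rank = np.searchsorted(pool, np.abs(trend) - 1e-12)
            p = (1 + pool.size - rank) / (1 + pool.size)
        else:
            p = (1 + (np.abs(null) >= np.abs(trend)[None] - 1e-12).sum(axis=0)) \
                / (1 + self.n_perm)
        q = bh_fdr(p)

        labels = np.array([self.target_labels[t] for _, t in self.pairs])
        ms, p_ms, null_ms = self._ms_contrast(trend, q, labels)
        return SCNResults(model=self, trend=trend, p=p, q=q, ms=ms, p_ms=p_ms,
                          null_ms=null_ms)

    def _ms_contrast(self, trend, q, labels, n_perm: int | None = None):
        """Ms = mean significant trend (compensatory) - (declining)."""
        sig = q < self.alpha
        ms = _ms_value(trend, sig, labels)
        rng = rng_for(self.seed, "ms-perm")
        n_perm = n_perm or self.n_perm
        null = np.empty(n_perm)
        for b in range(n_perm):
            null[b] = _ms_value(trend, sig, rng.permutation(labels))
        k = int(np.sum(null >= ms - 1e-12))
        return float(ms), float((1 + k) / (1 + n_perm)), null


def _ms_value(trend: np.ndarray, sig: np.ndarray, labels: np.ndarray) -> float:
    comp = sig & (labels == "compensatory")
    decl = sig & (labels == "declining")
    mc = trend[comp].mean() if comp.any() else 0.0
    md = trend[decl].mean() if decl.any() else 0.0
    return float(mc - md)


@dataclass
class SCNResults:
    model: SCNAnalysis = field(repr=False)
    trend: np.ndarray
    p: np.ndarray
    q: np.ndarray
    ms: float
    p_ms: float
    null_ms: np.ndarray = field(repr=False)

    def pair_table(self) -> pd.DataFrame:
        hubs = [h for h, _ in self.model.pairs]
        targets = [t for _, t in self.model.pairs]
        return pd.DataFrame({
            "hub": hubs, "target": targets,
            "target_label": [self.model.target_labels[t] for t in targets],
            "trend_r": self.trend, "p": self.p, "q": self.q,
            "significant": self.q < self.model.alpha,
        })

    def summary(self) -> str:
        return "\n".join([
            "Structural covariance network aging",
            "=" * 40,
            f"hub-target pairs:   {len(self.model.pairs)}",
            f"significant pairs:  {int((self.q < self.model.alpha).sum())}",
            f"Ms contrast:        {self.ms:.3f}",
            f"permutation p:      {self.p_ms:.4g}",
        ])


@dataclass
class WMRegressionResult:
    r: float
    p: float
    alpha_ridge: float
    n_train: int
    n_test: int
    coef: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "alpha_ridge": self.alpha_ridge,
                "n_train": self.n_train, "n_test": self.n_test}


def wm_predicts_fc_aging(cohort: Cohort, hub_nodes, target_nodes,
                         edge_trend: dict[int, float] | pd.DataFrame,
                         test_frac: float = 0.25, n_perm: int = 1000,
                         seed: int = 0) -> WMRegressionResult:
    """Ridge regression of FC aging trends on white-matter fiber counts.

    The unit of analysis is the hub-target edge: predictor = standardised
    log1p mean fiber count, response = that edge's FC age-trend statistic
    (``edge_trend``: mapping edge index -> trend, or an edge_table with
    columns ``edge`` and ``trend_r``).  Fit on a random training split of
    edges; performance is corr(predicted, actual) on the held-out edges with
    a permutation p.
    """
    if cohort.wm is None:
        raise ValueError("cohort has no WM data")
    if isinstance(edge_trend, pd.DataFrame):
        edge_trend = dict(zip(edge_trend["edge"].astype(int),
                              edge_trend["trend_r"].astype(float)))
    from .edges import edges_between
    pairs = edges_between(hub_nodes, target_nodes, cohort.n_nodes)
    pairs = np.array([e for e in pairs if int(e) in edge_trend], dtype=int)
    if pairs.size < 8:
        raise ValueError("too few hub-target edges with an aging trend")
    from .edges import edge_pair
    i, j = edge_pair(pairs, cohort.n_nodes)
    wm_strength = cohort.wm[:, i, j].mean(axis=0)
    if np.all(wm_strength == 0):
        raise ValueError("degenerate input: all-zero WM submatrix")
    x = np.log1p(wm_strength)
    x = (x - x.mean()) / (x.std() if x.std() else 1.0)
    y = np.array([edge_trend[int(e)] for e in pairs])
    y_std = (y - y.mean()) / (y.std() if y.std() else 1.0)

    rng = rng_for(seed, "wm-regression")
    perm = rng.permutation(pairs.size)
    n_test = max(3, int(round(pairs.size * test_frac)))
    test_i, train_i = perm[:n_test], perm[n_test:]
    model = RidgeCV(alphas=np.logspace(-3, 3, 13))
    model.fit(x[train_i, None], y_std[train_i])
    pred = model.predict(x[test_i, None])
    r = float(np.corrcoef(pred, y_std[test_i])[0, 1])
    null = np.array([np.corrcoef(pred, y_std[test_i][rng.permutation(n_test)])[0, 1]
                     for _ in range(n_perm)])
    k = int(np.sum(null >= r - 1e-12))
    return WMRegressionResult(r=r, p=float((1 + k) / (1 + n_perm)),
                              alpha_ridge=float(model.alpha_),
                              n_train=len(train_i), n_test=n_test,
                              coef=np.atleast_1d(model.coef_))
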