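"""Sliding age-window analysis of narrative-FC coupling trends.

Subjects are sorted by age and grouped into windows of 30; within each
window every hub-seeded edge is correlated with the narrative score, and
each edge's *trend* is the correlation of its (Fisher-z) window-wise
coupling with window mean age.  Significance comes from a permutation null
that shuffles subject ages and re-runs the whole window pipeline — the only
scheme that respects the strong dependence created by overlapping windows.
Null trend statistics are pooled across edges (the edges share one window
structure and comparable scales), giving p-value resolution fine enough for
BH-FDR across thousands of edges at modest permutation counts; a per-edge
null remains available.

Edges with FDR q < 0.05 are signed compensatory (positive trend) or
declining (negative); nodes are labelled by majority vote of their
significant incident edges.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import bh_fdr, columnwise_corr, rng_for
from .cohort import Cohort
from .edges import edge_pair, edges_incident

__all__ = ["WindowSeries", "make_windows", "window_edge_correlations",
           "AgingTrendAnalysis", "AgingTrendResults", "age_trend_statistic"]

log = logging.getLogger(__name__)


@dataclass
class WindowSeries:
    """Ordered age windows: subject index arrays and their mean ages."""

    windows: list[np.ndarray]
    mean_ages: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def make_windows(ages: np.ndarray, window_size: int = 30, mode: str = "sliding",
                 step: int = 1, n_bins: int | None = None) -> WindowSeries:
    """Build age windows over the age-sorted subject order.

    modes: ``sliding`` (overlapping, given step), ``disjoint`` (consecutive
    blocks, trailing remainder merged into the last), ``fixed_age_range``
    (equal-width age bins; empty bins dropped).
    """
    ages = np.asarray(ages, dtype=float)
    n = ages.size
    if window_size < 3:
        raise ValueError("window_size must be >= 3")
    if window_size < 10:
        warnings.warn("window_size < 10 gives very noisy window correlations",
                      stacklevel=2)
    if n < window_size:
        raise ValueError(f"cohort of {n} smaller than window_size {window_size}")
    order = np.argsort(ages, kind="stable")
    windows: list[np.ndarray] = []
    if mode == "sliding":
        for start in range(0, n - window_size + 1, step):
            windows.append(order[start:start + window_size])
    elif mode == "disjoint":
        n_full = n // window_size
        for b in range(n_full):
            windows.append(order[b * window_size:(b + 1) * window_size])
        rem = n - n_full * window_size
        if rem and windows:
            windows[-1] = np.concatenate([windows[-1], order[n_full * window_size:]])
    elif mode == "fixed_age_range":
        n_bins = n_bins or max(2, int(np.ceil(n / window_size)))
        edges_ = np.linspace(ages.min(), ages.max(), n_bins + 1)
        which = np.clip(np.digitize(ages, edges_[1:-1]), 0, n_bins - 1)
        for b in range(n_bins):
            members = np.nonzero(which == b)[0]
            if members.size >= 3:
                windows.append(members)
    else:
        raise ValueError(f"unknown window mode {mode!r}")
    mean_ages = np.array([ages[w].mean() for w in windows])
    return WindowSeries(windows=windows, mean_ages=mean_ages)


def window_edge_correlations(cohort: Cohort, ws: WindowSeries, score: str,
                             edge_indices: np.ndarray) -> np.ndarray:
    """(n_windows, n_edges) Pearson r of each edge with the score per window.

    Windows whose score variance vanishes yield NaN rows (counted and
    excluded downstream).
    """
    X = cohort.edge_matrix[:, np.asarray(edge_indices, dtype=int)]
    y = cohort.score(score)
    out = np.empty((ws.n_windows, X.shape[1]))
    n_degenerate = 0
    for w, members in enumerate(ws.windows):
        yy = y[members]
        if np.std(yy) == 0:
            out[w] = np.nan
            n_degenerate += 1
            continue
        out[w] = columnwise_corr(X[members], yy)
    if n_degenerate:
        log.info("window_edge_correlations: %d degenerate-variance windows excluded",
                 n_degenerate)
    return out


def age_trend_statistic(window_corr: np.ndarray, mean_ages: np.ndarray,
                        fisher: bool = True) -> np.ndarray:
    """Per-edge trend: corr of (Fisher-z) window coupling with window mean age."""
    C = np.asarray(window_corr, dtype=float)
    keep = ~np.isnan(C).any(axis=1)
    C, ages = C[keep], np.asarray(mean_ages)[keep]
    if C.shape[0] < 5:
        raise ValueError("need >= 5 usable windows for a trend")
    if fisher:
        C = np.arctanh(np.clip(C, -0.9999, 0.9999))
    return columnwise_corr(C, ages)


class AgingTrendAnalysis:
    """Model object: per-edge narrative-coupling trend across age windows.

    Parameters
    ----------
    cohort : Cohort
    score : narrative score column.
    seed_nodes : hub nodes; the tested edges are all edges incident to them.
    window_size, mode, step : window construction (30-subject sliding
        windows, step 1, by default).
    n_perm : age-shuffling permutations (the full window pipeline is re-run
        per permutation).
    pooled_null : pool null statistics across edges (default) or keep
        per-edge nulls.
    fisher : trend computed on Fisher-z window correlations.
    """

    def __init__(self, cohort: Cohort, score: str, seed_nodes,
                 window_size: int = 30, mode: str = "sliding", step: int = 1,
                 n_perm: int = 1000, alpha: float = 0.05, seed: int = 0,
                 pooled_null: bool = True, fisher: bool = True):
        if n_perm < 100:
            warnings.warn("n_perm < 100 gives unstable permutation p-values",
                          stacklevel=2)
        self.cohort = cohort
        self.score = score
        self.seed_nodes = np.asarray(sorted(set(int(v) for v in seed_nodes)))
        self.window_size = window_size
        self.mode = mode
        self.step = step
        self.n_perm = n_perm
        self.alpha = alpha
        self.seed = seed
        self.pooled_null = pooled_null
        self.fisher = fisher
        self.edge_indices = edges_incident(self.seed_nodes, cohort.n_nodes)

    def _trends(self, ages: np.ndarray) -> np.ndarray:
        ws = make_windows(ages, self.window_size, self.mode, self.step)
        C = window_edge_correlations(self.cohort, ws, self.score, self.edge_indices)
        return age_trend_statistic(C, ws.mean_ages, self.fisher)

    def fit(self) -> "AgingTrendResults":
        ages = self.cohort.ages
        trend = self._trends(ages)
        rng = rng_for(self.seed, "aging-perm", self.score)
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
        sign = np.where(q < self.alpha, np.where(trend > 0, "positive", "negative"), "ns")
        return AgingTrendResults(model=self, trend=trend, p=p, q=q, sign=sign)


@dataclass
class AgingTrendResults:
    model: AgingTrendAnalysis = field(repr=False)
    trend: np.ndarray
    p: np.ndarray
    q: np.ndarray
    sign: np.ndarray

    def edge_table(self) -> pd.DataFrame:
        n_nodes = self.model.cohort.n_nodes
        i, j = edge_pair(self.model.edge_indices, n_nodes)
        return pd.DataFrame({"edge": self.model.edge_indices, "node_i": i,
                             "node_j": j, "trend_r": self.trend, "p": self.p,
                             "q": self.q, "sign": self.sign})

    def region_table(self) -> pd.DataFrame:
        """Node labels by majority vote of significant incident edges."""
        n_nodes = self.model.cohort.n_nodes
        i, j = edge_pair(self.model.edge_indices, n_nodes)
        n_pos = np.zeros(n_nodes, dtype=int)
        n_neg = np.zeros(n_nodes, dtype=int)
        for a, b, s in zip(i, j, self.sign):
            if s == "positive":
                n_pos[a] += 1
                n_pos[b] += 1
            elif s == "negative":
                n_neg[a] += 1
                n_neg[b] += 1
        label = np.where(n_pos > n_neg, "compensatory",
                         np.where(n_neg > n_pos, "declining",
                                  np.where(n_pos > 0, "mixed", "ns")))
        return pd.DataFrame({"node": np.arange(n_nodes), "n_pos": n_pos,
                             "n_neg": n_neg, "label": label})

    def region_nodes(self, label: str, exclude_seeds: bool = True) -> np.ndarray:
        """Nodes carrying a given label (seeds excluded by default)."""
        t = self.region_table()
        nodes = t.loc[t["label"] == label, "node"].to_numpy()
        if exclude_seeds:
            nodes = np.setdiff1d(nodes, self.model.seed_nodes)
        return nodes

    def summary(self) -> str:
        n_sig = int((self.q < self.model.alpha).sum())
        n_pos = int(((self.q < self.model.alpha) & (self.trend > 0)).sum())
        return "\n".join([
            "Sliding age-window narrative-coupling trends",
            "=" * 46,
            f"score:                 {self.model.score}",
            f"edges tested:          {self.trend.size}",
            f"windows:               size {self.model.window_size}, "
            f"mode {self.model.mode}, step {self.model.step}",
            f"significant edges:     {n_sig} (q < {self.model.alpha})",
            f"  compensatory (+):    {n_pos}",
            f"  declining (-):       {n_sig - n_pos}",
        ])
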