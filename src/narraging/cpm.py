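"""Connectome-based predictive modelling (CPM) with permutation-constrained
edge selection and cross-validated edge stability.

The pipeline per phenotype score:

1. Hold out ``test_frac`` of subjects before any selection.
2. Within the training set, run k-fold edge screening: in each fold's
   training portion, correlate every edge with the score and keep edges
   whose two-sided permutation p (shared shuffle set) falls below
   ``alpha_edge``.
3. Edges surviving in at least ``stability_frac`` of folds form the
   *validated* ("contributing") edge set, signed by their training-set
   correlation direction.
4. A subject-level summary feature — the signed sum of validated edge
   values — enters a univariate linear regression fitted on the full
   training set.
5. Generalisation is the Pearson r between predicted and observed scores on
   the held-out subjects, with significance from permutations of the test
   labels.

The screening threshold, fold count and stability rule are this package's
concrete choices (configurable); the edge-stability criterion is one
reading of selecting edges "validated" across resamples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._stats import columnwise_corr, corr_perm_pvalues, perm_pvalue, rng_for
from .cohort import Cohort
from .edges import edge_endpoints, edge_pair

__all__ = ["CPMConfig", "EdgeScreen", "screen_edges",
           "ConnectomePredictiveModel", "CPMResults",
           "train_test_split_indices"]


@dataclass
class CPMConfig:
    n_perm_edge: int = 1000
    alpha_edge: float = 0.01
    cv_folds: int = 10
    stability_frac: float = 0.9
    test_frac: float = 0.1
    n_perm_model: int = 1000
    edge_polarity: str = "both"   # "both" | "positive" | "negative"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_edge < 1:
            raise ValueError("alpha_edge must lie in (0, 1)")
        if not 0 < self.test_frac < 0.5:
            raise ValueError("test_frac must lie in (0, 0.5)")
        if self.edge_polarity not in ("both", "positive", "negative"):
            raise ValueError(f"unknown edge_polarity {self.edge_polarity!r}")


@dataclass
class EdgeScreen:
    """Per-edge screening output: correlation, permutation p, retention."""

    r: np.ndarray
    p: np.ndarray
    selected: np.ndarray          # bool mask over edges
    alpha: float

    @property
    def selected_indices(self) -> np.ndarray:
        return np.nonzero(self.selected)[0]

    @property
    def signs(self) -> np.ndarray:
        """+1/-1 for each selected edge, by correlation direction."""
        return np.sign(self.r[self.selected]).astype(int)


def screen_edges(cohort: Cohort, score: str, cfg: CPMConfig | None = None,
                 subjects: np.ndarray | None = None,
                 rng: np.random.Generator | None = None) -> EdgeScreen:
    """Permutation-thresholded correlation screening of all edges.

    ``subjects`` restricts to a subject subset (used internally by the CV
    folds); the permutation shuffle set is shared across edges.
    """
    cfg = cfg or CPMConfig()
    X = cohort.edge_matrix
    y = cohort.score(score)
    if subjects is not None:
        X, y = X[subjects], y[subjects]
    if len(y) < 20:
        raise ValueError(f"need >= 20 subjects for screening, got {len(y)}")
    if np.std(y) == 0:
        raise ValueError("degenerate input: constant score vector")
    rng = rng or rng_for(cfg.seed, "screen", score)
    r, p = corr_perm_pvalues(X, y, cfg.n_perm_edge, rng)
    selected = p < cfg.alpha_edge
    if cfg.edge_polarity == "positive":
        selected &= r > 0
    elif cfg.edge_polarity == "negative":
        selected &= r < 0
    return EdgeScreen(r=r, p=p, selected=selected, alpha=cfg.alpha_edge)


def train_test_split_indices(n: int, test_frac: float, seed: int,
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic held-out split used by :class:`ConnectomePredictiveModel`."""
    rng = rng_for(seed, "split")
    perm = rng.permutation(n)
    n_test = max(1, int(round(n * test_frac)))
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


class ConnectomePredictiveModel:
    """Predict a phenotype score from FC edges (statsmodels-style model).

    Parameters
    ----------
    cohort : Cohort
    score : phenotype column to predict (e.g. ``"macro_score"``).
    config : CPMConfig, optional.
    """

    def __init__(self, cohort: Cohort, score: str, config: CPMConfig | None = None):
        self.cohort = cohort
        self.score = score
        self.config = config or CPMConfig()

    def fit(self) -> "CPMResults":
        cfg = self.config
        n = self.cohort.n_subjects
        train_idx, test_idx = train_test_split_indices(n, cfg.test_frac, cfg.seed)
        X = self.cohort.edge_matrix
        y = self.cohort.score(self.score)

        # fold-wise screening inside the training set only
        folds = np.array_split(rng_for(cfg.seed, "folds").permutation(train_idx),
                               cfg.cv_folds)
        survive = np.zeros(X.shape[1], dtype=int)
        fold_cfg = replace(cfg)
        for k in range(cfg.cv_folds):
            fold_train = np.sort(np.concatenate([f for j, f in enumerate(folds) if j != k]))
            scr = screen_edges(self.cohort, self.score, fold_cfg, subjects=fold_train,
                               rng=rng_for(cfg.seed, "screen", self.score, k))
            survive += scr.selected
        validated = np.nonzero(survive >= cfg.stability_frac * cfg.cv_folds)[0]

        r_train_edges = columnwise_corr(X[train_idx][:, validated], y[train_idx]) \
            if validated.size else np.empty(0)
        signs = np.sign(r_train_edges).astype(int)

        if validated.size == 0:
            return CPMResults(model=self, selected_edges=validated, edge_signs=signs,
                              edge_r=r_train_edges, coef=np.nan, intercept=np.nan,
                              train_r=np.nan, test_r=np.nan, p_perm=np.nan,
                              train_idx=train_idx, test_idx=test_idx,
                              status="no predictive edges")

        feat = (X[:, validated] * signs).sum(axis=1)
        ft, yt = feat[train_idx], y[train_idx]
        slope, intercept = np.polyfit(ft, yt, 1)
        pred = slope * feat + intercept
        train_r = float(np.corrcoef(pred[train_idx], y[train_idx])[0, 1])
        test_pred, y_test = pred[test_idx], y[test_idx]
        test_r = float(np.corrcoef(test_pred, y_test)[0, 1])

        rng_m = rng_for(cfg.seed, "model-perm", self.score)
        null = np.array([
            np.corrcoef(test_pred, y_test[rng_m.permutation(len(y_test))])[0, 1]
            for _ in range(cfg.n_perm_model)
        ])
        p = perm_pvalue(null, test_r, alternative="greater")
        return CPMResults(model=self, selected_edges=validated, edge_signs=signs,
                          edge_r=r_train_edges, coef=float(slope),
                          intercept=float(intercept), train_r=train_r,
                          test_r=test_r, p_perm=float(p),
                          train_idx=train_idx, test_idx=test_idx, status="ok")


@dataclass
class CPMResults:
    """Fitted CPM: validated edges, summary-feature regression, performance."""

    model: ConnectomePredictiveModel = field(repr=False)
    selected_edges: np.ndarray
    edge_signs: np.ndarray
    edge_r: np.ndarray
    coef: float
    intercept: float
    train_r: float
    test_r: float
    p_perm: float
    train_idx: np.ndarray = field(repr=False)
    test_idx: np.ndarray = field(repr=False)
    status: str = "ok"

    @property
    def n_edges_selected(self) -> int:
        return int(self.selected_edges.size)

    def predict(self, fc_edge_matrix: np.ndarray) -> np.ndarray:
        """Predicted scores for an (n_subjects, n_edges) edge matrix."""
        X = np.asarray(fc_edge_matrix)
        expected = self.model.cohort.edge_matrix.shape[1]
        if X.ndim != 2 or X.shape[1] != expected:
            raise ValueError(f"edge matrix must have {expected} columns, got {X.shape}")
        if self.status != "ok":
            raise ValueError("cannot predict from a model with no predictive edges")
        feat = (X[:, self.selected_edges] * self.edge_signs).sum(axis=1)
        return self.coef * feat + self.intercept

    def edge_table(self) -> pd.DataFrame:
        n_nodes = self.model.cohort.n_nodes
        i, j = edge_pair(self.selected_edges, n_nodes) if self.selected_edges.size \
            else (np.empty(0, int), np.empty(0, int))
        return pd.DataFrame({"edge": self.selected_edges, "node_i": i, "node_j": j,
                             "sign": self.edge_signs, "r_train": self.edge_r})

    def to_dict(self) -> dict:
        return {"score": self.model.score, "status": self.status,
                "n_edges": self.n_edges_selected,
                "edges": self.selected_edges.tolist(),
                "signs": self.edge_signs.tolist(),
                "coef": self.coef, "intercept": self.intercept,
                "train_r": self.train_r, "test_r": self.test_r,
                "p_perm": self.p_perm}

    def summary(self) -> str:
        lines = [
            "Connectome-based predictive model",
            "=" * 45,
            f"score:            {self.model.score}",
            f"status:           {self.status}",
            f"validated edges:  {self.n_edges_selected}",
            f"train r:          {self.train_r:.3f}",
            f"test r:           {self.test_r:.3f}",
            f"permutation p:    {self.p_perm:.4g}",
            f"n train / test:   {len(self.train_idx)} / {len(self.test_idx)}",
        ]
        return "\n".join(lines)
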