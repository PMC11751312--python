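"""PCA functional gradients with Procrustes alignment and group contrasts.

Each subject's FC matrix is embedded into a low-dimensional space by PCA on
its rows (nodes as observations), yielding per-node gradient values ordering
regions along a putative processing hierarchy.  Individual gradients are
aligned to a template (the cohort-mean gradient by default) by orthogonal
Procrustes, and groups are compared node-wise with two-sample t-tests under
BH-FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import orthogonal_procrustes
from sklearn.decomposition import PCA

from ._stats import bh_fdr
from .cohort import Cohort

__all__ = ["fc_gradients", "align_gradients", "compute_gradients",
           "GradientResult", "compare_gradient_groups", "top_third_groups"]


def fc_gradients(fc: np.ndarray, m: int = 2) -> np.ndarray:
    """(n_nodes, m) PCA embedding of one FC matrix's row space."""
    fc = np.asarray(fc, dtype=float)
    n = fc.shape[0]
    if m >= n:
        raise ValueError(f"number of components {m} must be < n_nodes {n}")
    return PCA(n_components=m, svd_solver="full").fit_transform(fc)


def align_gradients(g: np.ndarray, template: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal Procrustes alignment of ``g`` onto ``template``.

    Returns (aligned gradients, rotation matrix).  Aligning a gradient set
    to itself yields the identity transform.
    """
    R, _ = orthogonal_procrustes(g, template)
    return g @ R, R


@dataclass
class GradientResult:
    """Aligned per-subject gradients and the shared template."""

    gradients: np.ndarray = field(repr=False)  # (n_subjects, n_nodes, m)
    template: np.ndarray = field(repr=False)   # (n_nodes, m)
    rotations: np.ndarray = field(repr=False)  # (n_subjects, m, m)

    @property
    def m(self) -> int:
        return self.template.shape[1]


def compute_gradients(fc_stack: np.ndarray, m: int = 2,
                      template: np.ndarray | None = None) -> GradientResult:
    """Per-subject PCA gradients aligned to a common template.

    With no template supplied, the gradient of the subject-mean FC matrix
    serves as the alignment target (all-participant template).
    """
    fc_stack = np.asarray(fc_stack, dtype=float)
    if template is None:
        template = fc_gradients(fc_stack.mean(axis=0), m)
    n_sub, n_nodes = fc_stack.shape[0], fc_stack.shape[1]
    out = np.empty((n_sub, n_nodes, m))
    rots = np.empty((n_sub, m, m))
    for s in range(n_sub):
        g = fc_gradients(fc_stack[s], m)
        out[s], rots[s] = align_gradients(g, template)
    return GradientResult(gradients=out, template=template, rotations=rots)


def compare_gradient_groups(ga: GradientResult, gb: GradientResult,
                            alpha: float = 0.05) -> pd.DataFrame:
    """Node-wise two-sample t-tests on aligned gradients, BH-FDR corrected.

    Requires both groups aligned to the same template.  Returns one row per
    (node, component) with t, p, q, significant.
    """
    if ga.template.shape != gb.template.shape:
        raise ValueError("groups must share one alignment template")
    if ga.gradients.shape[0] < 2 or gb.gradients.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    n_nodes, m = ga.template.shape
    t, p = stats.ttest_ind(ga.gradients, gb.gradients, axis=0)
    q = bh_fdr(p.ravel()).reshape(p.shape)
    rows = []
    for comp in range(m):
        for node in range(n_nodes):
            rows.append({"node": node, "component": comp + 1,
                         "t": float(t[node, comp]), "p": float(p[node, comp]),
                         "q": float(q[node, comp]),
                         "significant": bool(q[node, comp] < alpha)})
    return pd.DataFrame(rows)


def top_third_groups(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    """Top third by macro score vs top third by micro score, overlap removed.

    Returns (macro-group indices, micro-group indices).
    """
    n = cohort.n_subjects
    k = max(2, n // 3)
    macro_top = set(np.argsort(-cohort.score("macro_score"), kind="stable")[:k].tolist())
    micro_top = set(np.argsort(-cohort.score("micro_score"), kind="stable")[:k].tolist())
    both = macro_top & micro_top
    return (np.sort(np.array(sorted(macro_top - both), dtype=int)),
            np.sort(np.array(sorted(micro_top - both), dtype=int)))
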