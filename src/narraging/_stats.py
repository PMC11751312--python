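"""Shared statistical helpers: seeded RNG fan-out, vectorised correlation,
permutation p-values, and BH-FDR."""

from __future__ import annotations

import zlib

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "rng_for",
    "columnwise_corr",
    "corr_perm_pvalues",
    "perm_pvalue",
    "bh_fdr",
    "standardize",
]


def rng_for(seed: int, *tags) -> np.random.Generator:
    """Deterministic per-component RNG derived from one global seed.

    Each analysis stage asks for its own stream by tag so that stages are
    reproducible independently of execution order.
    """
    keys = [zlib.crc32(str(t).encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(keys)))


def standardize(x: np.ndarray, axis: int = 0, ddof: int = 1) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, ddof=ddof, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def columnwise_corr(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of ``X`` (n x p) with ``y`` (n,)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Xc * Xc).sum(axis=0)) * np.sqrt((yc * yc).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / denom
    return r


def corr_perm_pvalues(
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    chunk: int = 64,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided permutation p for corr(column, y), one shared shuffle set.

    Returns (r_obs, p).  p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm).
    Shuffles are drawn sequentially from ``rng`` so the exact null can be
    re-enumerated from the same seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(y) == 0:
        raise ValueError("degenerate input: score vector is constant")
    n = y.shape[0]
    r_obs = columnwise_corr(X, y)
    Xs = standardize(X)
    exceed = np.zeros(X.shape[1], dtype=np.int64)
    abs_obs = np.abs(r_obs)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        P = np.empty((b, n))
        for t in range(b):
            P[t] = y[rng.permutation(n)]
        Ps = standardize(P, axis=1)
        # (b x n) @ (n x p) -> b x p correlations
        R = (Ps @ Xs) / (n - 1)
        exceed += (np.abs(R) >= abs_obs[None, :] - 1e-12).sum(axis=0)
        done += b
    p = (1 + exceed) / (1 + n_perm)
    return r_obs, p


def perm_pvalue(null: np.ndarray, observed: float, alternative: str = "greater") -> float:
    """Permutation p with the +1 correction: p in [1/(B+1), 1]."""
    null = np.asarray(null, dtype=float)
    B = null.size
    if alternative == "greater":
        k = int(np.sum(null >= observed - 1e-12))
    elif alternative == "less":
        k = int(np.sum(null <= observed + 1e-12))
    elif alternative == "two-sided":
        k = int(np.sum(np.abs(null) >= abs(observed) - 1e-12))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (1 + k) / (1 + B)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
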