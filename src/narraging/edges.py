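"""Upper-triangle edge indexing for symmetric connectivity matrices.

A connectome on ``n`` nodes is handled internally as the row-major upper
triangle (i < j, 0-based) flattened to a vector of length n(n-1)/2 — for the
default 236-node parcellation that is 27,730 edges.  All edge-level analyses
operate on these vectors; matrices are only materialised at I/O boundaries.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "n_edges",
    "n_nodes_from_edges",
    "edge_index",
    "edge_pair",
    "edge_endpoints",
    "vectorize",
    "devectorize",
    "edges_incident",
    "edges_between",
]


def n_edges(n_nodes: int) -> int:
    """Number of unordered node pairs (edges) for ``n_nodes`` nodes."""
    if n_nodes < 2:
        raise ValueError(f"need at least 2 nodes, got {n_nodes}")
    return n_nodes * (n_nodes - 1) // 2


def n_nodes_from_edges(m: int) -> int:
    """Invert n(n-1)/2 = m; raise if ``m`` is not a triangular number."""
    n = int((1 + math.isqrt(1 + 8 * m)) // 2)
    if n * (n - 1) // 2 != m:
        raise ValueError(f"{m} is not n(n-1)/2 for any integer n")
    return n


def edge_index(i, j, n_nodes: int):
    """Linear index of edge (i, j), 0-based, requiring i < j < n_nodes.

    Row-major upper-triangle order: (0,1), (0,2), ..., (0,n-1), (1,2), ...
    Accepts scalars or arrays.
    """
    i = np.asarray(i)
    j = np.asarray(j)
    if np.any(i < 0) or np.any(j >= n_nodes) or np.any(i >= j):
        raise IndexError("edge_index requires 0 <= i < j < n_nodes")
    k = i * (2 * n_nodes - i - 1) // 2 + (j - i - 1)
    return int(k) if k.ndim == 0 else k


def edge_pair(k, n_nodes: int):
    """Inverse of :func:`edge_index`: node pair (i, j) of linear index ``k``."""
    k = np.asarray(k)
    m = n_edges(n_nodes)
    if np.any(k < 0) or np.any(k >= m):
        raise IndexError(f"edge index out of range [0, {m})")
    # solve i(2n-i-1)/2 <= k for largest i
    kk = k.astype(np.float64)
    i = np.floor((2 * n_nodes - 1 - np.sqrt((2 * n_nodes - 1) ** 2 - 8 * kk)) / 2)
    i = i.astype(np.int64)
    # guard rounding at block boundaries
    start = i * (2 * n_nodes - i - 1) // 2
    i = np.where(start > k, i - 1, i)
    start = i * (2 * n_nodes - i - 1) // 2
    j = k - start + i + 1
    if k.ndim == 0:
        return int(i), int(j)
    return i, j


def edge_endpoints(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Arrays (rows, cols) of all edge endpoints in linear-index order."""
    return np.triu_indices(n_nodes, k=1)


def vectorize(mat: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Flatten a symmetric matrix to its upper-triangle edge vector."""
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=tol, rtol=0):
        raise ValueError("matrix is not symmetric within tolerance")
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def devectorize(vec: np.ndarray, diag: float = 1.0) -> np.ndarray:
    """Rebuild the symmetric matrix from an edge vector; diagonal set to ``diag``."""
    vec = np.asarray(vec)
    if vec.ndim != 1:
        raise ValueError("edge vector must be 1-D")
    n = n_nodes_from_edges(vec.shape[0])
    mat = np.empty((n, n), dtype=vec.dtype)
    np.fill_diagonal(mat, diag)
    iu = np.triu_indices(n, k=1)
    mat[iu] = vec
    mat[iu[1], iu[0]] = vec
    return mat


def edges_incident(nodes, n_nodes: int) -> np.ndarray:
    """Linear indices of all edges with at least one endpoint in ``nodes``."""
    mask = np.zeros(n_nodes, dtype=bool)
    mask[np.asarray(list(nodes), dtype=int)] = True
    r, c = edge_endpoints(n_nodes)
    return np.nonzero(mask[r] | mask[c])[0]


def edges_between(a, b, n_nodes: int) -> np.ndarray:
    """Linear indices of edges with one endpoint in ``a`` and the other in ``b``.

    An edge entirely inside ``a & b`` counts once.
    """
    ma = np.zeros(n_nodes, dtype=bool)
    mb = np.zeros(n_nodes, dtype=bool)
    ma[np.asarray(list(a), dtype=int)] = True
    mb[np.asarray(list(b), dtype=int)] = True
    r, c = edge_endpoints(n_nodes)
    keep = (ma[r] & mb[c]) | (mb[r] & ma[c])
    return np.nonzero(keep)[0]
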