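"""Graph topology of the contributing-edge network.

The validated ("contributing") edges of a CPM form an undirected weighted
graph; hub nodes are ranked by HITS authority (for a symmetric adjacency
this coincides with principal-eigenvector centrality), communities come from
consensus Louvain clustering, and node-set similarity is the Dice
coefficient with a size-preserving permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from ._stats import perm_pvalue, rng_for
from .edges import edge_pair

__all__ = ["build_graph", "authority_ranking", "HubRanking",
           "louvain_communities", "CommunityAssignment", "dice_overlap"]

log = logging.getLogger(__name__)


def build_graph(edge_indices: np.ndarray, weights: np.ndarray,
                n_nodes: int) -> nx.Graph:
    """Undirected weighted graph over the contributing edges.

    Weights default to the absolute screening statistic; nodes with no
    incident edge are excluded.  Duplicate edge indices are de-duplicated,
    keeping the first occurrence's weight.
    """
    edge_indices = np.asarray(edge_indices, dtype=int)
    if edge_indices.size == 0:
        raise ValueError("empty edge set: cannot build a contributing-edge graph")
    weights = np.abs(np.asarray(weights, dtype=float))
    if weights.shape != edge_indices.shape:
        raise ValueError("weights must align with edge indices")
    _, first = np.unique(edge_indices, return_index=True)
    if first.size < edge_indices.size:
        log.warning("build_graph: %d duplicate edges de-duplicated",
                    edge_indices.size - first.size)
        first = np.sort(first)
        edge_indices, weights = edge_indices[first], weights[first]
    i, j = edge_pair(edge_indices, n_nodes)
    g = nx.Graph()
    g.add_weighted_edges_from(zip(i.tolist(), j.tolist(), weights.tolist()))
    return g


@dataclass
class HubRanking:
    """Authority scores with deterministic ordering (score desc, node asc)."""

    scores: dict[int, float]
    order: list[int] = field(init=False)

    def __post_init__(self) -> None:
        self.order = sorted(self.scores, key=lambda v: (-self.scores[v], v))

    def top(self, k: int) -> list[int]:
        return self.order[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node": self.order,
            "authority": [self.scores[v] for v in self.order],
            "rank": np.arange(1, len(self.order) + 1),
        })


def _component_perron(A: np.ndarray, max_iter: int, tol: float,
                      ) -> tuple[np.ndarray, float]:
    """Perron vector and spectral radius of one connected component's
    adjacency via shifted power iteration."""
    n = A.shape[0]
    shift = float(A.sum(axis=1).max())
    if shift == 0:  # all-zero weights: uniform scores, radius 0
        return np.full(n, 1.0 / np.sqrt(n)), 0.0
    # positive diagonal shift: same eigenvectors, but breaks the +/-lambda
    # periodicity of (near-)bipartite contributing-edge graphs
    As = A + shift * np.eye(n)
    x = np.full(n, 1.0 / np.sqrt(n))
    resid = np.inf
    for _ in range(max_iter):
        y = As @ x
        nu = float(x @ y)
        resid = np.linalg.norm(y - nu * x)
        if resid <= tol * max(abs(nu), 1e-30):
            break
        x = y / np.linalg.norm(y)
    else:
        raise ArithmeticError(
            f"authority scores did not converge in {max_iter} iterations "
            f"(eigen-residual {resid:.2e})")
    x = np.abs(x)
    x /= np.linalg.norm(x)
    return x, float(x @ A @ x)


def authority_ranking(g: nx.Graph, k: int | None = None,
                      max_iter: int = 5000, tol: float = 1e-12) -> HubRanking:
    """HITS authority scores on the weighted adjacency via power iteration.

    For an undirected graph the hub and authority vectors coincide with the
    principal eigenvector of the adjacency.  Power iteration runs within
    each connected component (the only setting with a unique, fast-converging
    Perron vector); components are combined with weights proportional to
    their spectral radius — for a connected graph this is exactly
    eigenvector centrality, and for disconnected graphs it is a
    deterministic regularisation of the degenerate HITS limit.  Scores are
    non-negative and normalised to unit Euclidean norm.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    tol_resid = max(tol, 1e-10)
    scores = np.empty(0)
    all_nodes: list[int] = []
    radii: list[float] = []
    vectors: list[np.ndarray] = []
    comps: list[list[int]] = []
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        A = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
        v, nu = _component_perron(A, max_iter, tol_resid)
        comps.append(nodes)
        vectors.append(v)
        radii.append(nu)
    nu_max = max(radii) if radii else 0.0
    for nodes, v, nu in zip(comps, vectors, radii):
        w = (nu / nu_max) if nu_max > 0 else 1.0
        all_nodes.extend(nodes)
        scores = np.concatenate([scores, w * v])
    scores /= np.linalg.norm(scores)
    ranking = HubRanking({int(v): float(s) for v, s in zip(all_nodes, scores)})
    if k is not None:
        ranking = HubRanking({v: ranking.scores[v] for v in ranking.top(k)})
    return ranking


@dataclass
class CommunityAssignment:
    membership: dict[int, int]          # node -> community id (1-based)
    modularity: float                   # Q of the consensus partition
    mean_run_modularity: float          # mean Q over Louvain runs
    coassignment: np.ndarray = field(repr=False)  # node x node frequency
    nodes: list[int] = field(repr=False, default_factory=list)

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def community(self, cid: int) -> set[int]:
        return {v for v, c in self.membership.items() if c == cid}

    def communities(self) -> list[set[int]]:
        return [self.community(c) for c in sorted(set(self.membership.values()))]

    def main_community(self) -> set[int]:
        return max(self.communities(), key=len)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"node": list(self.membership),
                             "community": list(self.membership.values())})


def louvain_communities(g: nx.Graph, n_runs: int = 100, seed: int = 0,
                        n_communities: int = 4,
                        resolution: float = 1.0) -> CommunityAssignment:
    """Consensus Louvain: repeated runs, Ward clustering of co-assignment.

    Louvain is run ``n_runs`` times with distinct sub-seeds; the fraction of
    runs assigning each node pair to the same community is clustered
    hierarchically (Ward linkage on 1 - frequency) and cut at
    ``n_communities``.  The reported Q is the modularity of the consensus
    partition; the mean run Q is kept for diagnostics.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    nodes = sorted(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    co = np.zeros((n, n))
    qs = []
    for run in range(n_runs):
        sub = int(rng_for(seed, "louvain", run).integers(0, 2**31 - 1))
        parts = nx.community.louvain_communities(
            g, weight="weight", resolution=resolution, seed=sub)
        qs.append(nx.community.modularity(g, parts, weight="weight",
                                          resolution=resolution))
        for comm in parts:
            ii = np.fromiter((idx[v] for v in comm), dtype=int)
            co[np.ix_(ii, ii)] += 1
    co /= n_runs
    n_comm = min(n_communities, n)
    if n == 1:
        labels = np.array([1])
    else:
        dist = 1.0 - co[np.triu_indices(n, k=1)]
        labels = fcluster(linkage(dist, method="ward"), t=n_comm,
                          criterion="maxclust")
    membership = {v: int(c) for v, c in zip(nodes, labels)}
    parts = [ {v for v in nodes if membership[v] == c}
              for c in sorted(set(labels)) ]
    q = nx.community.modularity(g, parts, weight="weight", resolution=resolution)
    return CommunityAssignment(membership=membership, modularity=float(q),
                               mean_run_modularity=float(np.mean(qs)),
                               coassignment=co, nodes=nodes)


def dice_overlap(a, b, universe: int, n_perm: int = 10000,
                 seed: int = 0) -> tuple[float, float]:
    """Dice coefficient 2|A∩B| / (|A|+|B|) with a size-preserving null.

    The null draws random node sets of the observed sizes (without
    replacement) from the ``universe`` nodes; p is the fraction of null Dice
    values >= the observed one (with the +1 correction).
    """
    a, b = set(map(int, a)), set(map(int, b))
    if not a and not b:
        raise ValueError("Dice undefined: both node sets are empty")
    dice = 2 * len(a & b) / (len(a) + len(b))
    rng = rng_for(seed, "dice")
    null = np.empty(n_perm)
    na, nb = len(a), len(b)
    for t in range(n_perm):
        ra = set(rng.choice(universe, size=na, replace=False).tolist())
        rb = set(rng.choice(universe, size=nb, replace=False).tolist())
        null[t] = 2 * len(ra & rb) / (na + nb)
    return float(dice), float(perm_pvalue(null, dice, "greater"))
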