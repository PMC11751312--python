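"""Network enrichment of contributing edges and community membership.

The enrichment fold is the ratio of the observed count inside a target
network (A_i) to the count expected under proportional allocation (E_i).

Edge-level (hub-seeded): for a node (or node set) with selected edges, A_i
counts the selected edges landing in the target network and
E_i = total_selected_edges x network_size / denom, with denom defaulting to
the parcellation size (236 in the reference configuration).  Note the
quirk of that denominator: a node has only n-1 possible partners, yet the
expectation allocates a share of edges to the focal node's own slot, so each
E_i is biased slightly low relative to an allocation over true partners
(the E_i still sum to the A_i total because the network sizes sum to n).
A strict ``denom = n - 1`` option is provided.

Community-level: A_i = |community ∩ network| and
E_i = |community| x |network| / n.  Significance comes from permutations
that preserve the community (or edge-count) size exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._stats import rng_for
from .edges import edge_pair
from .parcellation import NETWORKS, Parcellation

__all__ = ["edge_enrichment", "community_enrichment"]


def _edge_partners(nodes: set[int], edge_indices: np.ndarray, n_nodes: int):
    """For each selected edge incident to ``nodes``: its outside endpoint.

    Edges with both endpoints in ``nodes`` contribute each endpoint once
    (they are within-set edges seen from either side).
    """
    i, j = edge_pair(np.asarray(edge_indices, dtype=int), n_nodes)
    partners, focal = [], []
    for a, b in zip(np.atleast_1d(i), np.atleast_1d(j)):
        ain, bin_ = int(a) in nodes, int(b) in nodes
        if ain and bin_:
            partners.extend([int(b), int(a)])
            focal.extend([int(a), int(b)])
        elif ain:
            partners.append(int(b))
            focal.append(int(a))
        elif bin_:
            partners.append(int(a))
            focal.append(int(b))
    return np.asarray(focal, dtype=int), np.asarray(partners, dtype=int)


def _fold_table(counts: dict[str, int], total: int, sizes: dict[str, int],
                denom: float) -> pd.DataFrame:
    rows = []
    for net in NETWORKS:
        A = counts.get(net, 0)
        E = total * sizes[net] / denom
        rows.append({"network": net, "A": A, "E": E,
                     "fold": A / E if E > 0 else np.nan})
    return pd.DataFrame(rows)


def edge_enrichment(nodes, edge_indices: np.ndarray, parc: Parcellation,
                    denom: int | None = None, n_perm: int = 1000,
                    seed: int = 0) -> pd.DataFrame:
    """Per-network enrichment of the selected edges of a node (set).

    Returns a DataFrame with columns network, A, E, fold, p.  The
    permutation null reassigns each selected edge's outside endpoint
    uniformly over the other nodes, recomputing folds.
    """
    if np.isscalar(nodes):
        nodes = [nodes]
    node_set = set(int(v) for v in np.asarray(list(nodes)).ravel())
    n = parc.n_nodes
    denom = denom if denom is not None else n
    focal, partners = _edge_partners(node_set, edge_indices, n)
    total = partners.size
    if total == 0:
        out = _fold_table({}, 0, {k: parc.network_size(k) for k in NETWORKS}, denom)
        out["fold"] = np.nan
        out["p"] = np.nan
        return out

    labels = parc.network_labels()
    sizes = {k: parc.network_size(k) for k in NETWORKS}
    obs_counts = {net: int(np.sum(labels[partners] == net)) for net in NETWORKS}
    table = _fold_table(obs_counts, total, sizes, denom)

    rng = rng_for(seed, "edge-enrich")
    exceed = np.zeros(len(NETWORKS), dtype=int)
    obs_fold = table["fold"].to_numpy()
    # per-edge candidate partners exclude the focal endpoint
    for _ in range(n_perm):
        rand = rng.integers(0, n - 1, size=total)
        rand = rand + (rand >= focal)  # skip the focal node itself
        perm_counts = np.array([np.sum(labels[rand] == net) for net in NETWORKS])
        with np.errstate(invalid="ignore", divide="ignore"):
            perm_fold = perm_counts / (total * np.array([sizes[k] for k in NETWORKS]) / denom)
        exceed += perm_fold >= obs_fold - 1e-12
    table["p"] = (1 + exceed) / (1 + n_perm)
    return table


def community_enrichment(community, parc: Parcellation, network: str | None = None,
                         n_perm: int = 10000, seed: int = 0) -> pd.DataFrame:
    """Per-network enrichment of community membership.

    A_i = |community ∩ network|, E_i = |community| x |network| / n.  The
    null randomises which nodes carry the community label while keeping the
    community size fixed.
    """
    community = np.asarray(sorted(set(int(v) for v in community)), dtype=int)
    if community.size == 0:
        raise ValueError("empty community")
    n = parc.n_nodes
    labels = parc.network_labels()
    sizes = {k: parc.network_size(k) for k in NETWORKS}
    total = community.size
    obs_counts = {net: int(np.sum(labels[community] == net)) for net in NETWORKS}
    table = _fold_table(obs_counts, total, sizes, n)

    rng = rng_for(seed, "community-enrich")
    obs_fold = table["fold"].to_numpy()
    exceed = np.zeros(len(NETWORKS), dtype=int)
    for _ in range(n_perm):
        draw = rng.choice(n, size=total, replace=False)
        counts = np.array([np.sum(labels[draw] == net) for net in NETWORKS])
        with np.errstate(invalid="ignore", divide="ignore"):
            fold = counts / (total * np.array([sizes[k] for k in NETWORKS]) / n)
        exceed += fold >= obs_fold - 1e-12
    table["p"] = (1 + exceed) / (1 + n_perm)
    if network is not None:
        table = table[table["network"] == network].reset_index(drop=True)
    return table
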