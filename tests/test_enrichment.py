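"""Enrichment folds: printed-formula fidelity and permutation calibration."""

import numpy as np
import pandas as pd
import pytest

from narraging.edges import edge_index
from narraging.enrichment import community_enrichment, edge_enrichment
from narraging.parcellation import Parcellation, default_parcellation



def test_edge_enrichment_hand_worked_case():
    """A node with 6 selected edges, 3 into a 59-node network:
    E = 6 x 59 / 236 = 1.5, fold = 2.0."""
    rows = []
    for nid in range(1, 237):
        net = "DAN" if nid <= 59 else ("DMN" if nid <= 160 else
                                       ("FPN" if nid <= 200 else "VAN"))
        rows.append((nid, f"n{nid}", net, "L"))
    parc = Parcellation(pd.DataFrame(rows, columns=["node_id", "name",
                                                    "network", "hemisphere"]))
    node = 100  # 0-based, in DMN
    partners = [0, 1, 2, 161, 162, 210]  # 3 into DAN, 2 FPN, 1 VAN
    edges = [edge_index(min(node, p), max(node, p), 236) for p in partners]
    res = edge_enrichment(node, np.array(edges), parc, n_perm=50, seed=0)
    res = res.set_index("network")
    assert res.loc["DAN", "A"] == 3
    assert res.loc["DAN", "E"] == pytest.approx(6 * 59 / 236)
    assert res.loc["DAN", "fold"] == pytest.approx(2.0)


def test_edge_enrichment_whole_universe_fold_is_one():
    """If the target network is the whole parcellation the fold is exactly 1."""
    rows = [(i + 1, f"n{i}", "DMN", "L") for i in range(20)]
    # single-network parcellation is rejected upstream only for unknown
    # labels, so build it directly
    parc = Parcellation(pd.DataFrame(rows, columns=["node_id", "name",
                                                    "network", "hemisphere"]))
    edges = [edge_index(0, j, 20) for j in (1, 5, 7)]
    res = edge_enrichment(0, np.array(edges), parc, n_perm=20, seed=0)
    dmn = res.set_index("network").loc["DMN"]
    assert dmn["fold"] == pytest.approx(1.0)


def test_edge_enrichment_zero_edges_undefined():
    parc = default_parcellation(40)
    res = edge_enrichment(3, np.array([], dtype=int), parc, n_perm=10)
    assert res["fold"].isna().all()


def test_edge_enrichment_null_mean_fold_near_one():
    """Endpoints assigned proportionally to network sizes give mean fold ~ 1."""
    parc = default_parcellation(236)
    labels = parc.network_labels()
    rng = np.random.default_rng(12)
    folds = {net: [] for net in parc.networks}
    node = 0
    for _ in range(300):
        partners = rng.choice(np.arange(1, 236), size=10, replace=False)
        edges = np.array([edge_index(0, int(p), 236) for p in partners])
        res = edge_enrichment(node, edges, parc, n_perm=1, seed=1)
        for _, row in res.iterrows():
            folds[row["network"]].append(row["fold"])
    for net in parc.networks:
        assert abs(np.mean(folds[net]) - 1.0) < 0.12


def test_edge_enrichment_count_identity_and_denominator_discrepancy():
    """A sums to the node's selected edges.  Under the default denominator
    (n = 236) E also sums to that total because the network sizes sum to the
    denominator — but part of each expectation is allocated to the focal
    node itself, which has only n-1 = 235 real partners.  The strict
    denominator inflates the E sum by exactly 236/235."""
    parc = default_parcellation(236)
    rng = np.random.default_rng(3)
    partners = rng.choice(np.arange(1, 236), size=12, replace=False)
    edges = np.array([edge_index(0, int(p), 236) for p in partners])
    res_default = edge_enrichment(0, edges, parc, n_perm=1, seed=0)
    assert res_default["A"].sum() == 12
    assert res_default["E"].sum() == pytest.approx(12.0)
    res_strict = edge_enrichment(0, edges, parc, denom=235, n_perm=1, seed=0)
    assert res_strict["E"].sum() == pytest.approx(12 * 236 / 235)


def test_community_enrichment_hand_worked_case():
    """|C|=90, |N|=59, A=20: E = 90 x 59 / 236 = 22.5, fold = 20/22.5."""
    rows = []
    for nid in range(1, 237):
        net = "FPN" if nid <= 59 else "DMN"
        rows.append((nid, f"n{nid}", net, "L"))
    parc = Parcellation(pd.DataFrame(rows, columns=["node_id", "name",
                                                    "network", "hemisphere"]))
    community = list(range(20)) + list(range(59, 129))  # 20 in FPN, 70 out
    res = community_enrichment(community, parc, n_perm=100, seed=0)
    fpn = res.set_index("network").loc["FPN"]
    assert fpn["A"] == 20
    assert fpn["E"] == pytest.approx(90 * 59 / 236)
    assert fpn["fold"] == pytest.approx(20 / 22.5)


def test_community_equal_to_parcellation_fold_one():
    parc = default_parcellation(118)
    res = community_enrichment(range(118), parc, n_perm=20, seed=0)
    assert np.allclose(res["fold"], 1.0)


def test_community_enrichment_p_bounds_and_empty_error():
    parc = default_parcellation(40)
    res = community_enrichment(range(10), parc, n_perm=99, seed=0)
    assert ((res["p"] >= 1 / 100) & (res["p"] <= 1.0)).all()
    with pytest.raises(ValueError, match="empty"):
        community_enrichment([], parc)
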