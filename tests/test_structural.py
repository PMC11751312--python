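"""Structural validation: SCN aging trends, Ms contrast, WM regression."""

import numpy as np
import pytest

from narraging.structural import SCNAnalysis, _ms_value, wm_predicts_fc_aging
from narraging.simulate import SimulationConfig, simulate_cohort


def target_labels(truth):
    labels = {int(v): "compensatory" for v in truth.positive_region_nodes}
    labels.update({int(v): "declining" for v in truth.negative_region_nodes})
    return labels


def test_scn_planted_covariance_trends(recovery_cohort):
    cohort, truth = recovery_cohort
    scn = SCNAnalysis(cohort, truth.hubs_macro, target_labels(truth),
                      n_perm=80, seed=1, step=4).fit()
    t = scn.pair_table()
    comp = t[t["target_label"] == "compensatory"]
    # age-increasing GMV covariance: positive significant trends dominate
    assert ((comp["trend_r"] > 0) & comp["significant"]).mean() > 0.5
    assert scn.ms > 0
    assert scn.p_ms < 0.05


def test_ms_antisymmetric_under_label_swap():
    trend = np.array([0.5, 0.4, -0.3, -0.2])
    sig = np.array([True, True, True, True])
    labels = np.array(["compensatory", "compensatory", "declining", "declining"])
    swapped = np.where(labels == "compensatory", "declining", "compensatory")
    assert _ms_value(trend, sig, labels) == pytest.approx(
        -_ms_value(trend, sig, swapped))


def test_ms_identity_permutation_reproduces_observed():
    trend = np.array([0.6, -0.1, 0.2, -0.4])
    sig = np.array([True, False, True, True])
    labels = np.array(["compensatory", "declining", "compensatory", "declining"])
    assert _ms_value(trend, sig, labels) == _ms_value(trend, sig, labels.copy())


def test_wm_noiseless_linear_map_is_recovered(recovery_cohort):
    """WM strengths constructed as an exact linear map of the trends."""
    cohort, truth = recovery_cohort
    from narraging.edges import edges_between

    targets = np.concatenate([truth.positive_region_nodes,
                              truth.negative_region_nodes])
    pairs = edges_between(truth.hubs_macro, targets, cohort.n_nodes)
    rng = np.random.default_rng(0)
    trend = {int(e): float(v) for e, v in zip(pairs, rng.uniform(-1, 1, pairs.size))}
    import copy
    c = copy.copy(cohort)
    wm = cohort.wm.copy()
    from narraging.edges import edge_pair
    i, j = edge_pair(pairs, cohort.n_nodes)
    exact = np.expm1(2.0 + 1.5 * np.array([trend[int(e)] for e in pairs]))
    wm[:, i, j] = exact[None, :]
    wm[:, j, i] = exact[None, :]
    c.wm = wm
    res = wm_predicts_fc_aging(c, truth.hubs_macro, targets, trend,
                               n_perm=200, seed=1)
    assert res.r > 0.99


def test_wm_coupling_recovery_and_null():
    """Planted wm_coupling>0 yields significant prediction; zero coupling
    is centred at r=0 over replicates."""
    rs_null = []
    for rep in range(8):
        cfg = SimulationConfig(
            n_subjects=60, n_nodes=40, seed=300 + rep,
            n_signal_edges_macro=5, n_signal_edges_micro=5,
            n_compensatory_edges=15, n_declining_edges=15,
            n_hub_nodes=4, n_positive_regions=8, n_negative_regions=8,
            wm_coupling=0.0)
        cohort, truth = simulate_cohort(cfg)
        targets = np.concatenate([truth.positive_region_nodes,
                                  truth.negative_region_nodes])
        trend = {int(e): s for e, s in zip(truth.compensatory_edges,
                                           truth.compensatory_slopes)}
        trend.update({int(e): -s for e, s in zip(truth.declining_edges,
                                                 truth.declining_slopes)})
        res = wm_predicts_fc_aging(cohort, truth.hubs_macro, targets, trend,
                                   n_perm=50, seed=rep)
        rs_null.append(res.r)
    assert abs(np.mean(rs_null)) < 0.25

    cfg = SimulationConfig(
        n_subjects=60, n_nodes=40, seed=77,
        n_signal_edges_macro=5, n_signal_edges_micro=5,
        n_compensatory_edges=15, n_declining_edges=15,
        n_hub_nodes=4, n_positive_regions=8, n_negative_regions=8,
        wm_coupling=2.0)
    cohort, truth = simulate_cohort(cfg)
    targets = np.concatenate([truth.positive_region_nodes,
                              truth.negative_region_nodes])
    trend = {int(e): s for e, s in zip(truth.compensatory_edges,
                                       truth.compensatory_slopes)}
    trend.update({int(e): -s for e, s in zip(truth.declining_edges,
                                             truth.declining_slopes)})
    res = wm_predicts_fc_aging(cohort, truth.hubs_macro, targets, trend,
                               n_perm=300, seed=5)
    assert res.r > 0.5
    assert res.p < 0.05


def test_wm_degenerate_submatrix_raises(recovery_cohort):
    cohort, truth = recovery_cohort
    import copy
    c = copy.copy(cohort)
    c.wm = np.zeros_like(cohort.wm)
    targets = np.concatenate([truth.positive_region_nodes,
                              truth.negative_region_nodes])
    trend = {int(e): 0.5 for e in truth.compensatory_edges}
    trend.update({int(e): -0.5 for e in truth.declining_edges})
    with pytest.raises(ValueError, match="zero WM"):
        wm_predicts_fc_aging(c, truth.hubs_macro, targets, trend)
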