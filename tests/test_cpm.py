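"""CPM: screening calibration, permutation oracle, recovery, no-leak."""

import numpy as np
import pytest
from scipy import stats

from conftest import with_noise_score
from narraging._stats import columnwise_corr, rng_for
from narraging.cpm import (CPMConfig, ConnectomePredictiveModel, screen_edges,
                           train_test_split_indices)


def test_screening_permutation_p_equals_explicit_enumeration(small_cohort):
    """The vectorised permutation p must equal a brute-force per-edge loop
    over the same explicitly enumerated shuffles (same seed, n_perm=200)."""
    cohort, _ = small_cohort
    cfg = CPMConfig(n_perm_edge=200, seed=42)
    scr = screen_edges(cohort, "macro_score", cfg)

    X = cohort.edge_matrix
    y = cohort.score("macro_score")
    rng = rng_for(cfg.seed, "screen", "macro_score")  # same stream
    perms = [rng.permutation(len(y)) for _ in range(200)]
    check_edges = np.arange(0, X.shape[1], 97)
    for e in check_edges:
        r_obs = np.corrcoef(X[:, e], y)[0, 1]
        count = sum(abs(np.corrcoef(X[:, e], y[p])[0, 1]) >= abs(r_obs) - 1e-12
                    for p in perms)
        p_brute = (1 + count) / 201
        assert scr.p[e] == pytest.approx(p_brute, abs=1e-12)
        assert scr.r[e] == pytest.approx(r_obs, abs=1e-12)


def test_null_screening_retains_alpha_fraction(null_cohort):
    cohort, _ = null_cohort
    rng = np.random.default_rng(5)
    fracs = []
    for _ in range(4):
        c = with_noise_score(cohort, rng)
        scr = screen_edges(c, "macro_score",
                           CPMConfig(n_perm_edge=200, alpha_edge=0.05, seed=1))
        fracs.append(scr.selected.mean())
    # edges are mutually correlated, so allow well beyond binomial slack
    assert 0.5 * 0.05 < np.mean(fracs) < 2.0 * 0.05


def test_screening_null_pvalues_uniform(null_cohort):
    """Per-edge permutation p over independent null replicates is uniform."""
    cohort, _ = null_cohort
    X = cohort.edge_matrix[:, :5]
    rng = np.random.default_rng(17)
    ps = []
    from narraging._stats import corr_perm_pvalues
    for _ in range(100):
        y = rng.standard_normal(cohort.n_subjects)
        _, p = corr_perm_pvalues(X, y, 100, rng)
        ps.append(p[0])
    ks = stats.kstest(ps, "uniform")
    assert ks.pvalue > 0.01


def test_constant_score_raises(small_cohort):
    cohort, _ = small_cohort
    c = with_noise_score(cohort, np.random.default_rng(0))
    c.phenotype["macro_score"] = 1.0
    with pytest.raises(ValueError, match="constant"):
        screen_edges(c, "macro_score", CPMConfig(n_perm_edge=50))


def test_planted_recovery_and_performance(recovery_cohort, fast_cpm_config):
    cohort, truth = recovery_cohort
    res = ConnectomePredictiveModel(cohort, "macro_score", fast_cpm_config).fit()
    assert res.status == "ok"
    sel = set(res.selected_edges.tolist())
    recall = np.mean([e in sel for e in truth.signal_edges_macro])
    assert recall >= 0.8
    assert res.test_r > 0.3
    assert res.p_perm < 0.05


def test_predict_self_consistency_and_edge_cases(recovery_cohort, fast_cpm_config):
    cohort, _ = recovery_cohort
    res = ConnectomePredictiveModel(cohort, "macro_score", fast_cpm_config).fit()
    X = cohort.edge_matrix
    pred = res.predict(X)
    r = np.corrcoef(pred[res.train_idx], cohort.score("macro_score")[res.train_idx])[0, 1]
    assert r == pytest.approx(res.train_r, abs=1e-12)
    # all-zero FC -> intercept; duplicated subject -> identical predictions
    z = np.zeros((1, X.shape[1]))
    assert res.predict(z)[0] == pytest.approx(res.intercept)
    two = np.vstack([X[3], X[3]])
    p2 = res.predict(two)
    assert p2[0] == p2[1]
    with pytest.raises(ValueError, match="columns"):
        res.predict(X[:, :10])


def test_null_model_reports_empty_or_null_performance(null_cohort):
    cohort, _ = null_cohort
    c = with_noise_score(cohort, np.random.default_rng(3))
    res = ConnectomePredictiveModel(
        c, "macro_score",
        CPMConfig(n_perm_edge=100, n_perm_model=100, cv_folds=5,
                  stability_frac=0.8, alpha_edge=0.01, seed=2)).fit()
    if res.status == "no predictive edges":
        assert res.n_edges_selected == 0
        assert np.isnan(res.test_r)
    else:
        assert res.p_perm > 0.01  # whatever survives must not look predictive


def test_no_information_leak_from_held_out_subjects(null_cohort):
    """Signal planted only in the held-out subjects must yield null test
    performance: selection and fitting never see the test set."""
    cohort, _ = null_cohort
    cfg = CPMConfig(n_perm_edge=100, n_perm_model=200, cv_folds=5,
                    stability_frac=0.6, alpha_edge=0.2, seed=8)
    rng = np.random.default_rng(21)
    c = with_noise_score(cohort, rng)
    _, test_idx = train_test_split_indices(c.n_subjects, cfg.test_frac, cfg.seed)
    # make the test-set score a deterministic function of test-set edges
    y = c.phenotype["macro_score"].to_numpy()
    y[test_idx] = c.edge_matrix[test_idx, :3].sum(axis=1)
    c.phenotype["macro_score"] = y
    res = ConnectomePredictiveModel(c, "macro_score", cfg).fit()
    if res.status == "ok":
        assert res.p_perm > 0.05


def test_recall_monotone_in_effect_size():
    """Median screening recall never decreases as effect_r grows."""
    from narraging.simulate import SimulationConfig, simulate_cohort

    med = []
    for r_eff in (0.1, 0.3, 0.5):
        recs = []
        for rep in range(5):
            cfg = SimulationConfig(
                n_subjects=200, n_nodes=30, seed=100 + rep, effect_r=r_eff,
                n_signal_edges_macro=20, n_signal_edges_micro=5,
                n_compensatory_edges=0, n_declining_edges=0,
                n_hub_nodes=3, n_positive_regions=3, n_negative_regions=3,
                with_structural=False)
            cohort, truth = simulate_cohort(cfg)
            scr = screen_edges(cohort, "macro_score",
                               CPMConfig(n_perm_edge=100, alpha_edge=0.05, seed=rep))
            recs.append(scr.selected[truth.signal_edges_macro].mean())
        med.append(np.median(recs))
    assert med[0] <= med[1] + 1e-9 <= med[2] + 2e-9
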