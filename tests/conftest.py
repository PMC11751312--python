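"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from narraging.cpm import CPMConfig
from narraging.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Fast cohort for plumbing tests: 120 subjects, 40 nodes, no structural."""
    cfg = SimulationConfig(
        n_subjects=120, n_nodes=40, seed=7,
        n_signal_edges_macro=20, n_signal_edges_micro=20,
        n_compensatory_edges=8, n_declining_edges=8,
        n_hub_nodes=4, n_positive_regions=5, n_negative_regions=5,
        with_structural=False)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def recovery_cohort():
    """Well-powered cohort for recovery tests: 500 subjects, 60 nodes."""
    cfg = SimulationConfig(
        n_subjects=500, n_nodes=60, seed=1,
        n_signal_edges_macro=40, n_signal_edges_micro=40,
        n_compensatory_edges=20, n_declining_edges=20,
        n_hub_nodes=6, n_positive_regions=10, n_negative_regions=10,
        with_structural=True)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort whose scores are later replaced with pure noise for null tests."""
    cfg = SimulationConfig(
        n_subjects=300, n_nodes=40, seed=11,
        n_signal_edges_macro=0, n_signal_edges_micro=0,
        n_compensatory_edges=0, n_declining_edges=0,
        n_hub_nodes=4, n_positive_regions=5, n_negative_regions=5,
        with_structural=False)
    return simulate_cohort(cfg)


@pytest.fixture
def fast_cpm_config():
    return CPMConfig(n_perm_edge=200, n_perm_model=200, cv_folds=5,
                     stability_frac=0.8, seed=0)


def with_noise_score(cohort, rng: np.random.Generator, column="macro_score"):
    """Copy of the cohort with one score replaced by pure noise."""
    import copy

    c2 = copy.copy(cohort)
    ph = cohort.phenotype.copy()
    ph[column] = rng.standard_normal(len(ph))
    c2.phenotype = ph
    return c2
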