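"""Shared fixtures: trained networks at the study conditions.

The expensive ensembles (3 networks, 40 mappings each) are session-scoped
and shared between the measurement tests and the acceptance tests.
"""

import numpy as np
import pytest

import bifmem as bm

R_PARAMS = bm.LearningParams(gamma_learn=16.0, epsilon=0.01)
NR_PARAMS = bm.LearningParams(gamma_learn=1.0, epsilon=0.5)
ENSEMBLE_SEED = 1


@pytest.fixture(scope="session")
def r_one_step_net():
    """One mapping learned at (16, 0.01), N=100: response regime."""
    ms = bm.generate_mapping_set(100, 1, seed=5)
    return bm.learn_sequence(ms, R_PARAMS, 5)


@pytest.fixture(scope="session")
def nr_one_step_net():
    """One mapping learned at (1, 0.5), N=100: non-response regime."""
    ms = bm.generate_mapping_set(100, 1, seed=5)
    return bm.learn_sequence(ms, NR_PARAMS, 5)


@pytest.fixture(scope="session")
def r_ensemble():
    """Three N=100 networks trained on 40 mappings at (16, 0.01)."""
    return bm.train_ensemble(100, 40, R_PARAMS, 3, seed=ENSEMBLE_SEED)


@pytest.fixture(scope="session")
def r_ensemble_capacity(r_ensemble):
    return bm.capacity(r_ensemble)


@pytest.fixture(scope="session")
def r_ensemble_50():
    """Three N=50 networks trained on 40 mappings at (16, 0.01)."""
    return bm.train_ensemble(50, 40, R_PARAMS, 3, seed=ENSEMBLE_SEED)


@pytest.fixture(scope="session")
def nr_ensemble():
    """Three N=100 networks trained on 40 mappings at (1, 0.5)."""
    return bm.train_ensemble(100, 40, NR_PARAMS, 3, seed=ENSEMBLE_SEED)


@pytest.fixture(scope="session")
def small_net():
    """A cheap N=30 network with 5 mappings for interface-level tests."""
    ms = bm.generate_mapping_set(30, 5, seed=11)
    return bm.learn_sequence(ms, R_PARAMS, 11)
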