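"""Shared fixtures: small seeded cohorts and trained pipelines."""

import logging

import pytest
from hypothesis import settings

from aidhs import simulate_cohort, train_aidhs
from aidhs.synthetic import SimulationConfig, make_surface

logging.getLogger("aidhs").setLevel(logging.ERROR)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def surface():
    return make_surface(12, 6, 0.5)


@pytest.fixture(scope="session")
def small_cohort():
    """Four sites, 42 subjects/site: enough for every pipeline stage."""
    cfg = SimulationConfig(seed=7, n_hs_left=10, n_hs_right=10,
                           n_healthy=12, n_disease=10)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def trained(small_cohort):
    """Full training result (features, LOSO predictions, ensemble, charts)."""
    return train_aidhs(small_cohort)
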