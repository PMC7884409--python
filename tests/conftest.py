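"""Shared fixtures.

The expensive bundled simulations (bursting neuron, detonation analog) are
session-scoped so the unit suite and the end-to-end checks share one run.
"""

import numpy as np
import pytest

from eqbalance import DominantBalance, generate_planted_balance
from eqbalance.systems import RDEConfig, bursting_config, simulate_hodgkin_huxley, simulate_rde_analog
from eqbalance.systems.rde import U_EQUATION_TERMS

PLANTED_PATTERNS = [(0, 1), (2, 3), (4, 5)]


@pytest.fixture(scope="session")
def planted_field():
    """3 planted patterns in K = 6, sigma = 0.01, 2000 points/pattern, seed 0."""
    field, truth = generate_planted_balance(
        PLANTED_PATTERNS, points_per_pattern=2000, K=6, noise_sigma=0.01, seed=0
    )
    return field, truth


@pytest.fixture(scope="session")
def planted_fit(planted_field):
    field, _ = planted_field
    return DominantBalance(field, cluster_range=range(1, 9)).fit(seed=0)


@pytest.fixture(scope="session")
def bursting_sim():
    """40 s of the calcium-mediated burster (a few burst cycles)."""
    return simulate_hodgkin_huxley(bursting_config(t_span=(0.0, 40000.0), dt=2.0))


@pytest.fixture(scope="session")
def bursting_fit(bursting_sim):
    esf = bursting_sim.to_equation_space()
    res = DominantBalance(esf, cluster_range=range(1, 9)).fit(seed=0)
    return esf, res


@pytest.fixture(scope="session")
def rde_sim():
    """Two-wave detonation analog run used by several end-to-end checks."""
    cfg = RDEConfig(t_span=(0.0, 150.0), n_snapshots=301)
    return simulate_rde_analog(cfg)


@pytest.fixture(scope="session")
def rde_fit(rde_sim):
    esf = rde_sim.to_equation_space(U_EQUATION_TERMS)
    esf.mask &= esf.coords[:, 1] >= 100.0  # discard the nucleation transient
    res = DominantBalance(esf, cluster_range=range(1, 9)).fit(seed=0)
    return esf, res


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
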