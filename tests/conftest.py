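from __future__ import annotations

import numpy as np
import pytest

from gazecpm.cpm import CPMConfig
from gazecpm.synthetic import StudyConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A small but complete simulated study shared across tests."""
    cfg = StudyConfig(
        n_participants=14,
        n_nodes=16,
        n_volumes=120,
        planted_effect=1.0,
        seed=3,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def toy_cpm_data():
    """n=12 subjects x 15 edges with a signal edge, plus covariates."""
    rng = np.random.default_rng(7)
    n, n_edges = 12, 15
    X = rng.normal(0, 1, (n, n_edges))
    y = X[:, 4] + 0.05 * rng.normal(0, 1, n)
    C = rng.normal(0, 1, (n, 2))
    return X, y, C


@pytest.fixture()
def cpm_config():
    return CPMConfig(n_permutations=50, seed=11)
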