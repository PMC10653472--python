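import numpy as np
import pytest

from multiview_irf.synthetic_data import (
    BooleanRule,
    PlantedFeature,
    SimulationConfig,
    simulate_multiomics,
)


def make_config(**overrides) -> SimulationConfig:
    """A small planted-signal configuration shared across tests."""
    defaults = dict(
        n_samples=200,
        p_gene=40,
        p_protein=20,
        planted_features=(
            PlantedFeature("gene", 0),
            PlantedFeature("gene", 1),
            PlantedFeature("protein", 0),
        ),
        boolean_rule=BooleanRule.parse([["G0000+", "P0000+"], ["G0000-", "G0001+"]]),
        p_signal=0.9,
        p_noise=0.1,
        beta=(0.5, 0.5, 0.5),
        coupled_pairs=((0, 0),),
        cross_view_rho=0.6,
        censor_rate=0.2,
        seed=0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_multiomics(make_config())


@pytest.fixture(scope="session")
def separable_data():
    """Two-feature, perfectly separable binary data."""
    rng = np.random.default_rng(7)
    n = 50
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, 5))
    X[:, 2] = np.where(y == 1, X[:, 2] + 10.0, X[:, 2] - 10.0)
    return X, y
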