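import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mortproj as mp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    return mp.SimulationConfig()


@pytest.fixture(scope="session")
def default_surface(default_config):
    surface, truth = mp.simulate_surface(default_config)
    return surface, truth


@pytest.fixture(scope="session")
def small_surface():
    """A quick 4-age x 12-year surface for cheap fits."""
    cfg = mp.SimulationConfig(
        n_ages=4,
        n_periods=12,
        horizon=5,
        baseline_logit=(-6.0, -5.0, -4.0, -3.0),
        population_base=2e5,
        ageing_rate=0.01,
        seed=11,
    )
    surface, truth = mp.simulate_surface(cfg)
    return cfg, surface, truth


@pytest.fixture(scope="session")
def fitted_bapc(default_surface):
    """One short default-prior fit shared across posterior-level tests."""
    surface, truth = default_surface
    spec = mp.BAPCModelSpec(chains=1, iterations=2000, burnin=800, thin=3, seed=4)
    return mp.fit_bapc(surface, spec), truth
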