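import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from heatrisk.simulate import SimConfig, gen_daily_panel, make_zone_map

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

TINY = dict(n_provinces=3, cities_per_province=2, grid_shape=(20, 24),
            years=(2006,), n_experts=6, n_inconsistent=2)


@pytest.fixture
def tiny_config():
    """A desk-scale configuration: 3 provinces × 2 cities, one season."""
    return SimConfig(seed=7, **TINY)


@pytest.fixture
def tiny_zones(tiny_config):
    return make_zone_map(tiny_config)


@pytest.fixture(scope="session")
def small_panel():
    """One-season panel with known MMTs, shared across read-only tests."""
    config = SimConfig(seed=3, n_provinces=3, cities_per_province=2,
                       grid_shape=(20, 24), years=(2006, 2007))
    panel, truth = gen_daily_panel(config)
    return config, panel, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
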