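import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from trisyn import SimulationConfig, preset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table_cfg() -> SimulationConfig:
    """Published-table defaults with both astrocytic gains off."""
    return SimulationConfig().with_overrides(
        {"astrocyte": {"gamma1": 0.0, "gamma2": 0.0}}
    )


@pytest.fixture(scope="session")
def control_cfg() -> SimulationConfig:
    """Response-curve preset without astrocytic modulation."""
    return preset("fig2")


@pytest.fixture(scope="session")
def astro_cfg() -> SimulationConfig:
    """Response-curve preset with bi-directional astrocytic modulation."""
    return preset("fig5")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
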