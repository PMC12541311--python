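import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cmbdf.features import CmbdfConfig
from cmbdf.grids import GridSet

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cfg3() -> CmbdfConfig:
    """Default published configuration: nu=3, m=4, n=2 (40 features)."""
    return CmbdfConfig()


@pytest.fixture(scope="session")
def cfg4() -> CmbdfConfig:
    """Four-body configuration: nu=4, m=4, n=2 (60 features)."""
    return CmbdfConfig(nu=4)


@pytest.fixture(scope="session")
def grids3(cfg3) -> GridSet:
    return GridSet.build(cfg3)


@pytest.fixture(scope="session")
def grids4(cfg4) -> GridSet:
    return GridSet.build(cfg4)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
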