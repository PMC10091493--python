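import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import slowerx as sx

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def big_pop():
    """Large population: exact and first-order rates agree to ~1e-6."""
    return sx.PopulationModel(N=1_000_000)


@pytest.fixture(scope="session")
def equal_ne_pop():
    """Ne_X forced equal to Ne_A (disentangling scenario)."""
    return sx.PopulationModel(N=1_000_000, Ne_X=1_000_000.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20231)
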