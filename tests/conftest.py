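import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fluidwalls import FluidProperties, default_dumbbell

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def fluids():
    return FluidProperties()


@pytest.fixture
def dumbbell():
    return default_dumbbell()


@pytest.fixture
def rng():
    return np.random.default_rng(20240607)
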