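import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cfglucose import ControlGains, ModelParameters

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """Default kinetic constants."""
    return ModelParameters()


@pytest.fixture(scope="session")
def default_gains() -> ControlGains:
    """The globally recommended gain pair."""
    return ControlGains(d1=0.2, d3=0.1)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
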