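import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rexsim import RelaxationParams, SimConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cfg():
    return SimConfig()


@pytest.fixture(scope="session")
def relax_off():
    return RelaxationParams.disabled()


@pytest.fixture(scope="session")
def relax_default():
    return RelaxationParams()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
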