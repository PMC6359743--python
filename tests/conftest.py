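import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oligorep import ThermoConfig, default_parameters

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def cfg():
    return ThermoConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20190118)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
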