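import pytest
from hypothesis import HealthCheck, settings

from ocudelay import default_parameters

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def defaults():
    """Shipped constants + the five key-diagnosis profiles."""
    return default_parameters()


@pytest.fixture(scope="session")
def constants(defaults):
    return defaults[0]


@pytest.fixture(scope="session")
def profiles(defaults):
    return {p.name: p for p in defaults[1]}
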