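import pytest
from hypothesis import HealthCheck, settings

from ambucea import default_config

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def config():
    """Packaged default configuration (reproduces the published ledger)."""
    return default_config()


@pytest.fixture(scope="session")
def arms(config):
    return config.arms


@pytest.fixture(scope="session")
def params(config):
    return config.econ_params
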