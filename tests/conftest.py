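import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from dbsrecon.simulate import SimulationConfig, generate_anatomy, generate_implants


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def anatomy(default_config):
    return generate_anatomy(default_config)


@pytest.fixture(scope="session")
def implants(default_config, anatomy):
    return generate_implants(default_config, anatomy)
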