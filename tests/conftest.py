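import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from swdscope import GeneratorConfig, generate_session

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_session():
    """One simulated session under the default study conditions."""
    recording, truth = generate_session(GeneratorConfig(seed=0))
    return recording, truth


@pytest.fixture(scope="session")
def small_session():
    """A short, cheap session for I/O and pipeline tests."""
    config = GeneratorConfig(
        seed=11, session_length=60.0, swd_count=3, swd_duration_range=(2.0, 4.0)
    )
    recording, truth = generate_session(config)
    return config, recording, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
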