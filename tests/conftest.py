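import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_config():
    """Generator configuration at 2 kHz for waveform tests."""
    from mepmap.synth import GeneratorConfig

    return GeneratorConfig(sampling_rate=2000.0, seed=7)
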