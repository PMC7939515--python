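import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_mask(rng, shape=(12, 12), p=0.25):
    """Small random binary mask helper shared by oracle tests."""
    return rng.random(shape) < p
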