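import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def sharp_phantom():
    """Noiseless, sharp-edged default phantom: the easy end-to-end case."""
    from torusseg import PhantomSpec, generate_phantom

    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def sharp_segmentation(sharp_phantom):
    """Segmentation of the sharp phantom with default configuration."""
    from torusseg import segment

    return segment(sharp_phantom.image)
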