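import numpy as np
import pytest

from cspine import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_phantom():
    """One phantom at the default (noisy) study conditions."""
    return generate_phantom(PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def quiet_phantom():
    """One noise-free phantom for exact geometric checks."""
    return generate_phantom(
        PhantomSpec(seed=42, gaussian_noise_sigma=0.0, salt_pepper_fraction=0.0)
    )


def rect_mask(shape, rows, cols):
    """Binary uint8 image with a filled axis-aligned rectangle (half-open)."""
    m = np.zeros(shape, dtype=np.uint8)
    m[rows[0] : rows[1], cols[0] : cols[1]] = 255
    return m
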