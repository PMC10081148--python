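import numpy as np
import pytest

import radialmri as rm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """Desk-miniature phantom: 32x32, 6 frames, noiseless by default."""
    return rm.default_spec(grid_size=32, n_frames=6, noise_sigma=0.0)


@pytest.fixture
def small_truth(small_spec):
    return rm.generate_phantom(small_spec)


def disk_image(n: int, radius: float = 0.4, value: float = 1.0) -> np.ndarray:
    """Centered circularly symmetric disk on the unit FOV."""
    ax = (np.arange(n) - n // 2) / (n / 2)
    y, x = np.meshgrid(ax, ax, indexing="ij")
    return (x * x + y * y <= radius * radius) * value


@pytest.fixture
def disk64():
    return disk_image(64)
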