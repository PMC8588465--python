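import numpy as np
import pytest

from snilp import SimulationSpec, make_flat_image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noisy_flat_small():
    """A 96x128 noisy simulated flat-field (f=50 mm, default noise)."""
    spec = SimulationSpec(focal_length_mm=50.0, resolution=(96, 128), seed=7)
    return make_flat_image(spec).pixels


@pytest.fixture
def separable_surface():
    """Positive separable polynomial surface P(col) * Q(row) on a 48x64 grid."""
    rows, cols = np.arange(48), np.arange(64)
    p = 1.0 + 0.01 * cols - 1e-4 * cols**2  # degree 2 in the column coord
    q = 2.0 - 0.005 * rows + 2e-5 * rows**2
    surface = np.outer(q, p)
    assert surface.min() > 0
    return surface
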