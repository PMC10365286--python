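import numpy as np
import pytest

from pulmo3d.io_formats import CTVolume, IntensitySpace


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def hu_volume(rng):
    """A small random HU volume with anisotropic spacing."""
    data = rng.integers(-1200, 600, size=(8, 12, 10)).astype(np.int16)
    return CTVolume(data=data, spacing=(2.0, 1.0, 1.0),
                    origin=(-100.0, -100.0, -100.0),
                    intensity_space=IntensitySpace.HU)


def num_grad(fn, x, eps=1e-3):
    """Central-difference gradient of a scalar function w.r.t. array x."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = fn()
        x[i] = orig - eps
        fm = fn()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g
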