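import numpy as np
import pytest

from microwear import HeightMap


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def rough_surface(rng):
    """Small correlated random surface, zero mean."""
    from scipy import ndimage

    z = ndimage.gaussian_filter(rng.standard_normal((64, 64)), 2.0, mode="wrap")
    z -= z.mean()
    return HeightMap(z, dx=0.5, dy=0.5)


def random_surfaces(n, shape=(48, 48), seed=99):
    """Deterministic batch of correlated random surfaces for property tests."""
    from scipy import ndimage

    out = []
    g = np.random.default_rng(seed)
    for _ in range(n):
        z = ndimage.gaussian_filter(g.standard_normal(shape), 1.5, mode="wrap")
        z -= z.mean()
        out.append(HeightMap(z, dx=0.5, dy=0.5))
    return out
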