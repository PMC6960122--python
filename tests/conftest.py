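import numpy as np
import pytest

from deltarad.textures import VolumeROI


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_volume(rng, max_side=12, min_side=4, p_mask=0.7, n_levels_range=(2, 6)):
    """A small random VolumeROI with a random (connected-ish) mask."""
    shape = tuple(int(rng.integers(min_side, max_side + 1)) for _ in range(3))
    intensities = rng.normal(50.0, 20.0, shape)
    mask = rng.random(shape) < p_mask
    if mask.sum() < 30:  # keep neighborhood statistics well-defined
        idx = rng.choice(np.prod(shape), size=30, replace=False)
        flat = mask.ravel()
        flat[idx] = True
        mask = flat.reshape(shape)
    return VolumeROI(intensities, mask)


@pytest.fixture
def volume_factory(rng):
    def make(**kw):
        return random_volume(rng, **kw)

    return make
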