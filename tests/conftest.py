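import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import hermiteflow as hf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_smooth_volume(shape, seed, smooth=2.0, scale=100.0):
    """Band-limited periodic random field (natural-image-like fixture)."""
    g = np.random.default_rng(seed)
    vol = gaussian_filter(g.standard_normal(shape), smooth, mode="wrap")
    return vol * (scale / vol.std())


@pytest.fixture
def smooth_volume():
    return make_smooth_volume((20, 20, 20), seed=7)


@pytest.fixture
def bank3d():
    return hf.build_filter_bank(4, 5, ndim=3)


@pytest.fixture
def bank2d():
    return hf.build_filter_bank(4, 5, ndim=2)


@pytest.fixture(scope="session")
def default_phantom():
    """The default beating-ellipsoid sequence with its ground truth."""
    spec = hf.PhantomSpec()
    volumes, flows = hf.generate(spec)
    return spec, volumes, flows
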