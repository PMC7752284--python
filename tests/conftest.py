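import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def smooth_random_image():
    """A smooth-ish random test image in [0, 1] shared across oracle tests."""
    from scipy.ndimage import gaussian_filter
    r = np.random.default_rng(99)
    img = gaussian_filter(r.random((24, 24)), 1.0)
    img -= img.min()
    img /= img.max()
    return img
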