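import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def textured_image():
    """Smooth, tapered random texture; a well-behaved registration target."""
    from scipy import ndimage

    gen = np.random.default_rng(3)
    img = ndimage.gaussian_filter(gen.random((192, 192)), 3.0)
    img -= img.mean()
    yy, xx = np.mgrid[:192, :192]
    img *= np.exp(-((yy - 95.5) ** 2 + (xx - 95.5) ** 2) / (2 * 55.0**2))
    return img
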