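import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def asymmetric_image(rng):
    """Small odd-sized image with no symmetry, for rotation/projection
    checks (odd size puts the rotation axis on a pixel centre, so a 90
    degree rotation is an exact grid permutation for the projector)."""
    img = rng.random((25, 25)) * 0.3
    img[4:12, 6:20] += 0.5
    img[15:20, 3:9] += 0.2
    return np.clip(img, 0.0, 1.0)


@pytest.fixture
def disk_image():
    """Bright disk of radius 20 on a black 64x64 background."""
    yy, xx = np.mgrid[0:64, 0:64]
    mask = (yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2
    img = np.zeros((64, 64))
    img[mask] = 0.8
    return img, mask
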