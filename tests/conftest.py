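import numpy as np
import pytest

from wceclean import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scenes():
    """Twelve 64x64 scenes with the well-separated default palettes."""
    return synthetic.generate_scenes(12, height=64, width=64, seed=7)


@pytest.fixture(scope="session")
def fitted_model(small_scenes):
    from wceclean import gbc

    train = small_scenes[:4]
    return gbc.fit([s.image for s in train], [s.mask for s in train])


@pytest.fixture
def checker_image():
    """16x16 frame alternating two constant colors in 4x4 tiles."""
    img = np.zeros((16, 16, 3), dtype=np.uint8)
    tiles = (np.add.outer(np.arange(16) // 4, np.arange(16) // 4) % 2).astype(bool)
    img[tiles] = (200, 120, 110)
    img[~tiles] = (90, 160, 60)
    return img, tiles
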