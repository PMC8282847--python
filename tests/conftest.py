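import numpy as np
import pytest

from emrestore.volume_io import DensityMap


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def gaussian_blob_map():
    """Smooth band-limited map: one broad Gaussian blob at 2 A/voxel."""
    n = 32
    zz, yy, xx = np.mgrid[:n, :n, :n]
    c = (n - 1) / 2
    r2 = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2
    data = np.exp(-r2 / (2 * 4.0**2))
    return DensityMap(data, voxel_size=2.0)


@pytest.fixture
def noise_map(rng):
    return DensityMap(rng.normal(0.0, 1.0, size=(48, 48, 48)), voxel_size=1.0)
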