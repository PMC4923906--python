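import numpy as np
import pytest

from twibio.core_imaging import ScalarVolume


@pytest.fixture
def rng():
    return np.random.default_rng(20160628)


@pytest.fixture
def unit_grid():
    """20³ grid with identity affine (1 mm isotropic voxels)."""
    return ScalarVolume(np.zeros((20, 20, 20)), np.eye(4))
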