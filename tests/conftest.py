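import numpy as np
import pytest

from sinuscore import CTVolume, VOIMask
from sinuscore.phantom import default_phantom_spec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A 64^3 half-filled phantom with exact ground truth (session-cached)."""
    spec = default_phantom_spec(fill_fraction=0.5, grid_shape=(64, 64, 64), seed=11)
    ct, truth = generate_phantom(spec)
    return spec, ct, truth


@pytest.fixture
def uniform_ct():
    """A tiny CT factory: constant-HU block with a full mask."""

    def make(hu, shape=(4, 4, 4), spacing=(1.0, 1.0, 1.0)):
        ct = CTVolume(voxels=np.full(shape, hu, dtype=np.float32), spacing=spacing)
        mask = VOIMask(voxels=np.ones(shape, dtype=bool), spacing=spacing)
        return ct, mask

    return make
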