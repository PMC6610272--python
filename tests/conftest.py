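import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from texsurv.voi import TumourVOI, VoxelVolume, make_voi


def random_voi(rng, max_shape=(5, 5, 5), discrete=False):
    """A random VoxelVolume + TumourVOI on a small grid (mask non-empty)."""
    shape = tuple(int(rng.integers(1, m + 1)) for m in max_shape)
    if discrete:
        grid = rng.integers(0, 7, shape).astype(float)
    else:
        grid = rng.normal(50, 12, shape)
    while True:
        mask = rng.random(shape) < 0.6
        if mask.any():
            break
    volume = VoxelVolume(grid=grid, spacing=(1.0, 1.0, 1.0))
    return volume, make_voi(volume, mask)


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)
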