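import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from radiomap.imaging_io import MaskVolume, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_volume(data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> VolumeGrid:
    return VolumeGrid(data=np.asarray(data, dtype=np.float64), spacing=spacing, origin=origin)


def make_mask(data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> MaskVolume:
    return MaskVolume(data=np.asarray(data).astype(bool), spacing=spacing, origin=origin)


def random_mask(rng, shape, p=0.4) -> np.ndarray:
    m = rng.random(shape) < p
    if not m.any():
        m[tuple(s // 2 for s in shape)] = True
    return m


@pytest.fixture
def small_ct(rng):
    """A 12^3 pseudo-CT with a bright 4^3 block in lung-like noise."""
    data = rng.normal(-800, 50, (12, 12, 12))
    data[4:8, 4:8, 4:8] = rng.normal(0, 30, (4, 4, 4))
    mask = np.zeros((12, 12, 12), dtype=bool)
    mask[4:8, 4:8, 4:8] = True
    return make_volume(data, spacing=(2.0, 2.0, 2.0)), make_mask(mask, spacing=(2.0, 2.0, 2.0))
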