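import numpy as np
import pytest

from lucidmap import (MaskVolume, StatVolume, SynthConfig, Volume3D,
                      default_affine, simulate_group)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def small_affine():
    return default_affine((8, 8, 8))


def make_stat(data, stat_type="Z", df=None, voxel_mm=2.0):
    data = np.asarray(data, dtype=float)
    return StatVolume(Volume3D(data, default_affine(data.shape, voxel_mm)),
                      stat_type=stat_type, df=df)


def full_mask(shape, voxel_mm=2.0):
    return MaskVolume.from_data(np.ones(shape), default_affine(shape, voxel_mm))


@pytest.fixture
def default_group():
    return simulate_group(SynthConfig(seed=7))
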