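import numpy as np
import pytest

from pelviseg.volumes import LabelVolume, PredictionVolume, labels_from_indexmap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_onehot(rng, shape=(8, 8, 8), n_channels=2):
    """A random one-hot label array (X,Y,Z,C)."""
    idx = rng.integers(0, n_channels, size=shape)
    return labels_from_indexmap(idx, n_channels).data


def random_soft(rng, shape=(6, 6, 6), n_channels=4):
    """A random strictly-positive probability field normalised per voxel."""
    q = rng.uniform(0.05, 1.0, size=shape + (n_channels,))
    return q / q.sum(axis=-1, keepdims=True)


def cube_pair_8():
    """The worked example: p a 4x4x4 corner cube, q a 2x4x4 nested cube,
    both as background+1-channel one-hot volumes on an 8x8x8 grid."""
    p = np.zeros((8, 8, 8, 2))
    p[..., 0] = 1
    p[:4, :4, :4, 1] = 1
    p[:4, :4, :4, 0] = 0
    q = np.zeros((8, 8, 8, 2))
    q[..., 0] = 1
    q[:2, :4, :4, 1] = 1
    q[:2, :4, :4, 0] = 0
    return p, q


@pytest.fixture
def nested_cubes():
    return cube_pair_8()
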