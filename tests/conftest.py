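import numpy as np
import pytest

from sliceinform import ModelConfig, Volume3D


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_model_cfg():
    """A configuration small enough to train in well under a second."""
    return ModelConfig(input_size=(16, 16, 3), block_filters=(2, 4, 8),
                      attention_hidden=8, seed=0)


@pytest.fixture()
def random_volume(rng):
    return Volume3D(rng.random((24, 20, 18)), subject_id="rand")


def separable_images(n: int, side: int, rng: np.random.Generator):
    """Bright-top vs dark-top images: a linearly separable toy problem."""
    y = np.tile([0, 1], n // 2 + 1)[:n].astype(float)
    x = rng.normal(0.0, 0.05, size=(n, side, side, 3))
    x[y == 1, : side // 2] += 0.8
    return x, y
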