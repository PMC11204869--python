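import numpy as np
import pytest

from plantsr.image_io import RasterImage, UINT8, UNIT_FLOAT
from plantsr.plantsr_net import PlantSRConfig, build_plantsr
from plantsr.synthetic_data import gen_sr_dataset


@pytest.fixture(scope="session")
def synth_dataset(tmp_path_factory):
    """A small deterministic train/test tree of synthetic plant textures."""
    root = tmp_path_factory.mktemp("synth") / "dataset"
    return gen_sr_dataset(root, n_train=8, n_test=2, size=96, seed=0)


@pytest.fixture(scope="session")
def tiny_plantsr():
    """A small PlantSR ×2 network with seeded weights."""
    return build_plantsr(
        PlantSRConfig(scale=2, channels=16, m=1, n=2, se_reduction=4), seed=0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_uint8_image(rng):
    return RasterImage(rng.integers(0, 256, size=(24, 17, 3), dtype=np.uint8), UINT8)


@pytest.fixture
def random_float_image(rng):
    return RasterImage(rng.random((24, 17, 3)), UNIT_FLOAT)
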