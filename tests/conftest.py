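import numpy as np
import pytest

from laryngoseg.model import ModelConfig
from laryngoseg.synthetic_data import SceneConfig, generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_scene():
    return SceneConfig(image_size=(64, 64), seed=7)


@pytest.fixture(scope="session")
def tiny_model_config():
    return ModelConfig(
        encoder_channels=(4, 6, 8, 12, 16),
        d6_channels=16,
        d7_channels=16,
        residual_units_per_skip=1,
    )


@pytest.fixture(scope="session")
def tiny_manifest(tmp_path_factory, tiny_scene):
    """20 paired 64×64 samples on disk, split 16 train / 4 test."""
    root = tmp_path_factory.mktemp("tinydata")
    return generate_dataset(tiny_scene, 20, (16, 4), root)
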