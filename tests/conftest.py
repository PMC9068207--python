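import numpy as np
import pytest

from trapscope import ImageChannel, SceneParams, generate_scene
from trapscope.config import RunConfig


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def contact_scene():
    """One seeded scene with a 0.5 planted contact fraction."""
    return generate_scene(SceneParams(seed=42, target_contact_fraction=0.5))


@pytest.fixture()
def noise_channel():
    """Pure positive-offset Gaussian noise raster, sigma 1."""
    rng = np.random.default_rng(7)
    pixels = rng.standard_normal((256, 256)) + 50.0
    return ImageChannel(np.clip(pixels, 0, None), pixel_size_um=0.5, label="noise")
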