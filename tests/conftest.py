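import numpy as np
import pytest
from hypothesis import settings

from remikit import SceneConfig, generate_scene

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """Small, fast scene: 3 channels, moderate colocalization, quiet."""
    return SceneConfig(
        image_shape=(96, 96),
        n_sites=200,
        n_domains=12,
        channel_affinities=(0.8, 0.8, 0.8),
        background_site_rate=40,
        noise_sigma=2.0,
        background_amplitude=10.0,
        seed=7,
    )


@pytest.fixture
def small_scene(small_config):
    return generate_scene(small_config)


@pytest.fixture
def quiet_config(small_config):
    """Same field with noise and background switched off."""
    return small_config.replace(noise_sigma=0.0, background_amplitude=0.0)
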