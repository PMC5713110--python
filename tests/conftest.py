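import numpy as np
import pytest

from stemborer_hsi import SceneConfig, generate_scene


@pytest.fixture
def tiny_config():
    """Small scene config for fast unit tests (full 512-band axis kept)."""
    return SceneConfig(image_shape=(24, 24), class_counts=(2, 2, 2, 2, 2, 2), seed=7)


@pytest.fixture
def clean_config():
    """Deterministic scene: no pixel noise, no texture, no per-sample variation."""
    return SceneConfig(
        image_shape=(16, 16),
        class_counts=(1, 1, 1, 1, 1, 1),
        texture_scale=(0.0,) * 6,
        noise_sd=0.0,
        gain_sd=0.0,
        effect_jitter_sd=0.0,
        baseline_sd=0.0,
        seed=3,
    )


@pytest.fixture
def tiny_scene(tiny_config):
    return generate_scene(2, tiny_config, np.random.default_rng(0))
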