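import numpy as np
import pytest

from surgmtl import ModelConfig, SceneConfig, build_model, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    return ModelConfig(
        input_height=32,
        input_width=48,
        base_channels=4,
        depth=2,
        hidden_width=16,
        dropout_p=0.0,
        seed=7,
    )


@pytest.fixture
def small_model(small_config):
    return build_model(small_config)


@pytest.fixture
def tiny_scene_config():
    return SceneConfig(height=64, width=96, seed=5)


@pytest.fixture(scope="session")
def scene_batch():
    """A dozen small scenes shared by read-only tests."""
    config = SceneConfig(height=64, width=96, seed=42)
    rng = np.random.default_rng(42)
    return [generate_scene(config, rng) for _ in range(12)]
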