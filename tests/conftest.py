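import numpy as np
import pytest

from cryopick.model import ParticleTransformer, ModelConfig
from cryopick.synthetic import SceneSpec, simulate_scene

TINY_MODEL_CONFIG = ModelConfig(
    backbone_depth=18, hidden_dim=64, num_queries=20,
    encoder_layers=2, decoder_layers=2, attention_heads=8,
)


@pytest.fixture(scope="session")
def tiny_model() -> ParticleTransformer:
    """Small untrained detector used for contract/plumbing tests."""
    return ParticleTransformer(TINY_MODEL_CONFIG, seed=0)


@pytest.fixture(scope="session")
def small_scene():
    """One 64x64 scene with 5 particles plus its annotations."""
    spec = SceneSpec(image_height=64, image_width=64, particle_count=5,
                     particle_diameter=10.0, min_center_separation=12.0,
                     noise_sigma=0.2, ice_patch_count=0, seed=7)
    return simulate_scene(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
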