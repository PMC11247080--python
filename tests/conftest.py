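import numpy as np
import pytest

from fertiscan import SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_scene():
    """A deterministic noise-free scene shared across imaging tests."""
    return generate_scene(SceneSpec(width=128, height=128, seed=7))
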