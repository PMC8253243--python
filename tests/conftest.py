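import numpy as np
import pytest
from hypothesis import settings

from phenopipe import synthgen

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def small_scene():
    """Factory for quick-to-render thermal scenes used by unit tests."""

    def make(**overrides):
        params = dict(
            frame_size=(160, 200),
            arena_center=(100.0, 80.0),
            arena_radius=60.0,
            body_axes=(15.0, 8.0),
            tail_length=20.0,
            tail_width=3.0,
            duration=2.0,
            frame_rate=2.0,
            noise_sd=0.0,
            seed=7,
        )
        params.update(overrides)
        return synthgen.ThermalSceneConfig(**params)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
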