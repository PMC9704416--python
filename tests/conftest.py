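import numpy as np
import pytest

from ischemap import phantom


@pytest.fixture(scope="session")
def small_scene():
    """A 64x64 ischemic phantom with misalignment, reused across tests."""
    cfg = phantom.PhantomConfig(
        size=(64, 64), n_frames=32, warp_magnitude=4.0,
        lesion=phantom.LesionSpec(radius=10, severity=0.8,
                                  transition_width=4.0),
        seed=42)
    return phantom.generate_scene(cfg)


@pytest.fixture(scope="session")
def aligned_scene():
    """A 64x64 ischemic phantom without misalignment."""
    cfg = phantom.PhantomConfig(
        size=(64, 64), n_frames=32, warp_magnitude=0.0,
        lesion=phantom.LesionSpec(radius=10, severity=0.8,
                                  transition_width=4.0),
        seed=42)
    return phantom.generate_scene(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
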