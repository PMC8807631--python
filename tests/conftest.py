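import numpy as np
import pytest

from socialtrack3d.scene_synthesis import SceneConfig, render_sequence, sample_pose_sequence


@pytest.fixture(scope="session")
def small_scene():
    """A short rendered two-mouse scene shared across test modules."""
    config = SceneConfig(n_frames=150, seed=7)
    seq = sample_pose_sequence(config)
    frames = render_sequence(seq, config)
    return config, seq, frames


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
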