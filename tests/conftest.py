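import numpy as np
import pytest

from surgest.decomposition import DecompositionConfig, FrameSequence
from surgest.synthetic import generate_trial, pt_like_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Reference clip/volume geometry on 32x32 synthetic frames."""
    return DecompositionConfig(width=32, height=32, subsample_factor=1)


@pytest.fixture(scope="session")
def small_trial():
    """One synthetic 32x32 trial with its transcript (session-cached)."""
    spec = pt_like_spec(frame_size=32)
    return generate_trial(spec, seed=99, trial_id="fixture_trial")


def random_sequence(rng, n_frames: int, size: int = 32, trial_id: str = "t0") -> FrameSequence:
    frames = rng.random((n_frames, size, size, 3), dtype=np.float32)
    return FrameSequence(trial_id, "custom", frames)
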