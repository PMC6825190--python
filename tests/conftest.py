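import numpy as np
import pytest

from oralpdt import (
    MotionParams,
    RoiSeed,
    SceneParams,
    render_frames,
    simulate_trajectory,
)


def roi_around(position, side: int = 14, frame_index: int = 0) -> RoiSeed:
    """A tight square ROI centred on a (x, y) marker position."""
    x, y = position
    half = side // 2
    return RoiSeed(rect=(int(round(x)) - half, int(round(y)) - half, side, side),
                   frame_index=frame_index)


def make_video(jitter_sd=2.0, n_frames=20, seed=7, noise_sd=4.0, scene=None,
               **motion_kwargs):
    """Synthetic video plus its ground truth and a marker-centred ROI."""
    motion_kwargs.setdefault("swallow_rate", 0.0)
    motion_kwargs.setdefault("drift_rate", (0.0, 0.0))
    params = MotionParams(jitter_sd=jitter_sd, n_frames=n_frames, seed=seed,
                          **motion_kwargs)
    truth = simulate_trajectory(params)
    scene = scene or SceneParams(color_noise_sd=noise_sd)
    frames = render_frames(truth, scene)
    return frames, truth, roi_around(truth.positions[0])


@pytest.fixture
def small_video():
    """A short, quiet tracking scenario used by several tests."""
    return make_video(jitter_sd=1.0, n_frames=8, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
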