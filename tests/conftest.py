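import warnings

import numpy as np
import pytest

from navgaze.arena import build_arena, random_arena
from navgaze.synth import SynthConfig, generate_session


@pytest.fixture(scope="session")
def arena3():
    """Random connected n=3 arena with 12 obstacles (54 states)."""
    return random_arena(3, 12, seed=7)


@pytest.fixture(scope="session")
def open3():
    """Open n=3 arena, every interior edge passable."""
    return build_arena(3, 2.0)


@pytest.fixture(scope="session")
def maze5():
    """Maze-like n=5 arena (study granularity, 45 obstacles)."""
    return random_arena(5, 45, seed=7)


@pytest.fixture(scope="session")
def synth_session(arena3):
    """Small annotated session on the n=3 arena (all gaze modes active)."""
    cfg = SynthConfig(arena=arena3, n_trials=8, seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        log, trials, truth = generate_session(cfg)
    return log, trials, truth


@pytest.fixture(scope="session")
def sweep_session(maze5):
    """Session with scheduled sweeps on the maze arena (for sweep tests)."""
    mix = {"goal": 0.5, "relevant": 0.0, "alternative": 0.0,
           "random": 0.5, "sweep": 0.0}
    cfg = SynthConfig(arena=maze5, n_trials=25, seed=2, mixture=mix,
                      use_relevance_targets=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        log, trials, truth = generate_session(cfg)
    return log, trials, truth


def trial_gaze(log, truth_trial, gaze_valid_only=True):
    """Gaze array of one trial plus the raw->valid frame index map."""
    fr = log.frames.iloc[
        truth_trial.frame0: truth_trial.frame0 + truth_trial.n_frames
    ]
    valid = fr["gaze_valid"].to_numpy()
    gaze = fr[["gaze_x", "gaze_y"]].to_numpy()
    if gaze_valid_only:
        gaze = gaze[valid]
    idx_map = np.cumsum(valid) - 1
    return gaze, idx_map
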