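import numpy as np
import pytest

from remapkit import SimConfig, analyze_session, generate_population, generate_session
from remapkit.behavior import BeelineTrial, PositionTrace
from remapkit.tuning import ActivityRaster


def make_trials(speeds_lr=(), speeds_rl=(), frames_per_trial=10):
    """Synthetic trial lists with prescribed mean speeds (frames are dummies)."""
    trials = []
    pos = 0
    for s in speeds_lr:
        trials.append(BeelineTrial(pos, pos + frames_per_trial - 1, "LR", s))
        pos += frames_per_trial
    for s in speeds_rl:
        trials.append(BeelineTrial(pos, pos + frames_per_trial - 1, "RL", s))
        pos += frames_per_trial
    return trials


def staircase_trace(n_trials=2, n_bins=23, frame_rate=11.0, track_length=250.0):
    """Trace visiting every bin center once per trial, in order."""
    from remapkit.behavior import bin_centers

    x = np.tile(bin_centers(n_bins, track_length), n_trials)
    t = np.arange(x.size) / frame_rate
    return PositionTrace(t=t, x=x, frame_rate=frame_rate, track_length=track_length)


def staircase_trials(n_trials=2, n_bins=23):
    return [
        BeelineTrial(k * n_bins, (k + 1) * n_bins - 1, "LR", 50.0) for k in range(n_trials)
    ]


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_cells=60, n_trials_per_direction=12, untuned_fraction=0.4, seed=42)


@pytest.fixture(scope="session")
def small_population(small_config):
    return generate_population(small_config)


@pytest.fixture(scope="session")
def small_session(small_population, small_config):
    return generate_session(small_population, small_config, session_seed=1)


@pytest.fixture(scope="session")
def small_analysis(small_session):
    return analyze_session(small_session, seed=0, n_splits=100)
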