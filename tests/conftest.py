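"""Shared fixtures: small synthetic sessions reused across the suite.

Sessions are generated at reduced sampling rates and trial counts so the
whole suite stays fast; the generator's scientific defaults (task timing,
noise levels, volley morphology) are untouched.
"""

import numpy as np
import pytest

from padpipe import SimConfig, analyze_session, generate_session

#: Reduced problem-size rates used throughout the tests.
REDUCED = dict(neurogram_rate=20_000.0, emg_rate=2_000.0, torque_rate=500.0)

#: The gain pattern exercised in the recovery tests: suppressed volleys in
#: the active-movement epoch of extension, facilitated throughout flexion.
GAIN_PATTERN = {("extension", "AM"): 0.8,
                ("flexion", "Delay"): 1.2, ("flexion", "AM"): 1.2,
                ("flexion", "AH"): 1.2, ("flexion", "PM"): 1.2}


def make_config(**overrides) -> SimConfig:
    kw = dict(n_trials_per_direction=8, **REDUCED)
    kw.update(overrides)
    return SimConfig(**kw)


@pytest.fixture(scope="session")
def gain_session():
    """One session with the reference gain pattern and realistic noise."""
    return generate_session(make_config(epoch_gain=dict(GAIN_PATTERN)),
                            seed=11)


@pytest.fixture(scope="session")
def gain_analysis(gain_session):
    return analyze_session(gain_session, conduction_distance_m=0.13)


@pytest.fixture(scope="session")
def clean_session():
    """Noise-free kinematics with every outcome class injected."""
    cfg = make_config(n_trials_per_direction=10,
                      torque_noise_sd=0.0,
                      error_proportions={"no_movement": 0.2,
                                         "wrong_direction": 0.2,
                                         "short_hold": 0.2})
    return generate_session(cfg, seed=7)


@pytest.fixture(scope="session")
def spiking_session():
    """Session with a driven interneuron for the peristimulus analysis."""
    cfg = make_config(n_trials_per_direction=10,
                      response_prob={"Rest": 0.3, "Delay": 0.3, "AM": 0.8,
                                     "AH": 0.3, "PM": 0.3})
    return generate_session(cfg, seed=23)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
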