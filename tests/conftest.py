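"""Shared fixtures: small synthetic sessions generated at test time."""

import logging
import warnings

import numpy as np
import pytest

from gaitmep import gait_events as ge
from gaitmep import synthetic as syn

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def short_config() -> syn.SessionConfig:
    """A 70-second session: enough strides for every analysis stage."""
    return syn.default_config(trial_duration=70.0)


@pytest.fixture(scope="session")
def steady_kinematics(short_config):
    markers, truth, pert = syn.generate_gait_kinematics(short_config, "steady", seed=11)
    return markers, truth, pert


@pytest.fixture(scope="session")
def destabilised_kinematics(short_config):
    markers, truth, pert = syn.generate_gait_kinematics(
        short_config, "destabilised", seed=11
    )
    return markers, truth, pert


@pytest.fixture(scope="session")
def true_events(steady_kinematics) -> ge.GaitEvents:
    _, truth, _ = steady_kinematics
    return ge.GaitEvents(truth.hs_left, truth.hs_right, truth.to_left, truth.to_right)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def noise_free_emg_session():
    """Noise- and artifact-free session for closed-loop MEP recovery."""
    cfg = syn.default_config(
        trial_duration=60.0, emg_noise=0.0, mep_amplitude_jitter=0.0,
        artifact_amplitude=0.0,
    )
    markers, truth, pert = syn.generate_gait_kinematics(cfg, "steady", seed=7)
    emg, stim_times, stim_truth = syn.generate_emg_with_meps(cfg, "steady", truth, seed=7)
    return cfg, truth, emg, stim_times, stim_truth
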