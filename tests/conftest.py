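"""Shared fixtures: synthetic experiments at full and desk scale.

Session-scoped so expensive artifacts (62 waveforms, their embeddings) are
built once per run.
"""

import numpy as np
import pytest

import soundease as se
from soundease.pipeline import embed_stimuli

SEED = 11


@pytest.fixture(scope="session")
def full_design():
    return se.ExperimentDesign()


@pytest.fixture(scope="session")
def full_stimuli(full_design):
    return se.generate_stimuli(full_design, seed=SEED, keep_audio=True)


@pytest.fixture(scope="session")
def full_participants(full_design):
    return se.generate_participants(full_design, seed=SEED)


@pytest.fixture(scope="session")
def full_embeddings(full_stimuli):
    return embed_stimuli(full_stimuli)


@pytest.fixture(scope="session")
def noiseless_trials(full_stimuli, full_participants, full_design):
    response = se.ResponseModel(noise_sd=0.0)
    return se.generate_trials(full_stimuli, full_participants, response, SEED, full_design)


@pytest.fixture(scope="session")
def default_trials(full_stimuli, full_participants, full_design):
    return se.generate_trials(
        full_stimuli, full_participants, se.ResponseModel(), SEED, full_design
    )


@pytest.fixture(scope="session")
def tiny_design():
    """Deliberately scaled-down layout for cheap end-to-end checks."""
    return se.ExperimentDesign(
        n_dd=2,
        n_td=2,
        n_training=4,
        n_training_reserve=2,
        n_test=2,
        n_test_reserve=2,
        n_repeats=1,
        missing_participant=None,
    )


@pytest.fixture(scope="session")
def tone_20s():
    fs = 44_100
    t = np.arange(fs * 20) / fs
    return se.AudioBuffer(0.3 * np.sin(2 * np.pi * 440.0 * t), fs)


@pytest.fixture()
def short_tone():
    fs = 44_100
    t = np.arange(fs * 2) / fs
    return se.AudioBuffer(0.3 * np.sin(2 * np.pi * 440.0 * t), fs)
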