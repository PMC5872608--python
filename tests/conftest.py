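import numpy as np
import pytest

import semgkit as sk


@pytest.fixture(scope="session")
def profiles():
    return sk.default_profiles()


@pytest.fixture(scope="session")
def short_session(profiles):
    """A 2-repetition hand-open session (50 s) with its ground truth."""
    return sk.generate_session(profiles["hand_open"], n_reps=2, seed=7)


@pytest.fixture(scope="session")
def fes_trial(profiles):
    """A default 30 Hz power-grasp FES trial (60 s) with its ground truth."""
    return sk.generate_fes_trial(profiles["power_grasp"], sk.StimulusSpec(), seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tone(freq_hz, amplitude_mv=1.0, duration_s=10.0, fs=250.0, n_channels=1):
    """Single-frequency test record."""
    t = np.arange(round(duration_s * fs)) / fs
    x = amplitude_mv * np.sin(2 * np.pi * freq_hz * t)
    return sk.SignalRecord(data=np.tile(x, (n_channels, 1)), fs=fs)


@pytest.fixture
def make_tone():
    return tone
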