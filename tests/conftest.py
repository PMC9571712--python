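import numpy as np
import pandas as pd
import pytest

from neurofuse.datatypes import Recording
from neurofuse.simulate import SimConfig, generate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """Two participants, one session of one set, minimal montages."""
    return SimConfig(
        n_participants=2, n_sessions=1, n_sets_per_session=1,
        eeg_channels=["Fp1", "Fp2", "AFz", "POz", "O1", "O2"],
        fnirs_channels=["AF8", "AFpz", "PPOz"],
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_session(tiny_config):
    """(eeg, hbo, hbr, events) for the first participant of tiny_config."""
    return generate_session(tiny_config, 0, 0)


def make_events(onsets, labels, duration=40.0, participant=0, session=0):
    """Minimal hand-built event table for segmentation tests."""
    return pd.DataFrame({
        "participant": participant,
        "session": session,
        "series": range(len(onsets)),
        "label": labels,
        "onset_s": onsets,
        "duration_s": duration,
    })


def make_recording(data, rate=200.0, modality="eeg"):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return Recording(data, rate, modality,
                     [f"ch{i}" for i in range(data.shape[0])])
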