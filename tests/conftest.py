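import logging

import numpy as np
import pytest

from specexp.montage import LABELS_1020
from specexp.recording import EEGRecording
from specexp.synth import default_channel_specs, simulate_recording

logging.getLogger("specexp").setLevel(logging.ERROR)

FS = 256.0


@pytest.fixture(scope="session")
def clean_recording():
    """19-channel, 200 s, chi=-1.12 everywhere, alpha peaks, no artifacts."""
    rec, truth = simulate_recording(
        default_channel_specs(chi=-1.12), None, duration_s=200.0, fs=FS, seed=42)
    return rec, truth


@pytest.fixture(scope="session")
def flat_recording():
    """Short peak-free recording for cheap filter tests."""
    rec, _ = simulate_recording(
        default_channel_specs(chi=-1.0, alpha_peak=False), None,
        duration_s=30.0, fs=FS, seed=3)
    return rec


@pytest.fixture()
def white_recording():
    rng = np.random.default_rng(11)
    data = rng.standard_normal((19, int(60 * FS))) * 10
    return EEGRecording(data=data, fs=FS, labels=LABELS_1020)
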