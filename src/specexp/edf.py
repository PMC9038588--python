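"""EDF (European Data Format) input/output for EEG recordings.

Reading goes through MNE's EDF reader and normalizes channel labels to the
classic 10-20 names. Writing uses a minimal self-contained EDF encoder
(16-bit samples, physical dimension µV, 1-second data records) so simulated
cohorts travel through exactly the same file path as clinical recordings.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

from .montage import normalize_label
from .recording import EEGRecording


class SamplingRateError(ValueError):
    """Raised when an EDF's sampling rate differs from the one required."""


def read_edf(path: str | Path, expected_fs: float | None = None) -> EEGRecording:
    """Load a continuous EDF/EDF+ file as an :class:`EEGRecording` in µV.

    Channel labels such as ``"EEG Fp1-REF"`` are normalized to 10-20 names.
    If ``expected_fs`` is given and the file's rate differs, the file is
    refused with :class:`SamplingRateError` — no silent resampling.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    if expected_fs is not None and abs(fs - expected_fs) > 1e-6:
        raise SamplingRateError(
            f"{path}: sampling rate {fs} Hz, expected {expected_fs} Hz; "
            "resample explicitly before analysis"
        )
    labels = tuple(normalize_label(ch) for ch in raw.ch_names)
    data_uv = raw.get_data() * 1e6  # MNE holds EEG in volts
    return EEGRecording(data=data_uv, fs=fs, labels=labels)


def write_edf(recording: EEGRecording, path: str | Path) -> None:
    """Write a recording to EDF with 16-bit samples and µV physical dimension.

    Uses 1-second data records, so ``fs`` must be a whole number of samples
    per second; the trailing partial second, if any, is zero-padded.
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per record per channel
    nch = recording.n_channels
    n = recording.n_samples
    n_records = int(np.ceil(n / spr))

    data = np.zeros((nch, n_records * spr))
    data[:, :n] = recording.data

    # per-channel physical range, padded so the signal never clips
    pmin = np.floor(np.minimum(data.min(axis=1), -1.0))
    pmax = np.ceil(np.maximum(data.max(axis=1), 1.0))
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(
        np.rint((data - pmin[:, None]) * scale[:, None]) + dmin, dmin, dmax
    ).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF field too long: {text!r}")
        return b.ljust(width)

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),  # patient
            pad("Startdate X X X X", 80),  # recording
            pad(now.strftime("%d.%m.%y"), 8),
            pad(now.strftime("%H.%M.%S"), 8),
            pad(str(256 + 256 * nch), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),  # record duration, seconds
            pad(str(nch), 4),
        ]
    )
    fields: list[bytes] = []
    for width, values in [
        (16, [f"EEG {lab}" for lab in recording.labels]),
        (80, ["" for _ in range(nch)]),  # transducer
        (8, ["uV" for _ in range(nch)]),
        (8, [f"{v:g}"[:8] for v in pmin]),
        (8, [f"{v:g}"[:8] for v in pmax]),
        (8, [str(dmin) for _ in range(nch)]),
        (8, [str(dmax) for _ in range(nch)]),
        (80, ["" for _ in range(nch)]),  # prefiltering
        (8, [str(spr) for _ in range(nch)]),
        (32, ["" for _ in range(nch)]),  # reserved
    ]:
        fields.extend(pad(v, width) for v in values)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"".join(fields))
        # records are channel-blocked: ch0 samples, ch1 samples, ...
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())
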