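"""In-memory container for multichannel EEG with montage labels and annotations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import POSITIONS_1020


@dataclass(frozen=True)
class Annotation:
    """One marked event: ``channel`` is a 10-20 label or ``"all"``."""

    channel: str
    start_s: float
    end_s: float
    kind: str

    def __post_init__(self) -> None:
        if self.end_s < self.start_s:
            raise ValueError(f"annotation ends before it starts: {self}")


@dataclass
class EEGRecording:
    """Channels x samples EEG in microvolts.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    fs : float
        Sampling rate in Hz.
    labels : tuple of str
        10-20 channel names, unique, aligned with rows of ``data``.
    positions : dict
        Schematic 2-D montage coordinates per label.
    annotations : list of Annotation
        Known or detected events.
    reference : str
        ``"as-recorded"`` or ``"average"``.
    history : list of str
        Names of processing stages already applied, in order.
    """

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]
    positions: dict[str, tuple[float, float]] = field(default_factory=dict)
    annotations: list[Annotation] = field(default_factory=list)
    reference: str = "as-recorded"
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = tuple(self.labels)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels/data channel count mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.positions:
            self.positions = {
                lab: POSITIONS_1020[lab] for lab in self.labels if lab in POSITIONS_1020
            }
        dur = self.duration_s
        for a in self.annotations:
            if a.start_s < 0 or a.end_s > dur + 1e-9:
                raise ValueError(f"annotation outside record: {a}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D signal of one channel (a view)."""
        try:
            return self.data[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"no channel {label!r}") from None

    def copy_with(self, **changes) -> "EEGRecording":
        """Shallow-configured copy; ``data`` is copied, lists are re-created."""
        kwargs = dict(
            data=self.data.copy(),
            fs=self.fs,
            labels=self.labels,
            positions=dict(self.positions),
            annotations=list(self.annotations),
            reference=self.reference,
            history=list(self.history),
        )
        kwargs.update(changes)
        return EEGRecording(**kwargs)
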