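"""Artifact-cleaning chain from raw multichannel EEG to analysis-ready
segments.

Stage order is fixed — detrend, bad-channel handling, 0.5 Hz high-pass,
mains notch, BSS-CCA muscle removal, average reference, ICA-based ocular
rejection, residual-segment rejection — because later stages assume the
earlier ones (e.g. CCA autocorrelations are meaningless on drifting data,
and the ocular surrogate assumes filtered, referenced signals). The
:class:`PreprocessingPipeline` wrapper enforces that order; the stage
functions themselves are pure primitives usable in isolation.

Filters are applied forward-backward (zero phase): phase distortion of the
slow components would leak into the low-frequency end of the spectral-
exponent fit. The effective magnitude response is therefore the squared
design response.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import signal as sps

from .montage import ADJACENCY_1020
from .recording import EEGRecording

logger = logging.getLogger(__name__)


@dataclass
class QualityReport:
    """Outcome of the recording-level quality gate.

    A recording passes when at most one channel is bad (the single bad
    channel is interpolated) and at least 180 s of artifact-free signal
    remain for spectral estimation.
    """

    bad_channels: list[str]
    clean_seconds: float
    passed: bool = field(init=False)
    reasons: list[str] = field(init=False)

    MAX_BAD: int = 1
    MIN_CLEAN_S: float = 180.0

    def __post_init__(self) -> None:
        self.reasons = []
        if self.n_bad > self.MAX_BAD:
            self.reasons.append("bad_channels")
        if self.clean_seconds < self.MIN_CLEAN_S:
            self.reasons.append("insufficient_clean_data")
        self.passed = not self.reasons

    @property
    def n_bad(self) -> int:
        return len(self.bad_channels)

    def to_dict(self) -> dict:
        return {"bad_channels": list(self.bad_channels), "n_bad": self.n_bad,
                "clean_seconds": self.clean_seconds, "passed": self.passed,
                "reasons": list(self.reasons)}


class PipelineStateError(RuntimeError):
    """Raised when pipeline stages are invoked out of their fixed order."""


# ---------------------------------------------------------------------------
# stage primitives


def detrend(recording: EEGRecording) -> EEGRecording:
    """Subtract the per-channel best-fit straight line over the full record."""
    if recording.n_samples < 2:
        raise ValueError("need at least 2 samples to detrend")
    out = recording.copy_with()
    out.data = sps.detrend(out.data, axis=1, type="linear")
    out.history.append("detrend")
    return out


def _robust_z(values: np.ndarray, floor: float) -> np.ndarray:
    """Deviation from the median over a floored MAD scale.

    With only 19 channels the MAD occasionally collapses by chance and
    ordinary channels would score |z| > 3; conversely any scale estimate
    that includes gross outliers masks a *pair* of bad channels. The floor —
    a physiological minimum spread below which cross-channel differences are
    ordinary topography — solves both: it cannot collapse and cannot be
    inflated, so a genuinely deviant channel scores in the tens while
    structured but healthy variation stays in single digits.
    """
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    return (values - med) / max(1.4826 * mad, floor)


# Scale floors: the spread a healthy-to-pathological recording can show
# across channels (hemispheric steepening in severe stroke reaches ~1.3
# decades of log-variance and ~2.3 Fisher units of lag-1 autocorrelation)
# must score below threshold, while a faulty channel (20x gain error = 2.6
# decades) must score above it.
LOGVAR_FLOOR = 0.5  # decades of log10 variance
AC1_FLOOR = 0.8  # Fisher-z units of lag-1 autocorrelation


def detect_bad_channels(recording: EEGRecording, z_threshold: float = 3.0
                        ) -> list[str]:
    """Flag outlier channels by robust z-scores of log-variance and
    Fisher-transformed lag-1 autocorrelation across channels (median/MAD
    with a physiological scale floor; see :func:`_robust_z`).

    The Fisher transform (atanh) decompresses the autocorrelation scale near
    1, where physiological channels cluster. A flat (dead) channel is
    categorically bad and flagged regardless of the scores.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    if recording.n_channels < 4:
        raise ValueError("bad-channel z-scores need at least 4 channels")
    x = recording.data
    var = x.var(axis=1)
    flat = var < 1e-24
    logvar = np.where(flat, -50.0, np.log10(np.maximum(var, 1e-50)))
    xc = x - x.mean(axis=1, keepdims=True)
    denom = np.sum(xc**2, axis=1)
    num = np.sum(xc[:, 1:] * xc[:, :-1], axis=1)
    ac1 = np.where(denom > 0, num / np.maximum(denom, 1e-30), 0.0)
    ac1_fisher = np.arctanh(np.clip(ac1, -1 + 1e-12, 1 - 1e-12))
    z_var = _robust_z(logvar[~flat], LOGVAR_FLOOR) if (~flat).any() else None
    z_ac = _robust_z(ac1_fisher[~flat], AC1_FLOOR) if (~flat).any() else None
    bad = flat.copy()
    if z_var is not None:
        over = (np.abs(z_var) > z_threshold) | (np.abs(z_ac) > z_threshold)
        bad[~flat] |= over
    return [lab for lab, b in zip(recording.labels, bad) if b]


def interpolate_channel(recording: EEGRecording, label: str) -> EEGRecording:
    """Replace one channel by the unweighted mean of its montage neighbours."""
    if label not in recording.labels:
        raise ValueError(f"unknown channel {label!r}")
    neighbours = [n for n in ADJACENCY_1020.get(label, ())
                  if n in recording.labels]
    if not neighbours:
        raise ValueError(f"no montage neighbours available for {label!r}")
    out = recording.copy_with()
    idx = out.labels.index(label)
    nidx = [out.labels.index(n) for n in neighbours]
    out.data[idx] = out.data[nidx].mean(axis=0)
    out.history.append(f"interpolate:{label}")
    return out


def highpass(recording: EEGRecording, cutoff: float = 0.5, order: int = 5
             ) -> EEGRecording:
    """Zero-phase Butterworth high-pass (default 5th order, 0.5 Hz)."""
    if not 0 < cutoff < recording.fs / 2:
        raise ValueError("cutoff must lie in (0, fs/2)")
    sos = sps.butter(order, cutoff, btype="highpass", fs=recording.fs,
                     output="sos")
    out = recording.copy_with()
    out.data = sps.sosfiltfilt(sos, out.data, axis=1)
    out.history.append("highpass")
    return out


def notch(recording: EEGRecording, center: float = 50.0, bandwidth: float = 2.0
          ) -> EEGRecording:
    """Zero-phase IIR notch for mains interference (center configurable)."""
    if not 0 < center < recording.fs / 2:
        raise ValueError("notch center must lie in (0, fs/2)")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    b, a = sps.iirnotch(center, center / bandwidth, fs=recording.fs)
    out = recording.copy_with()
    out.data = sps.filtfilt(b, a, out.data, axis=1)
    out.history.append("notch")
    return out


def _cca_window(X: np.ndarray, delay: int, ridge: float
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """BSS-CCA of a window against its delayed copy.

    Returns (sources, mixing, autocorrs): canonical components ordered from
    most to least autocorrelated; the canonical correlations equal the
    components' lag-``delay`` autocorrelations.
    """
    A = X[:, :-delay]
    B = X[:, delay:]
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    n = A.shape[1]
    Caa = A @ A.T / n
    Cbb = B @ B.T / n
    Cab = A @ B.T / n
    lam = ridge * np.trace(Caa) / Caa.shape[0]
    Caa_r = Caa + lam * np.eye(Caa.shape[0])
    Cbb_r = Cbb + lam * np.eye(Cbb.shape[0])
    La = sla.cholesky(Caa_r, lower=True)
    Lb = sla.cholesky(Cbb_r, lower=True)
    M = sla.solve_triangular(La, Cab, lower=True)
    M = sla.solve_triangular(Lb, M.T, lower=True).T
    U, svals, _ = sla.svd(M)
    W = sla.solve_triangular(La.T, U, lower=False)  # canonical weights, X side
    Xc = X - X.mean(axis=1, keepdims=True)
    S = W.T @ Xc
    mixing = np.linalg.pinv(W.T)
    return S, mixing, svals


def cca_muscle_removal(recording: EEGRecording, window_s: float = 10.0,
                       delay_samples: int = 1,
                       autocorr_threshold: float = 0.7,
                       ridge: float = 1e-6) -> EEGRecording:
    """Blind-source-separation CCA muscle-artifact removal.

    Per consecutive window, the canonical correlation problem between the
    windowed signal and its ``delay_samples``-shifted copy yields components
    ordered by autocorrelation; broadband muscle activity is nearly white, so
    components with autocorrelation below ``autocorr_threshold`` are zeroed
    and the window rebuilt from the rest. A trailing partial window is
    processed if at least 2 s long, else passed through. Rank-deficient
    windows are handled by ridge-regularized whitening (warning logged).
    """
    if not 0 <= autocorr_threshold < 1:
        raise ValueError("autocorr_threshold must lie in [0, 1)")
    win = int(round(window_s * recording.fs))
    if win <= recording.n_channels:
        raise ValueError("window too short for the channel count")
    out = recording.copy_with()
    n = out.n_samples
    start = 0
    while start < n:
        stop = min(start + win, n)
        if stop - start < 2 * recording.fs and start > 0:
            break  # short tail (< 2 s): passed through untouched
        X = out.data[:, start:stop]
        mean = X.mean(axis=1, keepdims=True)
        try:
            S, mixing, rho = _cca_window(X, delay_samples, ridge)
        except sla.LinAlgError:
            logger.warning("CCA window %d-%d rank-deficient; raising ridge",
                           start, stop)
            S, mixing, rho = _cca_window(X, delay_samples, ridge * 1e4)
        keep = rho >= autocorr_threshold
        if autocorr_threshold == 0:
            keep[:] = True
        if not keep.all():
            S = S.copy()
            S[~keep] = 0.0
            out.data[:, start:stop] = mixing @ S + mean
        start += win
    out.history.append("cca_muscle_removal")
    return out


def average_reference(recording: EEGRecording) -> EEGRecording:
    """Re-reference to the instantaneous channel mean (channel-sum becomes 0)."""
    if recording.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    out = recording.copy_with()
    out.data = out.data - out.data.mean(axis=0, keepdims=True)
    out.reference = "average"
    out.history.append("average_reference")
    return out


def remove_ocular(recording: EEGRecording,
                  frontal_labels: tuple[str, ...] = ("Fp1", "Fp2"),
                  corr_threshold: float = 0.7,
                  random_state: int = 0,
                  max_components: int | None = None) -> EEGRecording:
    """Remove ICA components correlated with an ocular surrogate.

    The surrogate is the mean of the frontal channels low-passed at 5 Hz —
    blink and eye-movement energy lives there. FastICA components whose
    absolute correlation with the surrogate exceeds ``corr_threshold`` are
    zeroed (count logged). If ICA does not converge, the surrogate is
    regressed out of every channel instead (warning logged).
    """
    for lab in frontal_labels:
        if lab not in recording.labels:
            raise ValueError(f"frontal label {lab!r} not present")
    out = recording.copy_with()
    if corr_threshold >= 1.0:
        out.history.append("remove_ocular")
        return out  # nothing can exceed the threshold

    frontal = np.mean([out.channel(lab) for lab in frontal_labels], axis=0)
    sos = sps.butter(4, 5.0, btype="lowpass", fs=out.fs, output="sos")
    surrogate = sps.sosfiltfilt(sos, frontal)

    from sklearn.decomposition import FastICA

    from sklearn.exceptions import ConvergenceWarning

    # average-referenced data has rank n_channels - 1; cap the ICA dimension
    # at the numerical rank or whitening degenerates
    cov = np.cov(out.data)
    eig = np.linalg.eigvalsh(cov)
    rank = int(np.sum(eig > eig.max() * 1e-10))
    n_comp = min(max_components or out.n_channels, rank)
    converged = True
    # A non-converged FastICA is still a valid orthogonal unmixing of the
    # whitened data (reconstruction stays exact); only numerical failure
    # triggers the regression fallback. Near-Gaussian background activity
    # routinely leaves ICA formally unconverged while the strongly
    # non-Gaussian blink component is isolated within the first iterations.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        try:
            ica = FastICA(n_components=n_comp, random_state=random_state,
                          max_iter=200, tol=1e-3, whiten="unit-variance")
            sources = ica.fit_transform(out.data.T)  # samples x comps
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("FastICA failed (%s); falling back to "
                           "surrogate regression", exc)
            converged = False
    if converged:
        s_c = surrogate - surrogate.mean()
        removed = 0
        for k in range(sources.shape[1]):
            comp = sources[:, k] - sources[:, k].mean()
            denom = np.linalg.norm(comp) * np.linalg.norm(s_c)
            r = comp @ s_c / denom if denom > 0 else 0.0
            if abs(r) > corr_threshold:
                sources[:, k] = 0.0
                removed += 1
        logger.info("ocular ICA: removed %d component(s)", removed)
        recon = ica.inverse_transform(sources).T
        out.data = recon
        out.history.append(f"remove_ocular:n={removed}")
        return out
    else:
        s_c = surrogate - surrogate.mean()
        ss = s_c @ s_c
        if ss > 0:
            beta = (out.data - out.data.mean(axis=1, keepdims=True)) @ s_c / ss
            out.data = out.data - beta[:, None] * s_c[None, :]
    out.history.append("remove_ocular")
    return out


def reject_artifact_segments(recording: EEGRecording,
                             amp_threshold: float = 150.0,
                             jump_threshold: float = 50.0
                             ) -> tuple[list[tuple[int, int]], float]:
    """Scan 1-second windows for residual high-amplitude or step artifacts.

    A window is flagged when any channel exceeds ``amp_threshold`` µV
    absolute amplitude or ``jump_threshold`` µV/sample absolute first
    difference. Returns the unflagged runs as (start_sample, stop_sample)
    pairs plus the total clean duration in seconds. Infinite thresholds
    return the whole record as one segment.
    """
    if amp_threshold <= 0 or jump_threshold <= 0:
        raise ValueError("thresholds must be positive")
    fs = int(round(recording.fs))
    n = recording.n_samples
    n_win = n // fs
    flagged = np.zeros(n_win, dtype=bool)
    diffs = np.abs(np.diff(recording.data, axis=1))
    for w in range(n_win):
        sl = slice(w * fs, (w + 1) * fs)
        if np.any(np.abs(recording.data[:, sl]) > amp_threshold):
            flagged[w] = True
            continue
        dsl = slice(max(w * fs - 1, 0), (w + 1) * fs - 1)
        if np.any(diffs[:, dsl] > jump_threshold):
            flagged[w] = True
    segments: list[tuple[int, int]] = []
    w = 0
    while w < n_win:
        if flagged[w]:
            w += 1
            continue
        w0 = w
        while w < n_win and not flagged[w]:
            w += 1
        stop = w * fs if w < n_win else n  # keep the sub-second tail
        segments.append((w0 * fs, stop))
    clean_seconds = sum(stop - start for start, stop in segments) / recording.fs
    return segments, clean_seconds


def extract_segments(recording: EEGRecording,
                     segments: list[tuple[int, int]]) -> list[np.ndarray]:
    """Materialize clean (channels x samples) arrays from segment bounds."""
    return [recording.data[:, a:b].copy() for a, b in segments]


def quality_gate(bad_channels: list[str], clean_seconds: float
                 ) -> QualityReport:
    """Apply the recording-level inclusion rule (≤1 bad channel, ≥180 s clean)."""
    return QualityReport(bad_channels=list(bad_channels),
                         clean_seconds=float(clean_seconds))


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class PreprocessingParams:
    """Tunable knobs of the cleaning chain with reproducible defaults."""

    bad_channel_z: float = 3.0
    highpass_cutoff: float = 0.5
    highpass_order: int = 5
    notch_center: float = 50.0
    notch_bandwidth: float = 2.0
    cca_window_s: float = 10.0
    cca_delay_samples: int = 1
    cca_autocorr_threshold: float = 0.7
    ocular_corr_threshold: float = 0.7
    ica_random_state: int = 0
    amp_threshold: float = 150.0
    jump_threshold: float = 50.0


STAGE_ORDER = (
    "detrend", "bad_channels", "highpass", "notch", "cca", "average_reference",
    "remove_ocular", "reject_segments",
)


@dataclass
class PreprocessResult:
    recording: EEGRecording
    report: QualityReport
    segments: list[tuple[int, int]]


class PreprocessingPipeline:
    """Runs the cleaning stages in their fixed order, refusing to skip ahead.

    Use :meth:`run` for the full chain, or call :meth:`run_stage` repeatedly;
    invoking a stage before its predecessors raises
    :class:`PipelineStateError`.
    """

    def __init__(self, params: PreprocessingParams | None = None):
        self.params = params or PreprocessingParams()
        self._done: list[str] = []
        self.bad_channels: list[str] = []
        self.segments: list[tuple[int, int]] = []
        self.clean_seconds: float = 0.0

    def _check_order(self, stage: str) -> None:
        pos = STAGE_ORDER.index(stage)
        expected = list(STAGE_ORDER[:pos])
        if self._done != expected:
            raise PipelineStateError(
                f"stage {stage!r} requires prior stages {expected}, "
                f"but completed stages are {self._done}")

    def run_stage(self, stage: str, recording: EEGRecording) -> EEGRecording:
        self._check_order(stage)
        p = self.params
        if stage == "detrend":
            recording = detrend(recording)
        elif stage == "bad_channels":
            self.bad_channels = detect_bad_channels(recording, p.bad_channel_z)
            if len(self.bad_channels) == 1:
                recording = interpolate_channel(recording, self.bad_channels[0])
            elif len(self.bad_channels) > 1:
                logger.warning("%d bad channels (%s): recording will fail "
                               "the quality gate; none interpolated",
                               len(self.bad_channels), self.bad_channels)
        elif stage == "highpass":
            recording = highpass(recording, p.highpass_cutoff, p.highpass_order)
        elif stage == "notch":
            recording = notch(recording, p.notch_center, p.notch_bandwidth)
        elif stage == "cca":
            recording = cca_muscle_removal(
                recording, p.cca_window_s, p.cca_delay_samples,
                p.cca_autocorr_threshold)
        elif stage == "average_reference":
            recording = average_reference(recording)
        elif stage == "remove_ocular":
            recording = remove_ocular(
                recording, corr_threshold=p.ocular_corr_threshold,
                random_state=p.ica_random_state)
        elif stage == "reject_segments":
            self.segments, self.clean_seconds = reject_artifact_segments(
                recording, p.amp_threshold, p.jump_threshold)
        else:
            raise ValueError(f"unknown stage {stage!r}")
        self._done.append(stage)
        return recording

    def run(self, recording: EEGRecording) -> PreprocessResult:
        rec = recording
        for stage in STAGE_ORDER:
            rec = self.run_stage(stage, rec)
        report = quality_gate(self.bad_channels, self.clean_seconds)
        return PreprocessResult(recording=rec, report=report,
                                segments=list(self.segments))


def preprocess_recording(recording: EEGRecording,
                         params: PreprocessingParams | None = None
                         ) -> PreprocessResult:
    """One-call full cleaning chain; see :class:`PreprocessingPipeline`."""
    return PreprocessingPipeline(params).run(recording)
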