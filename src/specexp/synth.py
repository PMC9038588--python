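"""Synthetic EEG with known ground truth: colored-noise channels, oscillatory
peaks, stereotyped artifacts, and full longitudinal stroke cohorts.

The aperiodic background is synthesized in the frequency domain: white Gaussian
spectral amplitudes are shaped by f^(χ/2) and inverse-transformed with random
phases, so the expected one-sided PSD is exactly ``scale * f**chi`` (µV²/Hz)
and the target exponent χ is the ground truth against which downstream
estimators are judged.

Cohort-level defaults encode an eyes-closed resting-state stroke study:
healthy controls around χ ≈ −1.12, patients steeper over the affected
hemisphere acutely (≈ −1.55 affected vs −1.40 unaffected) with partial
renormalization two months later (≈ −1.34 / −1.30), NIHSS impairment scores
with an acute median near 5, and effective recovery statistically coupled to
the acute affected-hemisphere exponent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .montage import LABELS_1020, OCULAR_WEIGHTS, POSTERIOR, hemisphere_sets
from .recording import Annotation, EEGRecording
from .stats import SubjectRecord, effective_recovery

RngLike = "np.random.Generator | int"


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class SimChannelSpec:
    """Ground-truth description of one simulated channel.

    ``exponent_chi`` is the slope of log10-power vs log10-frequency
    (typically −2..0); ``aperiodic_scale`` is the PSD at 1 Hz in µV²/Hz;
    ``peaks`` lists (center Hz, bandwidth Hz, peak PSD height µV²/Hz).
    """

    label: str
    exponent_chi: float
    aperiodic_scale: float = 20.0
    peaks: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if not math.isfinite(self.exponent_chi):
            raise ValueError("exponent_chi must be finite")
        if self.aperiodic_scale <= 0:
            raise ValueError("aperiodic_scale must be positive")
        for c, bw, p in self.peaks:
            if bw <= 0:
                raise ValueError(f"peak bandwidth must be > 0, got {bw}")
            if c <= 0:
                raise ValueError(f"peak center must be > 0, got {c}")
            if p < 0:
                raise ValueError("peak power must be >= 0")


@dataclass(frozen=True)
class ArtifactSpec:
    """One artifact process: ``kind`` in {ocular, muscle, jump}.

    ``rate`` is events per minute, ``amplitude`` in µV (peak for ocular and
    jump, RMS for muscle bursts), ``band`` the muscle passband in Hz, and
    ``channels`` the affected labels (None → kind-specific default:
    ocular events project to all channels with frontal weighting, muscle to
    the temporal chain, jumps to a random single channel per event).
    """

    kind: str
    rate: float = 6.0
    amplitude: float = 100.0
    band: tuple[float, float] = (20.0, 100.0)
    duration_s: float = 0.4
    channels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"ocular", "muscle", "jump"}:
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.kind == "muscle" and not 0 < self.band[0] < self.band[1]:
            raise ValueError(f"invalid muscle band {self.band}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")


def muscle_spec(rate=10.0, amplitude=30.0, channels=("T3", "T4", "F7", "F8"),
                band=(20.0, 100.0), duration_s=1.0) -> ArtifactSpec:
    """Convenience constructor for temporal-chain muscle bursts."""
    return ArtifactSpec("muscle", rate=rate, amplitude=amplitude, band=band,
                        duration_s=duration_s, channels=tuple(channels))


def ocular_spec(rate=8.0, amplitude=120.0, duration_s=0.4) -> ArtifactSpec:
    """Convenience constructor for blink-like frontal deflections."""
    return ArtifactSpec("ocular", rate=rate, amplitude=amplitude,
                        duration_s=duration_s)


# ---------------------------------------------------------------------------
# signal-level generators


def generate_aperiodic_signal(exponent_chi: float, duration_s: float, fs: float,
                              scale: float = 20.0, seed: RngLike = 0) -> np.ndarray:
    """Colored Gaussian noise whose one-sided PSD is ``scale * f**exponent_chi``.

    Spectral synthesis: complex-Gaussian Fourier coefficients with standard
    deviation proportional to f^(χ/2) (the DC bin is zeroed — the power law
    diverges at f = 0), inverse real FFT back to the time domain. Deterministic
    for a fixed seed. Returns a 1-D array in µV of length ``duration_s * fs``.
    """
    if not math.isfinite(exponent_chi):
        raise ValueError("exponent_chi must be finite")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs <= 80:
        raise ValueError("fs must exceed 80 Hz so the 1-40 Hz range exists")
    n = int(round(duration_s * fs))
    if n < 2 * fs:
        raise ValueError("need at least 2 s of signal")
    rng = _as_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    # E|X_k|^2 = target_psd * fs * n / 2 makes the one-sided periodogram
    # 2|X_k|^2/(fs n) match the target in expectation.
    amp = np.zeros_like(freqs)
    amp[1:] = np.sqrt(scale * freqs[1:] ** exponent_chi * fs * n / 2.0)
    z = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    coeffs = amp * z / np.sqrt(2.0)
    coeffs[0] = 0.0
    if n % 2 == 0:
        coeffs[-1] = coeffs[-1].real * np.sqrt(2.0)
    return np.fft.irfft(coeffs, n=n)


def add_oscillation(x: np.ndarray, fs: float, center_freq: float,
                    bandwidth: float, peak_power: float,
                    seed: RngLike = 0) -> np.ndarray:
    """Add an independent stochastic narrowband component to ``x``.

    The component is white noise band-passed around ``center_freq`` (zero-phase
    Butterworth), scaled so the added PSD height at the peak center is
    ``peak_power`` µV²/Hz. ``peak_power = 0`` returns an unmodified copy.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if not 0 < center_freq < fs / 2:
        raise ValueError("center_freq must lie in (0, fs/2)")
    if peak_power < 0:
        raise ValueError("peak_power must be >= 0")
    x = np.asarray(x, dtype=float)
    if peak_power == 0:
        return x.copy()
    lo = max(center_freq - bandwidth / 2.0, 1e-3)
    hi = min(center_freq + bandwidth / 2.0, fs / 2 * 0.999)
    rng = _as_rng(seed)
    # white noise with one-sided PSD = peak_power at the passband center
    noise = rng.standard_normal(x.size) * np.sqrt(peak_power * fs / 2.0)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return x + sps.sosfiltfilt(sos, noise)


def _event_starts(n_events: int, duration_s: float, event_dur: float,
                  rng: np.random.Generator) -> np.ndarray:
    lo, hi = 1.0, max(duration_s - event_dur - 1.0, 1.5)
    return np.sort(rng.uniform(lo, hi, size=n_events))


def inject_artifacts(recording: EEGRecording,
                     artifact_specs: list[ArtifactSpec] | tuple[ArtifactSpec, ...],
                     seed: RngLike = 0) -> tuple[EEGRecording, list[Annotation]]:
    """Superimpose stereotyped artifact events and annotate every one.

    Ocular: half-sine biphasic-looking low-frequency deflection, projected to
    all channels with frontal weighting (Fp1/Fp2 strongest). Muscle:
    band-limited noise bursts (default 20-100 Hz, clipped below Nyquist) with
    near-zero lag-1 autocorrelation on the target channels. Jump: a step
    discontinuity on one channel. Event count per spec is deterministic
    (rate · duration); placement is random under the seed.
    """
    rng = _as_rng(seed)
    out = recording.copy_with()
    fs = recording.fs
    dur = recording.duration_s
    annotations: list[Annotation] = []

    for spec in artifact_specs:
        n_events = int(round(spec.rate * dur / 60.0))
        if n_events == 0:
            continue
        starts = _event_starts(n_events, dur, spec.duration_s, rng)
        if spec.kind == "ocular":
            nsamp = int(round(spec.duration_s * fs))
            template = np.sin(np.pi * np.arange(nsamp) / nsamp)
            for t0 in starts:
                i0 = int(round(t0 * fs))
                seg = slice(i0, i0 + nsamp)
                sign = rng.choice([-1.0, 1.0])
                for ci, lab in enumerate(out.labels):
                    w = OCULAR_WEIGHTS.get(lab, 0.1)
                    out.data[ci, seg] += sign * spec.amplitude * w * template
                annotations.append(
                    Annotation("all", t0, t0 + spec.duration_s, "ocular"))
        elif spec.kind == "muscle":
            chans = spec.channels or ("T3", "T4", "F7", "F8")
            lo = spec.band[0]
            hi = min(spec.band[1], fs / 2 * 0.99)
            sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
            nsamp = int(round(spec.duration_s * fs))
            taper = sps.windows.tukey(nsamp, alpha=0.25)
            for t0 in starts:
                i0 = int(round(t0 * fs))
                for lab in chans:
                    if lab not in out.labels:
                        continue
                    burst = sps.sosfiltfilt(sos, rng.standard_normal(nsamp))
                    burst *= taper
                    rms = np.sqrt(np.mean(burst**2))
                    if rms > 0:
                        burst *= spec.amplitude / rms
                    out.data[out.labels.index(lab), i0:i0 + nsamp] += burst
                    annotations.append(
                        Annotation(lab, t0, t0 + spec.duration_s, "muscle"))
        else:  # jump
            for t0 in starts:
                i0 = int(round(t0 * fs))
                if spec.channels:
                    lab = spec.channels[int(rng.integers(len(spec.channels)))]
                else:
                    lab = out.labels[int(rng.integers(len(out.labels)))]
                sign = rng.choice([-1.0, 1.0])
                out.data[out.labels.index(lab), i0:] += sign * spec.amplitude
                annotations.append(Annotation(lab, t0, t0, "jump"))

    out.annotations.extend(annotations)
    return out, annotations


def default_channel_specs(chi: float | dict[str, float] = -1.12,
                          aperiodic_scale: float = 20.0,
                          alpha_peak: bool = True,
                          alpha_power: float = 2.0,
                          labels: tuple[str, ...] = LABELS_1020
                          ) -> list[SimChannelSpec]:
    """Build per-channel specs with an eyes-closed alpha topography.

    Posterior channels (O1/O2/P3/P4/T5/T6) receive 3x the anterior alpha peak
    power, a plausible eyes-closed gradient. ``chi`` may be a single exponent
    or a per-label map.
    """
    specs = []
    for lab in labels:
        c = chi[lab] if isinstance(chi, dict) else chi
        peaks: tuple = ()
        if alpha_peak and alpha_power > 0:
            power = alpha_power * (3.0 if lab in POSTERIOR else 1.0)
            peaks = ((10.0, 2.0, power),)
        specs.append(SimChannelSpec(lab, c, aperiodic_scale, peaks))
    return specs


def simulate_recording(channel_specs: list[SimChannelSpec],
                       artifact_specs: list[ArtifactSpec] | None = None,
                       duration_s: float = 200.0, fs: float = 256.0,
                       seed: RngLike = 0
                       ) -> tuple[EEGRecording, "GroundTruth"]:
    """Assemble one multichannel recording from per-channel specs.

    Each channel is an independent aperiodic series plus its oscillatory
    peaks; artifacts are then injected and annotated. Ground truth records
    every channel's χ and every artifact event.
    """
    labels = [s.label for s in channel_specs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate channel labels in channel_specs")
    rng = _as_rng(seed)
    data = np.empty((len(channel_specs), int(round(duration_s * fs))))
    for i, spec in enumerate(channel_specs):
        x = generate_aperiodic_signal(spec.exponent_chi, duration_s, fs,
                                      spec.aperiodic_scale, rng)
        for center, bw, power in spec.peaks:
            x = add_oscillation(x, fs, center, bw, power, rng)
        data[i] = x
    rec = EEGRecording(data=data, fs=fs, labels=tuple(labels))
    annotations: list[Annotation] = []
    if artifact_specs:
        rec, annotations = inject_artifacts(rec, artifact_specs, rng)
    truth = GroundTruth(
        exponent_by_channel={s.label: s.exponent_chi for s in channel_specs},
        artifact_annotations=annotations,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class ClinicalCoupling:
    """Linear link from the acute affected-hemisphere exponent to recovery.

    ER (percent) = er_at_mean + slope * (χ_AH_T0 − AH_T0 group mean) + noise.
    A positive slope means shallower-than-average acute spectra (less negative
    χ) predict better recovery.
    """

    slope: float = 80.0
    noise_sd: float = 24.0
    er_at_mean: float = 60.0


@dataclass(frozen=True)
class CohortConfig:
    """Study-level generator configuration.

    ``hemisphere_exponent_means`` carries the condition means of χ;
    ``variance_components`` decomposes between-subject dispersion into a
    subject offset (shared across all conditions), a subject×time and a
    subject×hemisphere component, and a condition residual — jointly these
    set both the per-condition SDs and the paired-difference SDs of the
    hemisphere means. ``channel_sd`` is within-subject across-channel
    dispersion of χ.
    """

    n_patients: int = 18
    n_controls: int = 16
    duration_s: float = 200.0
    fs: float = 256.0
    hemisphere_exponent_means: dict[str, float] = field(default_factory=lambda: {
        "HC": -1.12, "AH_T0": -1.55, "UH_T0": -1.40,
        "AH_T1": -1.34, "UH_T1": -1.30,
    })
    variance_components: dict[str, float] = field(default_factory=lambda: {
        "subject": 0.191, "time": 0.198, "hemisphere": 0.070,
        "residual": 0.0, "hc_subject": 0.23,
    })
    channel_sd: float = 0.15
    clinical_coupling: ClinicalCoupling = field(default_factory=ClinicalCoupling)
    alpha_power: float = 2.0
    aperiodic_scale: float = 20.0
    artifact_specs: tuple[ArtifactSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_controls <= 0:
            raise ValueError("cohort counts must be positive")
        if self.fs <= 80:
            raise ValueError("fs must exceed 80 Hz")
        if self.channel_sd < 0:
            raise ValueError("channel_sd must be >= 0")
        needed = {"HC", "AH_T0", "UH_T0", "AH_T1", "UH_T1"}
        if not needed <= set(self.hemisphere_exponent_means):
            raise ValueError(f"hemisphere_exponent_means must cover {sorted(needed)}")
        if any(v < 0 for v in self.variance_components.values()):
            raise ValueError("variance components must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually put into a recording / subject."""

    exponent_by_channel: dict[str, float]
    artifact_annotations: list[Annotation] = field(default_factory=list)
    nihss_t0: int | None = None
    nihss_t1: int | None = None
    er: float | None = None
    # latent recovery from the clinical coupling, before integer NIHSS
    # scoring quantizes it; `er` is always re-derived from the NIHSS pair
    er_latent: float | None = None
    affected_side: str | None = None
    lesion_type: str | None = None

    def __post_init__(self) -> None:
        for v in (self.nihss_t0, self.nihss_t1):
            if v is not None and not 0 <= v <= 42:
                raise ValueError("NIHSS must lie in [0, 42]")
        if self.er is not None and self.nihss_t0:
            expected = effective_recovery(self.nihss_t0, self.nihss_t1)
            if abs(self.er - expected) > 1e-9:
                raise ValueError("ER inconsistent with its NIHSS pair")


@dataclass
class PatientEntry:
    recording_t0: EEGRecording | None
    recording_t1: EEGRecording | None
    record: SubjectRecord
    truth_t0: GroundTruth
    truth_t1: GroundTruth


@dataclass
class ControlEntry:
    recording: EEGRecording | None
    record: SubjectRecord
    truth: GroundTruth


def _draw_nihss_t0(rng: np.random.Generator) -> int:
    # discretized log-normal targeting median 5, IQR roughly 2-9
    v = int(round(math.exp(rng.normal(math.log(5.0), 1.0))))
    return int(np.clip(v, 1, 42))


def _hemisphere_truth_means(chi: dict[str, float], side: str
                            ) -> tuple[float, float]:
    ah, uh = hemisphere_sets(side)
    return (float(np.mean([chi[c] for c in ah])),
            float(np.mean([chi[c] for c in uh])))


def simulate_cohort(config: CohortConfig, synthesize: bool = True
                    ) -> tuple[list[PatientEntry], list[ControlEntry]]:
    """Generate a longitudinal patient cohort plus healthy controls.

    Per patient: a subject-level χ offset is drawn once and shared across all
    four conditions; subject×time and subject×hemisphere components plus a
    condition residual complete the hemisphere-mean model; per-channel χ adds
    ``channel_sd`` jitter. The affected side alternates L/R. NIHSS at T0 is a
    discretized log-normal (median ≈ 5); ER follows the clinical coupling
    applied to the subject's acute affected-hemisphere χ, NIHSS at T1 is
    back-computed by rounding and clipping to [0, NIHSS_T0], and the stored ER
    is re-derived from the final integer NIHSS pair so the two are always
    consistent.

    ``synthesize=False`` skips waveform synthesis (recordings are None) but
    draws identical clinical and χ ground truth — the cheap path for
    statistical calibration studies.
    """
    means = config.hemisphere_exponent_means
    vc = config.variance_components
    root = np.random.SeedSequence(config.seed)
    truth_rng = np.random.default_rng(root.spawn(1)[0])
    signal_seeds = root.spawn(config.n_patients * 2 + config.n_controls)

    patients: list[PatientEntry] = []
    sides = ["L", "R"]
    for i in range(config.n_patients):
        side = sides[i % 2]
        b = truth_rng.normal(0.0, vc["subject"])
        p_t = truth_rng.normal(0.0, vc["time"], size=2)      # T0, T1
        q_h = truth_rng.normal(0.0, vc["hemisphere"], size=2)  # AH, UH
        e = truth_rng.normal(0.0, vc["residual"], size=(2, 2))  # [time, hemi]
        cond = {}
        for ti, t in enumerate(("T0", "T1")):
            for hi, h in enumerate(("AH", "UH")):
                cond[f"{h}_{t}"] = (means[f"{h}_{t}"] + b + p_t[ti]
                                    + q_h[hi] + e[ti, hi])
        chi_maps = {}
        for t in ("T0", "T1"):
            ah_set, uh_set = hemisphere_sets(side)
            chi = {}
            for lab in LABELS_1020:
                if lab in ah_set:
                    base = cond[f"AH_{t}"]
                elif lab in uh_set:
                    base = cond[f"UH_{t}"]
                else:  # midline: average of the two hemispheres
                    base = 0.5 * (cond[f"AH_{t}"] + cond[f"UH_{t}"])
                chi[lab] = base + truth_rng.normal(0.0, config.channel_sd)
            chi_maps[t] = chi

        ah_m_t0, uh_m_t0 = _hemisphere_truth_means(chi_maps["T0"], side)
        ah_m_t1, uh_m_t1 = _hemisphere_truth_means(chi_maps["T1"], side)

        cpl = config.clinical_coupling
        nihss_t0 = _draw_nihss_t0(truth_rng)
        er_target = (cpl.er_at_mean + cpl.slope * (ah_m_t0 - means["AH_T0"])
                     + truth_rng.normal(0.0, cpl.noise_sd))
        nihss_t1 = int(np.clip(round(nihss_t0 * (1.0 - er_target / 100.0)),
                               0, nihss_t0))
        er = effective_recovery(nihss_t0, nihss_t1)
        lesion = "cortical" if truth_rng.uniform() < 12.0 / 18.0 else "subcortical"

        rec_t0 = rec_t1 = None
        truths = []
        for t, sseed in (("T0", signal_seeds[2 * i]), ("T1", signal_seeds[2 * i + 1])):
            truth = GroundTruth(
                exponent_by_channel=chi_maps[t], nihss_t0=nihss_t0,
                nihss_t1=nihss_t1, er=er, er_latent=float(er_target),
                affected_side=side, lesion_type=lesion)
            if synthesize:
                specs = default_channel_specs(
                    chi_maps[t], config.aperiodic_scale,
                    alpha_power=config.alpha_power)
                rec, sim_truth = simulate_recording(
                    specs, list(config.artifact_specs), config.duration_s,
                    config.fs, np.random.default_rng(sseed))
                truth.artifact_annotations = sim_truth.artifact_annotations
                if t == "T0":
                    rec_t0 = rec
                else:
                    rec_t1 = rec
            truths.append(truth)

        record = SubjectRecord(
            id=f"P{i + 1:02d}", group="patient", affected_side=side,
            lesion_type=lesion, nihss_t0=nihss_t0, nihss_t1=nihss_t1, er=er,
            se_by_channel_t0=dict(chi_maps["T0"]),
            se_by_channel_t1=dict(chi_maps["T1"]),
            ah_mean_t0=ah_m_t0, uh_mean_t0=uh_m_t0,
            ah_mean_t1=ah_m_t1, uh_mean_t1=uh_m_t1)
        patients.append(PatientEntry(rec_t0, rec_t1, record, *truths))

    controls: list[ControlEntry] = []
    for j in range(config.n_controls):
        b = truth_rng.normal(0.0, vc["hc_subject"])
        chi = {lab: means["HC"] + b + truth_rng.normal(0.0, config.channel_sd)
               for lab in LABELS_1020}
        truth = GroundTruth(exponent_by_channel=chi)
        rec = None
        if synthesize:
            specs = default_channel_specs(chi, config.aperiodic_scale,
                                          alpha_power=config.alpha_power)
            rec, sim_truth = simulate_recording(
                specs, list(config.artifact_specs), config.duration_s,
                config.fs,
                np.random.default_rng(signal_seeds[2 * config.n_patients + j]))
            truth.artifact_annotations = sim_truth.artifact_annotations
        lm, rm = _hemisphere_truth_means(chi, "L")
        record = SubjectRecord(
            id=f"HC{j + 1:02d}", group="control", affected_side="none",
            lesion_type="none", nihss_t0=None, nihss_t1=None, er=None,
            se_by_channel_t0=dict(chi), se_by_channel_t1=None,
            ah_mean_t0=lm, uh_mean_t0=rm, ah_mean_t1=None, uh_mean_t1=None)
        controls.append(ControlEntry(rec, record, truth))

    return patients, controls
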