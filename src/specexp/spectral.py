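"""Welch power spectra, broadband spectral-exponent fitting with
oscillatory-peak exclusion, and conventional narrowband metrics.

The spectral exponent (SE) is the slope of log10-power vs log10-frequency of
the aperiodic PSD background over a broad range (1-40 Hz by default): more
negative means a steeper, "slower" spectrum. Narrowband oscillations (the
eyes-closed alpha rhythm above all) ride on top of that background and would
bias a naive line fit, so the fit iteratively detects bins deviating upward
from a robust line and excludes them before refitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import griddata

from .recording import EEGRecording

BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 20.0),
}


@dataclass
class PSDSpectrum:
    """Per-channel one-sided Welch PSD in µV²/Hz."""

    freqs: np.ndarray
    power: np.ndarray  # channels x freqs
    labels: tuple[str, ...]
    window_s: float
    overlap: float
    n_segments_used: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if self.power.shape[1] != self.freqs.size:
            raise ValueError("power/freqs shape mismatch")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("negative PSD values")

    def channel_power(self, channel: int | str) -> np.ndarray:
        if isinstance(channel, str):
            channel = self.labels.index(channel)
        return self.power[channel]


@dataclass
class SpectralFitResult:
    """One channel's aperiodic fit: SE slope and diagnostics."""

    exponent: float
    intercept: float  # log10(µV²/Hz) at log10 f = 0
    fit_range: tuple[float, float]
    excluded_mask: np.ndarray  # over native bins inside fit_range
    n_iterations: int
    r_squared_aperiodic: float


@dataclass(frozen=True)
class BandMetrics:
    """Absolute (µV²) and relative band powers plus classical slowing ratios."""

    absolute: dict[str, float]
    relative: dict[str, float]
    dar: float
    dtabr: float
    theta_alpha: float
    total_power: float

    def log_absolute(self) -> dict[str, float]:
        return {k: float(np.log10(v)) for k, v in self.absolute.items()}


# ---------------------------------------------------------------------------


def welch_psd(segments, fs: float | None = None, window_s: float = 2.0,
              overlap: float = 0.5,
              labels: tuple[str, ...] | None = None) -> PSDSpectrum:
    """Welch PSD pooled over clean segments (Hann taper, density scaling).

    ``segments`` may be an :class:`EEGRecording`, a single channels x samples
    array, a 1-D array, or a list of such arrays (discontinuous clean
    stretches). Each segment is tapered/overlap-averaged separately and
    segments are combined weighted by their window counts, preserving Welch
    averaging semantics across gaps.
    """
    if isinstance(segments, EEGRecording):
        labels = labels or segments.labels
        fs = segments.fs
        segments = [segments.data]
    elif isinstance(segments, np.ndarray):
        segments = [segments]
    if fs is None:
        raise ValueError("fs is required unless an EEGRecording is passed")
    segments = [np.atleast_2d(np.asarray(s, dtype=float)) for s in segments]
    if not segments:
        raise ValueError("no segments supplied")
    nperseg = int(round(window_s * fs))
    noverlap = int(round(nperseg * overlap))
    total = sum(s.shape[1] for s in segments)
    if total < 2 * nperseg:
        raise ValueError(
            f"need >= {2 * window_s:g} s of signal total, got {total / fs:g} s")
    usable = [s for s in segments if s.shape[1] >= nperseg]
    if not usable:
        raise ValueError(f"every segment shorter than the {window_s:g} s window")

    acc = None
    freqs = None
    n_windows_total = 0
    for seg in usable:
        f, p = sps.welch(seg, fs=fs, window="hann", nperseg=nperseg,
                         noverlap=noverlap, detrend="constant",
                         scaling="density", average="mean")
        step = nperseg - noverlap
        n_win = 1 + (seg.shape[1] - nperseg) // step
        freqs = f
        acc = p * n_win if acc is None else acc + p * n_win
        n_windows_total += n_win
    power = acc / n_windows_total
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(power.shape[0]))
    return PSDSpectrum(freqs=freqs, power=power, labels=tuple(labels),
                       window_s=window_s, overlap=overlap,
                       n_segments_used=len(usable))


def _irls_line(x: np.ndarray, y: np.ndarray, max_iter: int = 50
               ) -> tuple[float, float]:
    """Iteratively reweighted least-squares line fit with bisquare weights.

    Falls back to the plain OLS solution when residuals are (numerically)
    zero — the perfect-power-law case must be recovered exactly.
    """
    X = np.column_stack([x, np.ones_like(x)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    for _ in range(max_iter):
        resid = y - X @ beta
        scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        if scale < 1e-12 * max(1.0, np.abs(y).max()):
            break
        u = np.clip(resid / (4.685 * scale), -1.0, 1.0)
        w = (1.0 - u**2) ** 2
        if w.sum() < 3 or np.allclose(w, 0):
            break
        Xw = X * w[:, None]
        new_beta = np.linalg.solve(Xw.T @ X, Xw.T @ y)
        if np.allclose(new_beta, beta, rtol=0, atol=1e-12):
            beta = new_beta
            break
        beta = new_beta
    return float(beta[0]), float(beta[1])


def fit_spectral_exponent(psd: PSDSpectrum, channel: int | str = 0,
                          f_low: float = 1.0, f_high: float = 40.0,
                          k_mad: float = 2.0, max_iter: int = 5
                          ) -> SpectralFitResult:
    """Robust aperiodic slope of log10-PSD vs log10-f with peak exclusion.

    Procedure: restrict to [f_low, f_high]; resample the log-log spectrum
    onto a grid uniform in log10 f (same point count as native bins, so the
    upper octaves do not dominate) by averaging the native bins nearest to
    each grid point — binned means homogenize the estimation noise along
    the grid, where point interpolation would leave the upper octaves
    noisier and let the exclusion step tilt the fit; robust IRLS bisquare
    line fit; mark grid points whose residual exceeds ``k_mad``
    consistency-scaled MADs above the retained-residual median (upward only
    — oscillatory peaks only add power), dilate marks by one bin to cover
    peak flanks; refit on unmarked points; iterate to convergence or
    ``max_iter``. The returned ``excluded_mask`` is mapped back to the
    native bins.
    """
    p = psd.channel_power(channel)
    sel = (psd.freqs >= f_low) & (psd.freqs <= f_high)
    f_nat = psd.freqs[sel]
    p_nat = p[sel]
    if f_nat.size < 5:
        raise ValueError("fit range covers fewer than 5 PSD bins")
    if np.any(p_nat <= 0):
        raise ValueError("non-positive PSD values inside the fit range")

    x_nat = np.log10(f_nat)
    y_nat = np.log10(p_nat)
    n_grid = f_nat.size
    x = np.linspace(x_nat[0], x_nat[-1], n_grid)
    step = x[1] - x[0]
    idx = np.clip(np.round((x_nat - x[0]) / step).astype(int), 0, n_grid - 1)
    acc = np.zeros(n_grid)
    accx = np.zeros(n_grid)
    cnt = np.zeros(n_grid)
    np.add.at(acc, idx, y_nat)
    np.add.at(accx, idx, x_nat)
    np.add.at(cnt, idx, 1.0)
    # each cell keeps its own mean abscissa so a perfect power law stays a
    # perfect line after averaging
    y = np.where(cnt > 0, acc / np.maximum(cnt, 1.0),
                 np.interp(x, x_nat, y_nat))
    x = np.where(cnt > 0, accx / np.maximum(cnt, 1.0), x)

    keep = np.ones(n_grid, dtype=bool)
    slope, inter = _irls_line(x, y)
    n_iterations = 0
    for _ in range(max_iter):
        n_iterations += 1
        resid = y - (slope * x + inter)
        r_keep = resid[keep]
        mad = 1.4826 * np.median(np.abs(r_keep - np.median(r_keep)))
        marks = keep & (resid > np.median(r_keep) + k_mad * max(mad, 1e-15))
        if not marks.any():
            break
        # dilate to contiguous clusters (one-bin flanks)
        dil = marks.copy()
        dil[:-1] |= marks[1:]
        dil[1:] |= marks[:-1]
        new_keep = keep & ~dil
        if new_keep.sum() < 5:
            raise ValueError("over-excluded spectrum: fewer than 5 bins retained")
        if new_keep.sum() == keep.sum():
            break
        keep = new_keep
        slope, inter = _irls_line(x[keep], y[keep])

    resid = y - (slope * x + inter)
    ss_res = float(np.sum(resid[keep] ** 2))
    ss_tot = float(np.sum((y[keep] - y[keep].mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)

    # map excluded grid intervals back to native bins
    excluded_nat = np.zeros(f_nat.size, dtype=bool)
    if (~keep).any():
        half = step / 2 if n_grid > 1 else 0.0
        for xg in x[~keep]:
            excluded_nat |= np.abs(x_nat - xg) <= half + 1e-12
    return SpectralFitResult(
        exponent=slope, intercept=inter, fit_range=(f_low, f_high),
        excluded_mask=excluded_nat, n_iterations=n_iterations,
        r_squared_aperiodic=min(1.0, r2))


def naive_fit(psd: PSDSpectrum, channel: int | str = 0,
              f_low: float = 1.0, f_high: float = 40.0) -> SpectralFitResult:
    """Single ordinary-least-squares log-log line on all native bins in range.

    Baseline comparator: no peak exclusion, no log-uniform resampling.
    """
    p = psd.channel_power(channel)
    sel = (psd.freqs >= f_low) & (psd.freqs <= f_high)
    f_nat = psd.freqs[sel]
    p_nat = p[sel]
    if f_nat.size < 2:
        raise ValueError("empty or degenerate fit range")
    if np.any(p_nat <= 0):
        raise ValueError("non-positive PSD values inside the fit range")
    x = np.log10(f_nat)
    y = np.log10(p_nat)
    X = np.column_stack([x, np.ones_like(x)])
    (slope, inter), res, *_ = np.linalg.lstsq(X, y, rcond=None)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - float(np.sum((y - X @ [slope, inter]) ** 2)) / ss_tot)
    return SpectralFitResult(
        exponent=float(slope), intercept=float(inter),
        fit_range=(f_low, f_high),
        excluded_mask=np.zeros(f_nat.size, dtype=bool),
        n_iterations=1, r_squared_aperiodic=min(1.0, r2))


def band_metrics(psd: PSDSpectrum, channel: int | str = 0,
                 total_range: tuple[float, float] = (1.0, 40.0)) -> BandMetrics:
    """Band powers by trapezoid integration on the native frequency grid.

    Bands: delta 1-4, theta 4-8, alpha 8-12, beta 13-20 Hz (the 12-13 Hz
    sliver belongs to no band). Relative power normalizes by the integral
    over ``total_range``. DAR = delta/alpha; DTABR = (delta+theta)/(alpha+beta).
    """
    p = psd.channel_power(channel)

    def integrate(lo: float, hi: float) -> float:
        m = (psd.freqs >= lo) & (psd.freqs <= hi)
        if m.sum() < 2:
            raise ValueError(f"PSD does not cover the {lo}-{hi} Hz band")
        return float(np.trapezoid(p[m], psd.freqs[m]))

    absolute = {name: integrate(lo, hi) for name, (lo, hi) in BANDS.items()}
    total = integrate(*total_range)
    if total <= 0:
        raise ValueError("zero total power")
    relative = {name: v / total for name, v in absolute.items()}
    alpha = absolute["alpha"]
    ab = absolute["alpha"] + absolute["beta"]
    return BandMetrics(
        absolute=absolute, relative=relative,
        dar=absolute["delta"] / alpha if alpha > 0 else np.inf,
        dtabr=(absolute["delta"] + absolute["theta"]) / ab if ab > 0 else np.inf,
        theta_alpha=absolute["theta"] / alpha if alpha > 0 else np.inf,
        total_power=total)


def channel_topography(values_by_label: dict[str, float],
                       positions: dict[str, tuple[float, float]],
                       grid_n: int = 64) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interpolate per-channel values onto a schematic scalp grid.

    Returns (xi, yi, grid) where ``grid`` is masked (NaN) outside the head
    circle. Purely cosmetic; no statistics are derived from it.
    """
    missing = [lab for lab in values_by_label if lab not in positions]
    if missing:
        raise ValueError(f"missing positions for {missing}")
    if len(values_by_label) < 3:
        raise ValueError("need at least 3 channels for a topography")
    pts = np.array([positions[lab] for lab in values_by_label])
    vals = np.array(list(values_by_label.values()), dtype=float)
    xi = np.linspace(-1.1, 1.1, grid_n)
    yi = np.linspace(-1.1, 1.1, grid_n)
    gx, gy = np.meshgrid(xi, yi)
    grid = griddata(pts, vals, (gx, gy), method="linear")
    nearest = griddata(pts, vals, (gx, gy), method="nearest")
    grid = np.where(np.isnan(grid), nearest, grid)
    grid[gx**2 + gy**2 > 1.1**2] = np.nan
    return xi, yi, grid


def plot_topography(values_by_label, positions, ax=None):  # pragma: no cover
    """Optional matplotlib rendering of :func:`channel_topography`."""
    import matplotlib.pyplot as plt

    xi, yi, grid = channel_topography(values_by_label, positions)
    if ax is None:
        _, ax = plt.subplots()
    im = ax.pcolormesh(xi, yi, grid, shading="auto", cmap="viridis")
    for lab, (px, py) in positions.items():
        if lab in values_by_label:
            ax.plot(px, py, "k.", ms=3)
    ax.set_aspect("equal")
    ax.set_axis_off()
    return im
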