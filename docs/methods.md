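# Methods

## The statistic

The spectral exponent (SE) is the slope χ of the resting EEG power spectral
density in log10-log10 coordinates over 1–40 Hz, fitted so that narrowband
oscillatory peaks do not bias it. It summarizes the aperiodic, 1/f-like
background of the spectrum; physiologically it tracks cortical
excitation/inhibition balance, and clinically it indexes EEG "slowing":
steeper (more negative) over the affected hemisphere in acute stroke, with
partial renormalization during recovery.

### Estimation procedure

1. Welch PSD: Hann taper, 2 s windows, 50 % overlap, density scaling
   (integral of the PSD ≈ signal variance). Discontinuous clean segments
   are tapered separately and pooled with window-count weights, preserving
   Welch averaging semantics across gaps. Frequency resolution 0.5 Hz.
2. Restrict to the fit range (default 1–40 Hz), take log10 of both axes.
3. Resample onto a grid uniform in log10 f with the same point count as the
   native bins (79 at 0.5 Hz), by averaging the native bins nearest each
   grid point. Without this, the 20–40 Hz octave contributes half the bins
   and dominates an unweighted fit. Binned means (rather than point
   interpolation) keep the estimation noise homogeneous along the grid;
   each cell keeps its own mean abscissa so an exact power law remains an
   exact line. Cells with no native bin (the lowest octave) are filled by
   interpolation.
4. Robust line fit: iteratively reweighted least squares with Tukey
   bisquare weights (c = 4.685, MAD scale). If residuals are numerically
   zero the plain least-squares solution is returned, so analytic power
   laws are recovered to machine precision.
5. Peak exclusion: grid points whose residual exceeds the retained-residual
   median by k = 2 consistency-scaled MADs (≈ 3σ), upward only — peaks only
   add power; a symmetric rule would also trim the troughs between peaks
   and tilt the fit. Marks are dilated by one grid cell to cover peak
   flanks, the line is refitted on the remainder, and the loop repeats to
   convergence or 5 iterations. Fewer than 5 surviving points is an error
   ("over-excluded spectrum"), not a silent fit.
6. Outputs per channel: exponent, intercept (log10 µV²/Hz at 1 Hz), the
   excluded-bin mask mapped back to native bins, iteration count, and R²
   on the retained bins.

A deliberately naive single-pass ordinary-least-squares fit on the raw
log-log bins (`naive_fit`) is kept as a baseline comparator; tests assert
the robust fit beats it whenever peaks are present.

### Band metrics

Delta 1–4, theta 4–8, alpha 8–12, beta 13–20 Hz (the 12–13 Hz sliver is
deliberately unassigned), integrated by trapezoid on the native grid over
the closed band interval. Relative powers normalize by the 1–40 Hz
integral; DAR = delta/alpha and DTABR = (delta+theta)/(alpha+beta) are the
classical slowing ratios. These are reported for comparison only — the SE
is the primary statistic.

## Preprocessing chain

Fixed order, enforced by `PreprocessingPipeline` (a stage invoked before
its predecessors raises):

detrend → bad-channel detection/interpolation → 0.5 Hz high-pass → 50 Hz
notch → BSS-CCA muscle removal → average reference → ICA ocular rejection →
residual segment rejection → quality gate.

Choices that were genuinely open:

- **Filters are zero-phase** (forward-backward), so the effective magnitude
  response is the squared design response; phase distortion of slow
  components would contaminate the low-frequency end of the SE fit.
  High-pass: 5th-order Butterworth at 0.5 Hz. Notch: second-order IIR,
  2 Hz bandwidth, center configurable (60 Hz mains supported).
- **Bad channels** are scored by two features across channels:
  log10-variance and Fisher-transformed (atanh) lag-1 autocorrelation. The
  Fisher transform decompresses the autocorrelation scale near 1 where
  physiological channels cluster. Deviations from the channel median are
  scaled by max(1.4826·MAD, floor), with floors of 0.5 decades
  (log-variance) and 0.8 (Fisher units). The floors are the load-bearing
  choice: a pure MAD scale collapses by chance with only 19 channels and
  flags healthy channels, while any scale that includes the outliers
  (SD-based hybrids) is inflated by a *pair* of bad channels and masks
  them — and caps the achievable |z| at (n−1)/√n ≈ 4.3. The floor values
  are set so that the cross-channel spread produced by severe hemispheric
  steepening itself (≈1.3 decades / 2.3 Fisher units at the simulator's
  pathological extreme) scores below the default threshold of 3, while a
  gain-error channel (20× = 2.6 decades) scores above it. Flat (dead)
  channels are flagged categorically. A single bad channel is replaced by
  the unweighted mean of its neighbours in a fixed schematic 10–20
  adjacency table; two or more fail the recording.
- **Muscle removal** is blind source separation by canonical correlation
  between the signal and its one-sample-delayed copy, in consecutive
  non-overlapping 10 s windows (a trailing window ≥ 2 s is processed,
  shorter is passed through). Components are ordered by canonical
  correlation — equal to their lag-1 autocorrelation — and those below 0.7
  are zeroed; broadband muscle activity is nearly white at 256 Hz while
  cortical signal is strongly autocorrelated. Whitening is
  ridge-regularized (relative λ = 1e-6, raised on rank deficiency).
  The 0.7 boundary bounds the method's validity range: a broadband process
  with χ ≥ −0.9 has lag-1 autocorrelation below 0.7 and is treated as
  muscle *by design*; eyes-closed cortical EEG (χ ≤ −1, plus alpha) sits
  safely above. A dedicated test documents this boundary.
- **Ocular rejection** replaces visual component selection with an
  automated criterion: FastICA components whose absolute correlation with
  an ocular surrogate — the mean of Fp1/Fp2 low-passed at 5 Hz — exceeds
  0.7 are removed. The ICA dimension is capped at the numerical rank
  (average-referenced data has rank n−1). FastICA that stops at its
  iteration cap is still a valid orthogonal unmixing of the whitened data
  and is used as such; formal non-convergence is expected on near-Gaussian
  background (ICA is unidentifiable for Gaussian sources) while the
  strongly non-Gaussian blink component is isolated within the first
  iterations. Only numerical failure falls back to regressing the
  surrogate out of every channel.
- **Segment rejection**: 1 s windows flagged when any channel exceeds
  150 µV absolute amplitude or 50 µV/sample first difference; both
  thresholds are configurable and deliberately conservative stand-ins for
  the visual review they replace.
- **Quality gate**: pass ⇔ at most 1 bad channel and ≥ 180 s clean signal;
  failing subjects are dropped at both timepoints, never half-analyzed.

Average referencing slightly attenuates hemispheric contrast relative to
the generator's sensor-level truth (the subtracted global mean contains the
steeper affected hemisphere); this is a property of the montage choice, not
a defect, and affects both hemispheres symmetrically.

## Statistics

- Hemisphere means use only the 16 lateral channels; Fz/Cz/Pz are
  discarded. Left set {Fp1,F3,F7,C3,T3,P3,T5,O1}, right set mirrored;
  AH/UH assignment follows the lesion side.
- 2×2 fully within-subject ANOVA (hemisphere × time) from explicit sums of
  squares, each effect tested against its own subject-interaction error
  term. With two levels per factor sphericity is automatic, so the
  Greenhouse–Geisser ε is identically 1 and is reported for completeness.
  Both classical eta-squared (SS_effect/SS_total) and partial eta-squared
  are reported, labeled; the two conventions differ and results should
  name the one used. The implementation is cross-checked against
  `pingouin.rm_anova` to 6 decimals in the test suite.
- Post-hocs: paired t-tests with Benjamini–Hochberg FDR across the
  comparison family (default family: AH_T0 vs UH_T0, AH_T0 vs AH_T1,
  AH_T0 vs UH_T1), plus percentile bootstrap CI95 of the mean difference.
- Asymmetry change: paired test of (AH−UH) at T0 vs T1; negative mean
  difference means larger asymmetry acutely.
- Group comparisons use the unequal-variance (Welch) t-test.
- Correlations: Pearson r with two-sided p and percentile bootstrap CI95
  (2000 pair resamples, seeded; degenerate resamples are dropped). The
  12-entry condition × score table reports raw p and Bonferroni-adjusted
  p (family of 12) side by side.
- Narrowband exploration: Wilcoxon signed-rank per metric/contrast,
  explicitly flagged uncorrected — sensitivity-first by design.
- Effective Recovery ER = 100·(NIHSS_T0 − NIHSS_T1)/NIHSS_T0 (percent;
  negative when worsening; undefined at NIHSS_T0 = 0 and raised as an
  error, since a patient without deficit has no recovery to measure).

## Synthetic cohort generator

The generator is first-class code: every downstream stage is tested against
its ground truth.

- **Aperiodic channels**: frequency-domain synthesis — complex-Gaussian
  Fourier coefficients shaped by f^(χ/2), random phases, DC zeroed (the
  power law diverges at f = 0), inverse FFT. The expected one-sided PSD is
  exactly scale·f^χ (µV²/Hz), scale defaulting to 20 µV²/Hz at 1 Hz.
- **Alpha**: band-passed white noise, 10 Hz center, 2 Hz bandwidth, peak
  height calibrated in PSD units; posterior channels (O1/O2/P3/P4/T5/T6)
  get 3× the anterior power — a plausible eyes-closed topography.
- **Artifacts**: ocular = half-sine deflections with frontal weighting
  (Fp1=Fp2=1, F3/F4/F7/F8=0.5, others 0.1), sub-5 Hz by construction;
  muscle = 20–100 Hz (Nyquist-clipped) noise bursts with near-zero lag-1
  autocorrelation, default on the temporal chain, RMS-calibrated; jump =
  step discontinuity. Event counts are deterministic (rate·duration),
  placements seeded; every event is annotated.
- **Cohort structure**: condition means of χ are {HC −1.12; AH/UH at T0
  −1.55/−1.40; at T1 −1.34/−1.30}. Between-subject structure decomposes
  into a subject offset (SD 0.191, shared across all four conditions), a
  subject×time component (0.198), a subject×hemisphere component (0.070),
  and per-channel jitter (0.15, whose hemisphere-mean contribution
  0.15/√8 ≈ 0.053 plays the residual's role). This decomposition is the
  unique one that simultaneously reproduces the per-condition SDs (~0.29),
  the acute asymmetry SD (0.124), the asymmetry-change SD (0.101) and the
  longitudinal change SD (0.29) that characterize the modeled population.
- **Clinical coupling**: NIHSS_T0 is a discretized log-normal (median ≈ 5,
  IQR ≈ 2–9, clipped to [1, 42]). A latent recovery is generated as
  ER = 60 + 80·(χ_AH,T0 − mean) + N(0, 24) percent — shallower acute
  spectra predict better recovery — then NIHSS_T1 =
  round(NIHSS_T0·(1−ER/100)) clipped to [0, NIHSS_T0], and the stored ER
  is re-derived from the integer pair so the two are always consistent.
  The slope/noise pair is calibrated so the sample correlation between the
  acute affected-hemisphere SE and ER centers near 0.63 at n = 18.
  Integer scoring quantizes ER (coarsely for mild patients), which is why
  the generator also exposes the latent value.
- **Determinism**: all generators are pure functions of (config, seed);
  `simulate_cohort(..., synthesize=False)` draws identical clinical and χ
  truth without waveform synthesis — the cheap path used by the
  statistical calibration studies, which need hundreds of cohorts and
  whose questions (type-I error, power, correlation recovery) live
  entirely at the hemisphere-summary level. Signal-path fidelity is
  established separately by the estimator-recovery and cleaning tests.

### What the generator does not emulate

Gaussianity: the aperiodic background is a Gaussian process, where real
EEG is not (real ICA separates better than the synthetic case suggests).
No nonstationarity of the background within a recording, no heartbeat or
sweat artifacts, no electrode drift, no volume-conduction correlation
between channels (channels are independent given their χ), no lesion
geometry — the affected side is a label, and the χ shift is applied
hemisphere-wide. Passing tests therefore demonstrate correctness of the
estimators and workflow under the stated spectral model, not robustness to
every property of clinical recordings.

## Problem sizes and runtime choices

Estimator-fidelity checks use 200 s at 256 Hz (the scale of usable clinical
resting recordings) with 10–20 seeds per condition; calibration studies use
400 null cohorts and 50 calibrated cohorts of n = 18 at the summary level;
the end-to-end demonstration cohort is 18 patients × 2 timepoints + 16
controls at full signal scale. These sizes give stable Monte-Carlo
estimates while keeping a complete run of the suite and the acceptance
script in the minutes range on a single CPU.

## Known limitations

- The time main effect replicates in only about half of simulated cohorts
  at the modeled effect size (mean longitudinal change 0.155 SE units
  against a paired-difference SD of ~0.29, n = 18): a borderline effect by
  construction, and the corresponding acceptance check documents this
  honestly rather than inflating the generator's effect.
- The CCA muscle criterion removes genuine broadband signal for χ ≥ −0.9;
  the pipeline is intended for eyes-closed adult EEG (χ ≤ −1).
- The high-pass removes sub-0.5 Hz power whose spectral leakage otherwise
  steepens the raw low-frequency bins; consequently the cleaned SE can
  legitimately differ from the raw SE by more than their common distance
  to ground truth.
- Peak-exclusion constants (k = 2 scaled MADs, one-cell dilation, 5
  iterations) are fixed, configurable choices; other published 1/f
  parameterizations make different ones, and exponents are comparable
  across methods only qualitatively.
- EDF output is 16-bit; quantization error is bounded by the per-channel
  physical range over 65535 and is negligible relative to EEG noise.
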