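"""Hemisphere-by-time statistics for longitudinal spectral-exponent cohorts.

The layer mirrors a standard clinical qEEG workflow: sort the 16 lateral
10-20 channels into affected (AH) and unaffected (UH) hemispheres, run a
2x2 within-subject ANOVA (hemisphere x time), FDR-corrected paired post-hocs,
an asymmetry-change test, group comparisons, Pearson correlations with
bootstrap confidence intervals, and uncorrected narrowband explorations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as ss
from statsmodels.stats.multitest import multipletests

from .montage import LEFT_LATERAL, RIGHT_LATERAL, hemisphere_sets

CONDITIONS = ("AH_T0", "UH_T0", "AH_T1", "UH_T1")


@dataclass
class SubjectRecord:
    """Clinical fields plus hemisphere-mean spectral exponents per timepoint.

    ``er`` is Effective Recovery in percent: 100 * (NIHSS_T0 - NIHSS_T1) /
    NIHSS_T0, i.e. achieved improvement relative to the maximum possible
    (NIHSS = 0 means no deficit). Hemisphere means use only the 16 lateral
    channels; midline Fz/Cz/Pz never enter them.
    """

    id: str
    group: str  # patient | control
    affected_side: str  # L | R | none
    lesion_type: str  # cortical | subcortical | none
    nihss_t0: int | None
    nihss_t1: int | None
    er: float | None
    se_by_channel_t0: dict[str, float] | None = None
    se_by_channel_t1: dict[str, float] | None = None
    ah_mean_t0: float | None = None
    uh_mean_t0: float | None = None
    ah_mean_t1: float | None = None
    uh_mean_t1: float | None = None

    def __post_init__(self) -> None:
        for v in (self.nihss_t0, self.nihss_t1):
            if v is not None and not 0 <= int(v) <= 42:
                raise ValueError(f"NIHSS out of [0, 42]: {v}")
        if (self.er is not None and self.nihss_t0 and self.nihss_t1 is not None):
            expected = effective_recovery(self.nihss_t0, self.nihss_t1)
            # tolerance accommodates 6-decimal CSV round-tripping
            if abs(self.er - expected) > 1e-4:
                raise ValueError(
                    f"{self.id}: er={self.er} inconsistent with NIHSS pair "
                    f"({self.nihss_t0}, {self.nihss_t1}) -> {expected}")

    def condition_means(self) -> dict[str, float]:
        out = {"AH_T0": self.ah_mean_t0, "UH_T0": self.uh_mean_t0,
               "AH_T1": self.ah_mean_t1, "UH_T1": self.uh_mean_t1}
        missing = [k for k, v in out.items() if v is None]
        if missing:
            raise ValueError(f"{self.id}: missing condition means {missing}")
        return out


@dataclass(frozen=True)
class AnovaEffect:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    gg_epsilon: float
    eta_squared: float
    partial_eta_squared: float


@dataclass
class AnovaResult:
    effects: dict[str, AnovaEffect]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.effects.values()])


@dataclass(frozen=True)
class CorrelationEntry:
    pair: tuple[str, str]
    r: float
    p: float
    ci95: tuple[float, float]
    n: int


# ---------------------------------------------------------------------------


def hemisphere_means(se_by_channel: dict[str, float], affected_side: str
                     ) -> tuple[float, float]:
    """Mean SE over the affected and unaffected lateral channel sets.

    Midline channels (Fz/Cz/Pz) are discarded; the remaining 16 channels are
    split left/right and assigned to AH/UH according to ``affected_side``.
    """
    missing = [c for c in LEFT_LATERAL + RIGHT_LATERAL if c not in se_by_channel]
    if missing:
        raise ValueError(f"missing lateral channels: {missing}")
    ah_set, uh_set = hemisphere_sets(affected_side)
    ah = float(np.mean([se_by_channel[c] for c in ah_set]))
    uh = float(np.mean([se_by_channel[c] for c in uh_set]))
    return ah, uh


def effective_recovery(nihss_t0: int, nihss_t1: int) -> float:
    """Effective Recovery in percent: 100 * (T0 - T1) / T0.

    Negative when the patient worsened. Undefined (raises) for NIHSS_T0 = 0:
    a patient without deficit has no recovery to measure.
    """
    t0, t1 = int(nihss_t0), int(nihss_t1)
    if not (0 <= t0 <= 42 and 0 <= t1 <= 42):
        raise ValueError("NIHSS scores must lie in [0, 42]")
    if t0 == 0:
        raise ValueError("ER undefined for NIHSS_T0 = 0 (no deficit at baseline)")
    return 100.0 * (t0 - t1) / t0


def _condition_matrix(cohort) -> np.ndarray:
    """Subjects x 4 matrix in CONDITIONS order from records or dicts."""
    rows = []
    for subj in cohort:
        if isinstance(subj, SubjectRecord):
            cm = subj.condition_means()
        else:
            cm = subj
        try:
            rows.append([float(cm[c]) for c in CONDITIONS])
        except (KeyError, TypeError) as exc:
            sid = getattr(subj, "id", "<dict>")
            raise ValueError(f"incomplete cells for subject {sid}") from exc
    return np.asarray(rows, dtype=float)


def rm_anova_2x2(cohort) -> AnovaResult:
    """Two-way fully within-subject ANOVA: hemisphere (AH/UH) x time (T0/T1).

    Computed from explicit sums of squares. With two levels per factor
    sphericity holds automatically, so the Greenhouse-Geisser epsilon is 1
    and the corrected and uncorrected tests coincide; epsilon is still
    reported for generality. Both classical eta-squared (SS_effect/SS_total)
    and partial eta-squared are returned.
    """
    y = _condition_matrix(cohort)  # columns: AH_T0, UH_T0, AH_T1, UH_T1
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 complete subjects")
    # reshape to [subject, hemisphere(AH,UH), time(T0,T1)]
    cube = np.stack([y[:, [0, 2]], y[:, [1, 3]]], axis=1)
    grand = cube.mean()
    subj_m = cube.mean(axis=(1, 2))
    hemi_m = cube.mean(axis=(0, 2))
    time_m = cube.mean(axis=(0, 1))
    cell_m = cube.mean(axis=0)  # [hemi, time]

    ss_subj = 4.0 * np.sum((subj_m - grand) ** 2)
    ss_h = 2.0 * n * np.sum((hemi_m - grand) ** 2)
    ss_t = 2.0 * n * np.sum((time_m - grand) ** 2)
    ss_ht = n * np.sum(
        (cell_m - hemi_m[:, None] - time_m[None, :] + grand) ** 2)

    sh_m = cube.mean(axis=2)  # [subject, hemi]
    st_m = cube.mean(axis=1)  # [subject, time]
    ss_hs = 2.0 * np.sum(
        (sh_m - subj_m[:, None] - hemi_m[None, :] + grand) ** 2)
    ss_ts = 2.0 * np.sum(
        (st_m - subj_m[:, None] - time_m[None, :] + grand) ** 2)
    ss_total = np.sum((cube - grand) ** 2)
    ss_hts = ss_total - ss_subj - ss_h - ss_t - ss_ht - ss_hs - ss_ts

    dfe = n - 1
    eps = 1e-12 * max(float(ss_total), 1.0)  # numerically-zero SS guard
    effects = {}
    for name, ss_eff, ss_err in (
        ("hemisphere", ss_h, ss_hs),
        ("time", ss_t, ss_ts),
        ("hemisphere*time", ss_ht, ss_hts),
    ):
        ms_eff = ss_eff / 1.0
        ms_err = ss_err / dfe
        if ms_err > eps:
            f = ms_eff / ms_err
        else:
            f = 0.0 if ms_eff <= eps else np.inf
        p = float(ss.f.sf(f, 1, dfe)) if np.isfinite(f) else 0.0
        effects[name] = AnovaEffect(
            effect=name, F=float(f), df_num=1, df_den=dfe, p=p,
            gg_epsilon=1.0,
            eta_squared=float(ss_eff / ss_total) if ss_total > 0 else 0.0,
            partial_eta_squared=(float(ss_eff / (ss_eff + ss_err))
                                 if (ss_eff + ss_err) > 0 else 0.0),
        )
    return AnovaResult(effects)


def _bootstrap_ci_mean(diff: np.ndarray, n_boot: int, rng: np.random.Generator
                       ) -> tuple[float, float]:
    idx = rng.integers(0, diff.size, size=(n_boot, diff.size))
    boots = diff[idx].mean(axis=1)
    return tuple(np.percentile(boots, [2.5, 97.5]))


DEFAULT_POSTHOC = (("AH_T0", "UH_T0"), ("AH_T0", "AH_T1"), ("AH_T0", "UH_T1"))


def posthoc_paired_tests(cohort, comparisons=DEFAULT_POSTHOC,
                         n_boot: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Paired t-tests with Benjamini-Hochberg FDR across the family.

    Returns one row per comparison: t, raw p, BH-corrected p, mean difference
    (first minus second condition) and its percentile bootstrap CI95.
    """
    y = _condition_matrix(cohort)
    if y.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    for a, b in comparisons:
        if a not in CONDITIONS or b not in CONDITIONS:
            raise ValueError(f"unknown condition in comparison ({a}, {b})")
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in comparisons:
        da = y[:, CONDITIONS.index(a)]
        db = y[:, CONDITIONS.index(b)]
        diff = da - db
        if np.allclose(diff, 0):
            t, p = 0.0, 1.0
        else:
            t, p = ss.ttest_rel(da, db)
        lo, hi = _bootstrap_ci_mean(diff, n_boot, rng)
        rows.append({"comparison": f"{a} vs {b}", "t": float(t), "p_raw": float(p),
                     "mean_diff": float(diff.mean()), "ci95_low": lo, "ci95_high": hi})
    out = pd.DataFrame(rows)
    out["p_fdr"] = multipletests(out["p_raw"].to_numpy(), method="fdr_bh")[1]
    return out


def asymmetry_change_test(cohort, n_boot: int = 2000, seed: int = 0
                          ) -> dict[str, float]:
    """Paired test of the interhemispheric asymmetry (AH - UH) at T0 vs T1.

    Equivalent to a one-sample t-test of (AH-UH)_T0 − (AH-UH)_T1 against 0.
    ``mean_diff`` is negative when the asymmetry is larger (more negative)
    acutely than at follow-up.
    """
    y = _condition_matrix(cohort)
    if y.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    asym_t0 = y[:, 0] - y[:, 1]
    asym_t1 = y[:, 2] - y[:, 3]
    diff = asym_t0 - asym_t1
    if np.allclose(diff, 0):
        t, p = 0.0, 1.0
    else:
        t, p = ss.ttest_1samp(diff, 0.0)
    lo, hi = _bootstrap_ci_mean(diff, n_boot, np.random.default_rng(seed))
    return {"t": float(t), "p": float(p), "mean_diff": float(diff.mean()),
            "ci95_low": lo, "ci95_high": hi,
            "asym_t0_mean": float(asym_t0.mean()),
            "asym_t1_mean": float(asym_t1.mean())}


def group_ttest(values_a, values_b, paired: bool = False,
                n_boot: int = 2000, seed: int = 0) -> dict[str, float]:
    """Two-sample t-test (Welch for unpaired) with bootstrap CI95 of the mean
    difference (a minus b)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    rng = np.random.default_rng(seed)
    if paired:
        if a.size != b.size:
            raise ValueError("paired groups must have equal n")
        diff = a - b
        if np.allclose(diff, 0):
            t, p = 0.0, 1.0
        else:
            t, p = ss.ttest_rel(a, b)
        lo, hi = _bootstrap_ci_mean(diff, n_boot, rng)
        mean_diff = float(diff.mean())
    else:
        if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = ss.ttest_ind(a, b, equal_var=False)
        ia = rng.integers(0, a.size, size=(n_boot, a.size))
        ib = rng.integers(0, b.size, size=(n_boot, b.size))
        boots = a[ia].mean(axis=1) - b[ib].mean(axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        mean_diff = float(a.mean() - b.mean())
    return {"t": float(t), "p": float(p), "mean_diff": mean_diff,
            "ci95_low": float(lo), "ci95_high": float(hi)}


def pearson_bootstrap(x, y, n_boot: int = 2000, seed: int = 0,
                      pair: tuple[str, str] = ("x", "y")) -> CorrelationEntry:
    """Pearson r with two-sided p and percentile bootstrap CI95 over pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need n >= 4 paired finite values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in correlation input")
    r, p = ss.pearsonr(x, y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    xs, ys = x[idx], y[idx]
    xs_c = xs - xs.mean(axis=1, keepdims=True)
    ys_c = ys - ys.mean(axis=1, keepdims=True)
    denom = np.sqrt((xs_c**2).sum(axis=1) * (ys_c**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        boots = (xs_c * ys_c).sum(axis=1) / denom
    boots = boots[np.isfinite(boots)]  # drop degenerate resamples
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return CorrelationEntry(pair=tuple(pair), r=float(r), p=float(p),
                            ci95=(float(lo), float(hi)), n=int(x.size))


def correlation_table(cohort, n_boot: int = 2000, seed: int = 0,
                      bonferroni_family: int = 12) -> pd.DataFrame:
    """SE condition means vs NIHSS_T0 / NIHSS_T1 / ER, with raw and
    Bonferroni-adjusted p (12-entry family by default)."""
    y = _condition_matrix(cohort)
    clin = {
        "NIHSS_T0": np.array([s.nihss_t0 for s in cohort], dtype=float),
        "NIHSS_T1": np.array([s.nihss_t1 for s in cohort], dtype=float),
        "ER": np.array([s.er for s in cohort], dtype=float),
    }
    rng = np.random.default_rng(seed)
    rows = []
    for ci, cond in enumerate(CONDITIONS):
        for score, vals in clin.items():
            entry = pearson_bootstrap(
                y[:, ci], vals, n_boot=n_boot,
                seed=int(rng.integers(2**31)), pair=(cond, score))
            rows.append({"condition": cond, "score": score, "r": entry.r,
                         "p_raw": entry.p,
                         "p_bonferroni": min(1.0, entry.p * bonferroni_family),
                         "ci95_low": entry.ci95[0], "ci95_high": entry.ci95[1],
                         "n": entry.n})
    return pd.DataFrame(rows)


def narrowband_exploration(metric_pairs: dict[str, tuple[np.ndarray, np.ndarray]]
                           ) -> pd.DataFrame:
    """Uncorrected Wilcoxon signed-rank tests for paired narrowband metrics.

    ``metric_pairs`` maps a contrast name (e.g. ``"rel_delta AH T0 vs T1"``)
    to the two paired vectors. Output carries an explicit ``corrected=False``
    flag; these are sensitivity-first exploratory contrasts.
    """
    rows = []
    for name, (a, b) in metric_pairs.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size != b.size or a.size < 3:
            raise ValueError(f"{name}: need paired vectors with n >= 3")
        diff = a - b
        if np.allclose(diff, 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = ss.wilcoxon(a, b)
        rows.append({"contrast": name, "W": float(stat), "p": float(p),
                     "median_diff": float(np.median(diff)), "corrected": False})
    return pd.DataFrame(rows)
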