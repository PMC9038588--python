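"""End-to-end orchestration: simulated or real cohorts from one config to a
results bundle (cohort table, ANOVA, post-hocs, asymmetry, correlations,
narrowband exploration) with a run manifest.

Subjects failing the quality gate at either timepoint are dropped entirely
and counted — a longitudinal design cannot use half a subject.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .montage import LABELS_1020
from .preprocess import (PreprocessingParams, extract_segments,
                         preprocess_recording)
from .recording import EEGRecording
from .spectral import band_metrics, fit_spectral_exponent, welch_psd
from .stats import (SubjectRecord, asymmetry_change_test, correlation_table,
                    group_ttest, hemisphere_means, narrowband_exploration,
                    posthoc_paired_tests, rm_anova_2x2)
from .synth import CohortConfig, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One config drives a whole run.

    ``mode`` is ``"simulate"`` (a :class:`CohortConfig` provides the input)
    or ``"analyze"`` (a manifest CSV lists per-subject EDF paths). A seed is
    mandatory in simulate mode; in analyze mode randomness only enters the
    bootstrap CIs, which always take a seed (default 0).
    """

    mode: str = "simulate"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    manifest_csv: str | None = None
    preprocessing: PreprocessingParams = field(default_factory=PreprocessingParams)
    fit_range: tuple[float, float] = (1.0, 40.0)
    welch_window_s: float = 2.0
    welch_overlap: float = 0.5
    n_boot: int = 2000
    stats_seed: int = 0
    corrupt_subjects: tuple[str, ...] = ()
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.mode not in {"simulate", "analyze"}:
            raise ValueError("mode must be 'simulate' or 'analyze'")
        if self.mode == "analyze" and not self.manifest_csv:
            raise ValueError("analyze mode needs manifest_csv")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        prep = PreprocessingParams(**raw.pop("preprocessing", {}))
        fit_range = tuple(raw.pop("fit_range", (1.0, 40.0)))
        corrupt = tuple(raw.pop("corrupt_subjects", ()))
        return cls(cohort=cohort, preprocessing=prep, fit_range=fit_range,
                   corrupt_subjects=corrupt, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["clinical_coupling"] = dataclasses.asdict(
            self.cohort.clinical_coupling)
        return d


@dataclass
class RunManifest:
    config: dict
    version: str
    n_subjects_analyzed: int
    n_subjects_excluded: int
    exclusions: dict[str, list[str]]
    quality: dict[str, dict]
    outputs: list[str]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def analyze_recording(recording: EEGRecording, params: PreprocessingParams,
                      fit_range=(1.0, 40.0), welch_window_s=2.0,
                      welch_overlap=0.5):
    """Clean one recording, gate it, and compute per-channel SE + band metrics.

    Returns (QualityReport, se_by_channel, metrics_by_channel); the metric
    dicts are None when the gate fails.
    """
    res = preprocess_recording(recording, params)
    if not res.report.passed:
        return res.report, None, None
    segments = extract_segments(res.recording, res.segments)
    psd = welch_psd(segments, res.recording.fs, welch_window_s, welch_overlap,
                    labels=res.recording.labels)
    se = {}
    metrics = {}
    for lab in res.recording.labels:
        fit = fit_spectral_exponent(psd, lab, *fit_range)
        se[lab] = fit.exponent
        metrics[lab] = band_metrics(psd, lab)
    return res.report, se, metrics


def _corrupt(recording: EEGRecording) -> EEGRecording:
    """Make two channels wildly outlying so the quality gate must fail."""
    out = recording.copy_with()
    out.data[0] *= 25.0
    out.data[1] *= 25.0
    return out


def _hemisphere_metric_means(metrics_by_channel, affected_side: str):
    """Hemisphere means of the narrowband metrics (lateral channels only)."""
    from .montage import hemisphere_sets

    ah_set, uh_set = hemisphere_sets(affected_side)
    out = {}
    for tag, chans in (("AH", ah_set), ("UH", uh_set)):
        ms = [metrics_by_channel[c] for c in chans]
        out[tag] = {
            "rel_delta": float(np.mean([m.relative["delta"] for m in ms])),
            "rel_alpha": float(np.mean([m.relative["alpha"] for m in ms])),
            "rel_beta": float(np.mean([m.relative["beta"] for m in ms])),
            "log_delta": float(np.mean([np.log10(m.absolute["delta"]) for m in ms])),
            "log_beta": float(np.mean([np.log10(m.absolute["beta"]) for m in ms])),
            "dar": float(np.mean([m.dar for m in ms])),
            "dtabr": float(np.mean([m.dtabr for m in ms])),
        }
    return out


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full analysis and write the results bundle to
    ``config.out_dir``. Returns the manifest (also written as JSON)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.mode == "simulate":
        patients, controls = simulate_cohort(config.cohort, synthesize=True)
        patient_inputs = [
            (e.record,
             _corrupt(e.recording_t0) if e.record.id in config.corrupt_subjects
             else e.recording_t0,
             e.recording_t1)
            for e in patients]
        control_inputs = [(e.record, e.recording) for e in controls]
    else:
        patient_inputs, control_inputs = _load_manifest(config)

    quality: dict[str, dict] = {}
    exclusions: dict[str, list[str]] = {}
    analyzed: list[SubjectRecord] = []
    control_mean_se: list[float] = []
    band_rows: list[dict] = []

    for record, rec_t0, rec_t1 in patient_inputs:
        ses = {}
        mets = {}
        reasons: list[str] = []
        for t, rec in (("T0", rec_t0), ("T1", rec_t1)):
            if rec is None:
                reasons.append(f"{t}:missing_recording")
                continue
            report, se, m = analyze_recording(
                rec, config.preprocessing, config.fit_range,
                config.welch_window_s, config.welch_overlap)
            quality[f"{record.id}_{t}"] = report.to_dict()
            if not report.passed:
                reasons.extend(f"{t}:{r}" for r in report.reasons)
            else:
                ses[t], mets[t] = se, m
        if reasons:
            exclusions[record.id] = reasons
            logger.info("excluded %s: %s", record.id, reasons)
            continue
        ah0, uh0 = hemisphere_means(ses["T0"], record.affected_side)
        ah1, uh1 = hemisphere_means(ses["T1"], record.affected_side)
        analyzed.append(SubjectRecord(
            id=record.id, group="patient", affected_side=record.affected_side,
            lesion_type=record.lesion_type, nihss_t0=record.nihss_t0,
            nihss_t1=record.nihss_t1, er=record.er,
            se_by_channel_t0=ses["T0"], se_by_channel_t1=ses["T1"],
            ah_mean_t0=ah0, uh_mean_t0=uh0, ah_mean_t1=ah1, uh_mean_t1=uh1))
        for t in ("T0", "T1"):
            hm = _hemisphere_metric_means(mets[t], record.affected_side)
            for hemi in ("AH", "UH"):
                band_rows.append({"id": record.id, "time": t, "hemi": hemi,
                                  **hm[hemi]})

    for record, rec in control_inputs:
        if rec is None:
            continue
        report, se, _ = analyze_recording(
            rec, config.preprocessing, config.fit_range,
            config.welch_window_s, config.welch_overlap)
        quality[f"{record.id}"] = report.to_dict()
        if report.passed:
            control_mean_se.append(float(np.mean(list(se.values()))))
        else:
            exclusions[record.id] = list(report.reasons)

    outputs: list[str] = []

    def save_df(df: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        df.to_csv(path, index=False, float_format="%.6f")
        outputs.append(name)

    cohort_df = _cohort_frame(analyzed)
    save_df(cohort_df, "cohort.csv")
    bands_df = pd.DataFrame(band_rows)
    save_df(bands_df, "band_metrics.csv")

    results_json: dict = {"n_patients": len(analyzed),
                          "n_controls": len(control_mean_se)}
    if len(analyzed) >= 3:
        anova = rm_anova_2x2(analyzed)
        save_df(anova.to_frame(), "anova.csv")
        save_df(posthoc_paired_tests(analyzed, seed=config.stats_seed,
                                     n_boot=config.n_boot), "posthoc.csv")
        results_json["asymmetry_change"] = asymmetry_change_test(
            analyzed, seed=config.stats_seed, n_boot=config.n_boot)
        if len(analyzed) >= 4:  # bootstrap correlations need pairs to spare
            save_df(correlation_table(analyzed, seed=config.stats_seed,
                                      n_boot=config.n_boot),
                    "correlations.csv")
        patient_t0_means = [float(np.mean(list(s.se_by_channel_t0.values())))
                            for s in analyzed]
        if len(control_mean_se) >= 2:
            results_json["group_ttest_t0"] = group_ttest(
                patient_t0_means, control_mean_se, seed=config.stats_seed,
                n_boot=config.n_boot)
        cort = [s for s in analyzed if s.lesion_type == "cortical"]
        subc = [s for s in analyzed if s.lesion_type == "subcortical"]
        if len(cort) >= 2 and len(subc) >= 2:
            results_json["lesion_type_ttest_ah_t0"] = group_ttest(
                [s.ah_mean_t0 for s in cort], [s.ah_mean_t0 for s in subc],
                seed=config.stats_seed, n_boot=config.n_boot)
        if not bands_df.empty:
            save_df(narrowband_exploration(_narrowband_pairs(bands_df)),
                    "narrowband.csv")

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(results_json, fh, indent=2, sort_keys=True)
    outputs.append("summary.json")

    manifest = RunManifest(
        config=config.to_dict(), version=__version__,
        n_subjects_analyzed=len(analyzed),
        n_subjects_excluded=len(exclusions),
        exclusions=exclusions, quality=quality,
        outputs=sorted(outputs) + ["manifest.json"])
    manifest.to_json(out_dir / "manifest.json")
    return manifest


def _cohort_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for s in records:
        row = {"id": s.id, "group": s.group, "affected_side": s.affected_side,
               "lesion_type": s.lesion_type, "nihss_t0": s.nihss_t0,
               "nihss_t1": s.nihss_t1, "er": s.er,
               "ah_mean_t0": s.ah_mean_t0, "uh_mean_t0": s.uh_mean_t0,
               "ah_mean_t1": s.ah_mean_t1, "uh_mean_t1": s.uh_mean_t1}
        for lab in LABELS_1020:
            if s.se_by_channel_t0:
                row[f"se_{lab}_t0"] = s.se_by_channel_t0.get(lab)
            if s.se_by_channel_t1:
                row[f"se_{lab}_t1"] = s.se_by_channel_t1.get(lab)
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_records_from_csv(path: str | Path) -> list[SubjectRecord]:
    """Rebuild :class:`SubjectRecord`s from a cohort.csv written by
    :func:`run_pipeline` — the bridge format into the stats layer."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        se0 = {lab: row[f"se_{lab}_t0"] for lab in LABELS_1020
               if f"se_{lab}_t0" in row and pd.notna(row.get(f"se_{lab}_t0"))}
        se1 = {lab: row[f"se_{lab}_t1"] for lab in LABELS_1020
               if f"se_{lab}_t1" in row and pd.notna(row.get(f"se_{lab}_t1"))}
        records.append(SubjectRecord(
            id=str(row["id"]), group=row["group"],
            affected_side=row["affected_side"], lesion_type=row["lesion_type"],
            nihss_t0=None if pd.isna(row["nihss_t0"]) else int(row["nihss_t0"]),
            nihss_t1=None if pd.isna(row["nihss_t1"]) else int(row["nihss_t1"]),
            er=None if pd.isna(row["er"]) else float(row["er"]),
            se_by_channel_t0=se0 or None, se_by_channel_t1=se1 or None,
            ah_mean_t0=row["ah_mean_t0"], uh_mean_t0=row["uh_mean_t0"],
            ah_mean_t1=row["ah_mean_t1"], uh_mean_t1=row["uh_mean_t1"]))
    return records


def _narrowband_pairs(bands_df: pd.DataFrame) -> dict:
    """Paired hemisphere/time contrasts of the narrowband metrics."""
    pairs = {}
    metrics = ("rel_delta", "rel_alpha", "rel_beta", "log_delta", "log_beta",
               "dar", "dtabr")
    pivot = bands_df.pivot_table(index="id", columns=["time", "hemi"],
                                 values=list(metrics))
    for m in metrics:
        pairs[f"{m}: AH_T0 vs UH_T0"] = (
            pivot[(m, "T0", "AH")].to_numpy(), pivot[(m, "T0", "UH")].to_numpy())
        pairs[f"{m}: AH_T0 vs AH_T1"] = (
            pivot[(m, "T0", "AH")].to_numpy(), pivot[(m, "T1", "AH")].to_numpy())
        pairs[f"{m}: UH_T0 vs UH_T1"] = (
            pivot[(m, "T0", "UH")].to_numpy(), pivot[(m, "T1", "UH")].to_numpy())
    return pairs


def _load_manifest(config: RunConfig):
    """Read an analyze-mode manifest CSV and load the EDFs it lists."""
    from .edf import read_edf

    df = pd.read_csv(config.manifest_csv)
    patient_inputs = []
    control_inputs = []
    for _, row in df.iterrows():
        rid = str(row["id"])
        if row["group"] == "patient":
            rec_t0 = rec_t1 = None
            for col in ("edf_t0", "edf_t1"):
                p = row.get(col)
                if isinstance(p, str) and p and Path(p).exists():
                    rec = read_edf(p)
                    if col == "edf_t0":
                        rec_t0 = rec
                    else:
                        rec_t1 = rec
                else:
                    logger.warning("%s: missing %s file", rid, col)
            record = SubjectRecord(
                id=rid, group="patient", affected_side=row["affected_side"],
                lesion_type=row.get("lesion_type", "none"),
                nihss_t0=int(row["nihss_t0"]), nihss_t1=int(row["nihss_t1"]),
                er=None)
            record.er = (100.0 * (record.nihss_t0 - record.nihss_t1)
                         / record.nihss_t0) if record.nihss_t0 else None
            patient_inputs.append((record, rec_t0, rec_t1))
        else:
            p = row.get("edf_t0")
            rec = read_edf(p) if isinstance(p, str) and Path(p).exists() else None
            record = SubjectRecord(
                id=rid, group="control", affected_side="none",
                lesion_type="none", nihss_t0=None, nihss_t1=None, er=None)
            control_inputs.append((record, rec))
    return patient_inputs, control_inputs


def make_report(results_dir: str | Path) -> str:
    """Render a human-readable markdown summary from a completed run.

    Idempotent; raises on an empty or missing results directory, warns (in
    the text) about any table that is absent.
    """
    results_dir = Path(results_dir)
    if not results_dir.exists() or not any(results_dir.iterdir()):
        raise FileNotFoundError(f"no results in {results_dir}")
    lines = ["# Spectral-exponent cohort report", ""]

    summary_path = results_dir / "summary.json"
    if summary_path.exists():
        summary = json.loads(summary_path.read_text())
        lines += ["## Cohort",
                  f"- patients analyzed: {summary.get('n_patients')}",
                  f"- controls analyzed: {summary.get('n_controls')}", ""]
        if "group_ttest_t0" in summary:
            g = summary["group_ttest_t0"]
            lines += ["## Patients vs controls (mean SE, T0)",
                      f"t = {g['t']:.3f}, p = {g['p']:.4f}, "
                      f"mean diff = {g['mean_diff']:.3f} "
                      f"(CI95 {g['ci95_low']:.3f}..{g['ci95_high']:.3f})", ""]
        if "asymmetry_change" in summary:
            a = summary["asymmetry_change"]
            lines += ["## Asymmetry (AH-UH) change T0 -> T1",
                      f"t = {a['t']:.3f}, p = {a['p']:.4f}, "
                      f"mean diff = {a['mean_diff']:.3f}", ""]
        if "lesion_type_ttest_ah_t0" in summary:
            g = summary["lesion_type_ttest_ah_t0"]
            lines += ["## Cortical vs subcortical (AH SE, T0)",
                      f"t = {g['t']:.3f}, p = {g['p']:.4f}", ""]
    else:
        lines.append("WARNING: summary.json missing")

    for name, title in (("anova.csv", "Repeated-measures ANOVA"),
                        ("posthoc.csv", "Post-hoc paired tests (FDR)"),
                        ("correlations.csv", "SE vs clinical correlations"),
                        ("narrowband.csv", "Narrowband exploration (uncorrected)")):
        path = results_dir / name
        if path.exists():
            df = pd.read_csv(path)
            lines += [f"## {title}", "```", df.to_string(index=False), "```", ""]
        else:
            lines += [f"## {title}", f"WARNING: {name} missing", ""]

    text = "\n".join(lines)
    (results_dir / "report.md").write_text(text)
    return text
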