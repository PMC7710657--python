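"""End-to-end orchestration: cohort -> per-subject metrics -> group statistics.

A single config (dict or YAML file) names either input monitor files or a
simulation recipe, the light schedule, the analysis thresholds, and an output
directory.  The pipeline computes, per subject: rhythm strength (RS) and
classification separately for the LD and DD segments, per-phase activity, and
LD sleep metrics; then group descriptives and tests per metric; and writes a
results CSV, a human-readable summary, actogram matrices, and a log of
parameters, seeds and exclusions.  Fixed config and seed give byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as mio
from .actogram import ActogramMatrix, actogram_matrix
from .rhythmicity import (
    ANALYSIS_BIN_MIN,
    MAX_LAG_HOURS,
    RS_THRESHOLD,
    SEARCH_WINDOW_HOURS,
    compute_rhythmicity,
)
from .schedule import LightSchedule
from .series import ActivitySeries
from .simulate import DEFAULT_LIGHTS_ON, DEFAULT_START, simulate_cohort, treatment_preset
from .sleep import SLEEP_THRESHOLD_MIN, detect_sleep_bouts, phase_activity, summarize_sleep
from .stats import GroupComparison, one_way_anova_tukey, two_sample_t

#: metrics compared across groups when at least two groups are present
COMPARED_METRICS = [
    "rs_ld", "rs_dd",
    "activity_day", "activity_night",
    "activity_subjective_day", "activity_subjective_night",
    "sleep_total_day", "sleep_total_night",
    "sleep_bouts_day", "sleep_bouts_night",
    "mean_bout_day", "mean_bout_night",
]


@dataclass
class ResultsBundle:
    per_subject: pd.DataFrame
    comparisons: dict[str, GroupComparison]
    arrhythmic: dict[str, dict[str, tuple[float, int]]]  # regime -> group -> (pct, n)
    actograms: dict[str, ActogramMatrix]
    log: list[str] = field(default_factory=list)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and subject."""


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def split_regimes(
    series: ActivitySeries, schedule: LightSchedule
) -> tuple[Optional[ActivitySeries], Optional[ActivitySeries]]:
    """Split a series at the LD/DD boundary; either part may be None."""
    boundary = schedule.day_start(schedule.entrain_days) if schedule.dd_days else schedule.window_end
    parts = []
    for lo, hi in ((schedule.reference_start, boundary), (boundary, schedule.window_end)):
        lo = max(lo, series.start_time)
        hi = min(hi, series.end_time)
        if hi <= lo:
            parts.append(None)
            continue
        i0 = int((lo - series.start_time).total_seconds() // 60 // series.bin_width)
        i1 = int((hi - series.start_time).total_seconds() // 60 // series.bin_width)
        if i1 <= i0:
            parts.append(None)
            continue
        parts.append(
            ActivitySeries(
                subject_id=series.subject_id,
                start_time=series.bin_start(i0),
                bin_width=series.bin_width,
                counts=series.counts[i0:i1],
                modality=series.modality,
            )
        )
    return parts[0], parts[1]


def _gather_inputs(cfg: dict, seed: Optional[int], log: list[str]):
    """Yield (group, ActivitySeries) pairs plus the schedule."""
    inp = cfg.get("input", {})
    subjects: list[tuple[str, ActivitySeries]] = []
    if "simulate" in inp:
        sim = inp["simulate"]
        master = seed if seed is not None else int(sim.get("seed", 0))
        lights_on = int(sim.get("lights_on_clock", DEFAULT_LIGHTS_ON))
        start = pd.Timestamp(sim.get("start", DEFAULT_START))
        schedule = None
        for offset, (group, n) in enumerate(sorted(sim["groups"].items())):
            params = treatment_preset(group, **sim.get("overrides", {}))
            cohort = simulate_cohort(
                int(n), params, seed=master + offset, subject_prefix=group,
                lights_on_clock=lights_on, start=start,
            )
            if schedule is None:
                schedule = LightSchedule(
                    entrain_days=params.n_days_ld, dd_days=params.n_days_dd,
                    lights_on_clock=lights_on, reference_start=start,
                )
            subjects += [(group, s) for s, _ in cohort]
            log.append(f"simulated group {group}: n={n}, seed={master + offset}")
    elif "files" in inp:
        if not inp["files"]:
            raise PipelineError("input stage: no input files given")
        if "schedule" not in cfg:
            raise PipelineError("input stage: a schedule is required for file input")
        schedule = LightSchedule.from_dict(cfg["schedule"])
        for entry in inp["files"]:
            group = entry.get("group", "all")
            try:
                series_list = mio.read_monitor(
                    entry["path"], dialect=entry["dialect"],
                    channel_map=entry.get("channel_map"),
                )
            except (mio.MonitorFormatError, mio.MonitorDataError) as exc:
                raise PipelineError(f"input stage: {entry['path']}: {exc}") from exc
            subjects += [(group, s) for s in series_list]
            log.append(f"read {entry['path']}: {len(series_list)} subjects -> group {group}")
    else:
        raise PipelineError("input stage: config must name 'simulate' or 'files' input")
    if "schedule" in cfg:
        schedule = LightSchedule.from_dict(cfg["schedule"])
    if not subjects:
        raise PipelineError("input stage: no subjects found")
    return subjects, schedule


def _subject_row(group: str, series: ActivitySeries, schedule: LightSchedule,
                 analysis: dict, log: list[str]) -> dict:
    row: dict = {"subject_id": series.subject_id, "group": group, "excluded": False,
                 "exclusion_reason": ""}
    rs_kwargs = dict(
        max_lag_hours=float(analysis.get("max_lag_hours", MAX_LAG_HOURS)),
        search_window_hours=tuple(analysis.get("search_window_hours", SEARCH_WINDOW_HOURS)),
        rs_threshold=float(analysis.get("rs_threshold", RS_THRESHOLD)),
        analysis_bin_min=int(analysis.get("analysis_bin_min", ANALYSIS_BIN_MIN)),
    )
    ld, dd = split_regimes(series, schedule)
    for name, seg in (("ld", ld), ("dd", dd)):
        if seg is None:
            continue
        try:
            res = compute_rhythmicity(seg, **rs_kwargs)
        except ValueError as exc:
            log.append(f"rhythmicity[{name}] skipped for {series.subject_id}: {exc}")
            continue
        row[f"rs_{name}"] = res.rs
        row[f"label_{name}"] = res.label
        row[f"period_{name}_h"] = res.estimated_period_hours
    try:
        act = phase_activity(series, schedule)
    except ValueError as exc:
        raise PipelineError(f"activity stage failed for {series.subject_id}: {exc}") from exc
    for phase, mean in act.means.items():
        row[f"activity_{phase.value}"] = mean
    if series.bin_width == 1 and ld is not None and schedule.entrain_days > 0:
        threshold = int(analysis.get("sleep_threshold_min", SLEEP_THRESHOLD_MIN))
        bouts = detect_sleep_bouts(ld, threshold=threshold, schedule=schedule)
        summary = summarize_sleep(bouts, schedule, ld_only=True)
        row.update(
            sleep_total_day=summary.total_sleep_day / summary.n_days,
            sleep_total_night=summary.total_sleep_night / summary.n_days,
            sleep_bouts_day=summary.bouts_day / summary.n_days,
            sleep_bouts_night=summary.bouts_night / summary.n_days,
            mean_bout_day=summary.mean_bout_day,
            mean_bout_night=summary.mean_bout_night,
        )
    return row


def run_pipeline(config, out_dir: str | Path | None = None,
                 seed: Optional[int] = None) -> ResultsBundle:
    """Run the full analysis described by ``config``; see module docstring.

    ``seed`` overrides the config's simulation seed; ``out_dir`` overrides the
    config's output directory (no files are written when both are absent).
    """
    cfg = _load_config(config)
    analysis = cfg.get("analysis", {})
    log: list[str] = [
        f"rs_threshold={analysis.get('rs_threshold', RS_THRESHOLD)}",
        f"search_window_hours={tuple(analysis.get('search_window_hours', SEARCH_WINDOW_HOURS))}",
        f"sleep_threshold_min={analysis.get('sleep_threshold_min', SLEEP_THRESHOLD_MIN)}",
    ]
    subjects, schedule = _gather_inputs(cfg, seed, log)
    log.append(f"schedule: {schedule.to_dict()}")

    rows = []
    for group, series in subjects:
        rows.append(_subject_row(group, series, schedule, analysis, log))
    df = pd.DataFrame(rows)

    groups = sorted(df["group"].unique())
    comparisons: dict[str, GroupComparison] = {}
    if len(groups) >= 2:
        for metric in COMPARED_METRICS:
            if metric not in df.columns:
                continue
            samples = [df.loc[df["group"] == g, metric].dropna().to_numpy() for g in groups]
            if any(len(s) < 2 for s in samples):
                continue
            if len(groups) == 2:
                comparisons[metric] = two_sample_t(samples[0], samples[1],
                                                   labels=(groups[0], groups[1]))
            else:
                comparisons[metric] = one_way_anova_tukey(samples, labels=groups)

    arr: dict[str, dict[str, tuple[float, int]]] = {}
    for regime in ("ld", "dd"):
        col = f"label_{regime}"
        if col not in df.columns:
            continue
        arr[regime] = {}
        for g in groups:
            labels = df.loc[df["group"] == g, col].dropna()
            if len(labels):
                pct = 100.0 * (labels == "arrhythmic").mean()
                arr[regime][g] = (float(pct), int(len(labels)))

    actograms = {}
    for g in groups:
        sid = df.loc[df["group"] == g, "subject_id"].iloc[0]
        series = next(s for grp, s in subjects if s.subject_id == sid)
        actograms[sid] = actogram_matrix(series, bin_width=30, double_plot=True)

    bundle = ResultsBundle(per_subject=df, comparisons=comparisons,
                           arrhythmic=arr, actograms=actograms, log=log)
    out = out_dir or cfg.get("output")
    if out is not None:
        _write_bundle(bundle, Path(out))
    return bundle


def _fmt_comparison(name: str, c: GroupComparison) -> str:
    desc = "; ".join(f"{g.label}: {g.mean:.3f} ± {g.sem:.3f} (n={g.n})" for g in c.groups)
    if c.test == "anova_tukey":
        head = f"F({c.df[0]:.0f},{c.df[1]:.0f}) = {c.statistic:.3f}, p = {c.p_value:.4f}"
        pairs = "; ".join(f"{a} vs {b}: p = {p:.4f}" for a, b, p in c.pairwise)
        return f"{name}: {head}\n  {desc}\n  Tukey: {pairs}"
    return f"{name}: t({c.df[0]:.0f}) = {c.statistic:.3f}, p = {c.p_value:.4f}\n  {desc}"


def _write_bundle(bundle: ResultsBundle, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    mio.export_results_table(bundle.per_subject.to_dict("records"), out / "results.csv")
    lines = []
    for regime, by_group in bundle.arrhythmic.items():
        for g, (pct, n) in by_group.items():
            lines.append(f"arrhythmic [{regime}] {g}: {pct:.1f}% (n={n})")
    for name, comp in bundle.comparisons.items():
        lines.append(_fmt_comparison(name, comp))
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    (out / "log.txt").write_text("\n".join(bundle.log) + "\n")
    acto_dir = out / "actograms"
    acto_dir.mkdir(exist_ok=True)
    for sid, mat in bundle.actograms.items():
        pd.DataFrame(mat.values).to_csv(acto_dir / f"{sid}.csv", index=False,
                                        float_format="%.1f")
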