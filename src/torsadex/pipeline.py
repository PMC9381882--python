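"""Study orchestration: run every subject/timepoint through the analysis
modules and emit summary grids, per-subject values, event logs and an
arrhythmia-score table.

Group inferential statistics are deliberately not computed; the outputs
are mean ± SD grids plus per-subject values that any stats package can
consume. Every dropped signal/subject gets a machine-readable reason.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import arrhythmia_scoring, ecg_intervals, map_analysis, signal_io
from .core import TorsadexError, ValidationError

__all__ = ["StudyConfig", "SubjectConfig", "TimepointInput", "AnalysisParams",
           "StudyResult", "run_study", "report", "load_config"]

INTERVAL_PARAMS = ("RR", "PP", "QRS", "QT", "JT", "QTc", "JTc")
MAP_PARAMS = ("LV MAPD", "RV MAPD", "dMAPD", "STV LV MAPD", "STV RV MAPD")


class TimepointInput(BaseModel):
    trace: Path
    annotations: Path
    infusion_onset_ms: Optional[float] = None


class SubjectConfig(BaseModel):
    id: str
    timepoints: dict[str, TimepointInput]


class AnalysisParams(BaseModel):
    n_complexes: int = Field(default=5, ge=2)
    stv_beats: int = Field(default=30, ge=2)
    stv_divisor: str = "sqrt2"
    as_window_s: float = Field(default=600.0, gt=0)
    p_on_t_window_ms: float = Field(default=40.0, ge=0)
    mapd_fraction: float = Field(default=0.80, gt=0, le=1)


class StudyConfig(BaseModel):
    subjects: list[SubjectConfig]
    params: AnalysisParams = AnalysisParams()
    output_dir: Path
    seed: int = 0


def load_config(path: str | Path) -> StudyConfig:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml  # optional; JSON is the primary config format

        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    return StudyConfig(**doc)


@dataclass
class StudyResult:
    intervals: pd.DataFrame  # per subject x timepoint
    map_metrics: pd.DataFrame
    as_table: pd.DataFrame
    events: pd.DataFrame
    exclusions: pd.DataFrame
    summary_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    output_dir: Optional[Path] = None


def run_study(config: StudyConfig) -> StudyResult:
    """Deterministic full-study run; unreadable subjects are excluded with a
    logged reason, and the run aborts only when every subject is excluded."""
    params = config.params
    interval_rows, map_rows, as_rows, event_rows, excl_rows = [], [], [], [], []
    n_ok = 0

    for subject in config.subjects:
        subject_ok = False
        for label, tp in subject.timepoints.items():
            try:
                trace = signal_io.read_trace(tp.trace)
                ann = signal_io.read_annotations(tp.annotations)
            except (TorsadexError, OSError) as exc:
                excl_rows.append({"subject": subject.id, "timepoint": label,
                                  "reason": "unreadable_input", "detail": str(exc)})
                continue

            window = None
            if tp.infusion_onset_ms is not None:
                try:
                    _, window = ecg_intervals.select_timepoint(
                        trace, ann, tp.infusion_onset_ms)
                except ValidationError as exc:
                    excl_rows.append({"subject": subject.id, "timepoint": label,
                                      "reason": "bad_infusion_onset", "detail": str(exc)})
                    continue

            try:
                summary = ecg_intervals.measure_intervals(
                    ann, n=params.n_complexes, timepoint=label, window_ms=window)
                interval_rows.append({
                    "subject": subject.id, "timepoint": label,
                    "RR": summary.rr, "PP": summary.pp, "QRS": summary.qrs,
                    "QT": summary.qt, "JT": summary.jt,
                    "QTc": summary.qtc, "JTc": summary.jtc,
                    "n_complexes": summary.n_complexes,
                })
                subject_ok = True
            except TorsadexError as exc:
                excl_rows.append({"subject": subject.id, "timepoint": label,
                                  "reason": "intervals_failed", "detail": str(exc)})

            map_row = {"subject": subject.id, "timepoint": label}
            for chan, key in (("LV-MAP", "LV MAPD"), ("RV-MAP", "RV MAPD")):
                try:
                    series = map_analysis.mapd_series(
                        trace, ann, channel=chan, fraction=params.mapd_fraction)
                    series = map_analysis.exclude_beats(
                        series, ann, p_on_t_window_ms=params.p_on_t_window_ms)
                    kept = series.durations[~series.mask]
                    map_row[key] = float(np.mean(kept[:params.n_complexes]))
                    try:
                        res = map_analysis.stv(series, n_beats=params.stv_beats,
                                               divisor_mode=params.stv_divisor)
                        map_row["STV " + key] = res.stv
                    except TorsadexError as exc:
                        excl_rows.append({
                            "subject": subject.id, "timepoint": label,
                            "reason": f"stv_failed_{chan}", "detail": str(exc)})
                except TorsadexError as exc:
                    excl_rows.append({"subject": subject.id, "timepoint": label,
                                      "reason": f"mapd_failed_{chan}", "detail": str(exc)})
            if "LV MAPD" in map_row and "RV MAPD" in map_row:
                map_row["dMAPD"] = map_analysis.delta_mapd(
                    map_row["LV MAPD"], map_row["RV MAPD"])
            if len(map_row) > 2:
                map_rows.append(map_row)
                subject_ok = True

            events = arrhythmia_scoring.classify_runs(ann)
            for ev in events:
                event_rows.append({
                    "subject": subject.id, "timepoint": label, "kind": ev.kind,
                    "run_length": ev.run_length, "onset_ms": ev.onset_ms,
                    "offset_ms": ev.offset_ms, "duration_s": ev.duration_s,
                    "shocks": ev.shocks, "points": ev.points if not ev.orphan else None,
                })
            if tp.infusion_onset_ms is not None:
                res = arrhythmia_scoring.arrhythmia_score(
                    events, window_start_ms=tp.infusion_onset_ms,
                    window_s=params.as_window_s)
                as_rows.append({
                    "subject": subject.id, "timepoint": label,
                    "AS": res.as_value,
                    "contributing": "+".join(f"{p:g}" for p in res.contributing),
                    "any_sEB": res.any_seb, "any_mEB": res.any_meb,
                    "any_TdP": res.any_tdp,
                })
        if subject_ok:
            n_ok += 1

    if n_ok == 0:
        raise ValidationError("all subjects were excluded; nothing to analyze")

    intervals = pd.DataFrame(interval_rows)
    map_metrics = pd.DataFrame(map_rows)
    result = StudyResult(
        intervals=intervals,
        map_metrics=map_metrics,
        as_table=pd.DataFrame(as_rows),
        events=pd.DataFrame(event_rows),
        exclusions=pd.DataFrame(
            excl_rows, columns=["subject", "timepoint", "reason", "detail"]),
        summary_tables={
            "intervals": _summary_grid(intervals, INTERVAL_PARAMS),
            "map": _summary_grid(map_metrics, MAP_PARAMS),
        },
    )
    _write_outputs(result, config)
    return result


def _summary_grid(df: pd.DataFrame, params: tuple[str, ...]) -> pd.DataFrame:
    """Parameter x timepoint grid of mean, SD and n."""
    if df.empty:
        return pd.DataFrame()
    rows = []
    timepoints = list(dict.fromkeys(df["timepoint"]))
    for p in params:
        if p not in df.columns:
            continue
        row: dict = {"parameter": p}
        for tp in timepoints:
            vals = df.loc[df["timepoint"] == tp, p].dropna()
            row[f"{tp}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{tp}_sd"] = vals.std(ddof=1) if len(vals) > 1 else (0.0 if len(vals) else np.nan)
            row[f"{tp}_n"] = len(vals)
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")


def _write_outputs(result: StudyResult, config: StudyConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.output_dir = out
    result.intervals.to_csv(out / "intervals_per_subject.csv", index=False)
    result.map_metrics.to_csv(out / "map_per_subject.csv", index=False)
    result.as_table.to_csv(out / "arrhythmia_scores.csv", index=False)
    result.events.to_csv(out / "events.csv", index=False)
    result.exclusions.to_csv(out / "exclusions.csv", index=False)
    for name, table in result.summary_tables.items():
        signal_io.write_summary_table(table, out / f"summary_{name}.csv")
    manifest = {
        "seed": config.seed,
        "params": config.params.model_dump(),
        "n_subjects": len(config.subjects),
        "subjects": [s.id for s in config.subjects],
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")


def report(result: StudyResult) -> str:
    """Human-readable rendering; formatting only, no computation."""
    lines = ["# Study report", ""]
    for name, table in result.summary_tables.items():
        lines.append(f"## Summary: {name}")
        if table.empty:
            lines.append("(no data)")
        else:
            timepoints = sorted({c.rsplit("_", 1)[0] for c in table.columns
                                 if c.endswith("_mean")})
            for param, row in table.iterrows():
                cells = []
                for tp in timepoints:
                    m, s = row.get(f"{tp}_mean"), row.get(f"{tp}_sd")
                    if pd.notna(m):
                        cells.append(f"{tp}: {signal_io.format_mean_sd(m, s, 1)}")
                lines.append(f"  {param:<14} " + " | ".join(cells))
        lines.append("")
    if not result.as_table.empty:
        lines.append("## Arrhythmia scores")
        for _, row in result.as_table.iterrows():
            lines.append(
                f"  {row['subject']} @ {row['timepoint']}: AS = {row['AS']:.2f} "
                f"({row['contributing']})")
        lines.append("")
    if not result.events.empty:
        lines.append("## Events")
        for _, row in result.events.iterrows():
            lines.append(
                f"  {row['subject']} @ {row['timepoint']}: {row['kind']} "
                f"run={row['run_length']} onset={row['onset_ms']:.0f} ms")
        lines.append("")
    if not result.exclusions.empty:
        lines.append("## Exclusions")
        for _, row in result.exclusions.iterrows():
            lines.append(f"  {row['subject']} @ {row['timepoint']}: {row['reason']}")
        lines.append("")
    return "\n".join(lines)
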