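"""Read/write traces, annotations and result tables.

Trace container: delimited text (CSV body) with ``#``-prefixed typed
header lines — portable and diffable. Annotations: JSON with ``beats``
and ``events`` arrays. Both formats carry a version field; readers
reject unknown major versions.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .core import Annotations, BeatAnnotation, SignalTrace, TorsadexError, ValidationError
from .synthetic_signals import ScheduledEvent

__all__ = [
    "TRACE_FORMAT_VERSION",
    "ANNOTATION_FORMAT_VERSION",
    "TraceFormatError",
    "AnnotationFormatError",
    "read_trace",
    "write_trace",
    "read_annotations",
    "write_annotations",
    "write_summary_table",
]

TRACE_FORMAT_VERSION = 1
ANNOTATION_FORMAT_VERSION = 1

PathLike = Union[str, Path]


class TraceFormatError(TorsadexError):
    """Malformed trace file; message names the offending line/field."""


class AnnotationFormatError(TorsadexError):
    """Malformed annotation file."""


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def write_trace(trace: SignalTrace, path: PathLike) -> None:
    path = Path(path)
    names = list(trace.channels)
    with path.open("w") as fh:
        fh.write(f"# torsadex-trace v{TRACE_FORMAT_VERSION}\n")
        fh.write(f"# sampling_rate_hz: {trace.fs!r}\n")
        chan_spec = ", ".join(f"{n}:{trace.units.get(n, '')}" for n in names)
        fh.write(f"# channels: {chan_spec}\n")
        fh.write(",".join(names) + "\n")
        cols = [trace.channels[n] for n in names]
        for row in zip(*cols):
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def read_trace(path: PathLike) -> SignalTrace:
    path = Path(path)
    header: list[str] = []
    with path.open() as fh:
        while True:
            line = fh.readline()
            if line.startswith("#"):
                header.append(line.rstrip("\n"))
            else:
                break
    if not header or not header[0].startswith("# torsadex-trace v"):
        raise TraceFormatError(f"{path}: line 1: missing 'torsadex-trace' magic header")
    try:
        version = int(header[0].split("v")[-1])
    except ValueError as exc:
        raise TraceFormatError(f"{path}: line 1: unparseable version field") from exc
    if version != TRACE_FORMAT_VERSION:
        raise TraceFormatError(
            f"{path}: unsupported trace format version {version} "
            f"(reader supports v{TRACE_FORMAT_VERSION})"
        )
    fs = None
    units: dict[str, str] = {}
    for i, line in enumerate(header[1:], start=2):
        body = line.lstrip("#").strip()
        if body.startswith("sampling_rate_hz:"):
            try:
                fs = float(body.split(":", 1)[1])
            except ValueError as exc:
                raise TraceFormatError(
                    f"{path}: line {i}: bad sampling_rate_hz value"
                ) from exc
        elif body.startswith("channels:"):
            for part in body.split(":", 1)[1].split(","):
                part = part.strip()
                if not part:
                    continue
                name, _, unit = part.partition(":")
                units[name.strip()] = unit.strip()
    if fs is None:
        raise TraceFormatError(f"{path}: header lacks 'sampling_rate_hz' field")
    if fs <= 0:
        raise TraceFormatError(f"{path}: sampling_rate_hz must be positive, got {fs}")

    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:
        raise TraceFormatError(f"{path}: unparseable CSV body: {exc}") from exc
    if df.empty:
        raise TraceFormatError(f"{path}: trace body contains no samples")
    for name in df.columns:
        col = df[name].to_numpy()
        if np.issubdtype(col.dtype, np.number) and np.isnan(col).any():
            first_bad = int(np.flatnonzero(np.isnan(col))[0])
            raise TraceFormatError(
                f"{path}: channel {name!r} is short/has missing values "
                f"(first at body row {first_bad + 1})"
            )
        if not np.issubdtype(col.dtype, np.number):
            raise TraceFormatError(f"{path}: channel {name!r} holds non-numeric values")
    unknown = set(units) - set(df.columns)
    if unknown:
        raise TraceFormatError(
            f"{path}: header declares channels {sorted(unknown)} missing from the body"
        )
    channels = {name: df[name].to_numpy(dtype=float) for name in df.columns}
    return SignalTrace(fs=fs, channels=channels, units={n: units.get(n, "") for n in channels})


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

_BEAT_FIELDS = (
    ("q_onset", "q_onset_ms"),
    ("qrs_end", "qrs_end_ms"),
    ("t_end", "t_end_ms"),
    ("p_onset", "p_onset_ms"),
    ("map_upstroke", "map_upstroke_ms"),
    ("map_end", "map_end_ms"),
    ("lv_mapd80", "lv_mapd80_ms"),
    ("rv_mapd80", "rv_mapd80_ms"),
)


def write_annotations(ann: Annotations, path: PathLike) -> None:
    path = Path(path)
    beats = []
    for b in ann.beats:
        rec: dict = {"label": b.label}
        for attr, key in _BEAT_FIELDS:
            val = getattr(b, attr)
            if val is not None:
                rec[key] = val
        beats.append(rec)
    events = []
    for ev in ann.events:
        events.append({
            "kind": ev.kind,
            "onset_s": ev.onset_s,
            "run_length": ev.run_length,
            "shocks": ev.shocks,
        })
    doc = {
        "format": "torsadex-annotations",
        "version": ANNOTATION_FORMAT_VERSION,
        "beats": beats,
        "p_onsets_ms": list(ann.p_onsets),
        "events": events,
        "defib_marks_ms": list(ann.defib_marks),
    }
    with path.open("w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_annotations(path: PathLike) -> Annotations:
    path = Path(path)
    try:
        with path.open() as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise AnnotationFormatError(f"{path}: invalid JSON: {exc}") from exc
    if doc.get("format") != "torsadex-annotations":
        raise AnnotationFormatError(f"{path}: missing 'torsadex-annotations' format tag")
    version = doc.get("version")
    if version != ANNOTATION_FORMAT_VERSION:
        raise AnnotationFormatError(
            f"{path}: unsupported annotation version {version!r} "
            f"(reader supports v{ANNOTATION_FORMAT_VERSION})"
        )
    beats = []
    for i, rec in enumerate(doc.get("beats", [])):
        kwargs = {"label": rec.get("label", "regular")}
        for attr, key in _BEAT_FIELDS:
            if key in rec:
                kwargs[attr] = float(rec[key])
        if "q_onset" not in kwargs:
            raise AnnotationFormatError(f"{path}: beat {i}: missing q_onset_ms")
        try:
            beats.append(BeatAnnotation(**kwargs))
        except ValidationError as exc:
            raise AnnotationFormatError(f"{path}: beat {i}: {exc}") from exc
    events = []
    for i, rec in enumerate(doc.get("events", [])):
        try:
            events.append(ScheduledEvent(**rec))
        except Exception as exc:
            raise AnnotationFormatError(f"{path}: event {i}: {exc}") from exc
    p_onsets = [float(t) for t in doc.get("p_onsets_ms", [])]
    if any(b > a for a, b in zip(p_onsets[1:], p_onsets)):
        raise AnnotationFormatError(f"{path}: p_onsets_ms must be non-decreasing")
    return Annotations(
        beats=beats,
        p_onsets=p_onsets,
        events=events,
        defib_marks=[float(t) for t in doc.get("defib_marks_ms", [])],
    )


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_summary_table(df: pd.DataFrame, path: PathLike) -> None:
    """Write a parameter-by-timepoint summary grid (mean ± SD layout) as CSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=True)


def format_mean_sd(mean: float, sd: float, ndigits: int = 0) -> str:
    if any(map(math.isnan, (mean, sd))):
        return "NA"
    if ndigits == 0:
        return f"{_round_half_away(mean):.0f} ± {_round_half_away(sd):.0f}"
    return f"{mean:.{ndigits}f} ± {sd:.{ndigits}f}"


def _round_half_away(x: float) -> float:
    """Round half away from zero (reporting convention for ms intervals)."""
    return math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1)
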