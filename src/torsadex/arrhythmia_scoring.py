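"""Arrhythmic-event taxonomy and the arrhythmia score (AS).

Point rubric: a regular beat scores 1, a single ectopic beat (sEB) 2,
multiple ectopic beats (mEB, 2-5 complexes) 3-5, Torsade de Pointes
(TdP, >= 6 complexes) 6-49, and defibrillated TdP (> 10 s, shocked)
50/75/100 for 1/2/>=3 shocks. Within the open 3-5 and 6-49 ranges the
adopted mapping is ``run_length + 1`` capped at 5 for mEB and
``run_length`` capped at 49 for TdP (consistent with sEB = 1 + 1 and
with the 6-complex TdP floor of 6 points).

The AS is the mean of the three highest-scored events in the 10 min
after challenge onset; missing slots are padded with the regular-beat
score of 1, so an event-free window scores exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .core import Annotations, BeatAnnotation, ValidationError

__all__ = [
    "ArrhythmiaEvent",
    "ASResult",
    "classify_runs",
    "score_event",
    "arrhythmia_score",
    "incidence_summary",
    "REGULAR_BEAT_POINTS",
    "AS_WINDOW_S",
]

REGULAR_BEAT_POINTS = 1.0
AS_WINDOW_S = 600.0

_KINDS = ("regular", "sEB", "mEB", "TdP", "defib-TdP")
_SEVERITY = {k: i for i, k in enumerate(_KINDS)}


@dataclass
class ArrhythmiaEvent:
    """A classified episode of consecutive ectopic complexes."""

    kind: str
    run_length: int
    onset_ms: float
    offset_ms: float
    shocks: int = 0
    orphan: bool = False  # set on synthetic warning records only

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.offset_ms < self.onset_ms:
            raise ValidationError("event offset before onset")
        if self.kind == "sEB" and self.run_length != 1:
            raise ValidationError("sEB requires run_length == 1")
        if self.kind == "mEB" and not (2 <= self.run_length <= 5):
            raise ValidationError("mEB requires 2 <= run_length <= 5")
        if self.kind == "TdP" and self.run_length < 6:
            raise ValidationError("TdP requires run_length >= 6")
        if self.kind == "defib-TdP":
            if self.shocks < 1:
                raise ValidationError("defib-TdP requires shocks >= 1")
            if self.duration_s <= 10.0:
                raise ValidationError(
                    f"defib-TdP requires duration > 10 s, got {self.duration_s:.2f} s"
                )

    @property
    def duration_s(self) -> float:
        return (self.offset_ms - self.onset_ms) / 1000.0

    @property
    def points(self) -> float:
        return score_event(self)


@dataclass
class ASResult:
    as_value: float
    contributing: list[float]
    window: tuple[float, float]
    any_seb: bool = False
    any_meb: bool = False
    any_tdp: bool = False
    warnings: list[str] = field(default_factory=list)


def score_event(event: ArrhythmiaEvent) -> float:
    """Points for one event under the severity rubric (see module docstring)."""
    k = event.kind
    if k == "regular":
        return REGULAR_BEAT_POINTS
    if k == "sEB":
        return 2.0
    if k == "mEB":
        return float(min(event.run_length + 1, 5))
    if k == "TdP":
        return float(min(event.run_length, 49))
    # defib-TdP
    return {1: 50.0, 2: 75.0}.get(event.shocks, 100.0)


def classify_runs(
    beats: Annotations | Sequence[BeatAnnotation],
    defib_marks: Optional[Sequence[float]] = None,
) -> list[ArrhythmiaEvent]:
    """Group maximal runs of consecutive ectopic complexes into events.

    Kind follows run length (1 -> sEB, 2-5 -> mEB, >= 6 -> TdP). A
    defibrillation mark falling inside an event upgrades it to defib-TdP
    and sets the shock count. Marks outside any event produce an orphan
    warning record (kind 'regular', ``orphan=True``) rather than an error.
    """
    if isinstance(beats, Annotations):
        if defib_marks is None:
            defib_marks = beats.defib_marks
        beat_list = beats.beats
    else:
        beat_list = list(beats)
    defib_marks = sorted(defib_marks or [])

    runs: list[list[BeatAnnotation]] = []
    cur: list[BeatAnnotation] = []
    for b in sorted(beat_list, key=lambda x: x.q_onset):
        if b.label == "ectopic":
            cur.append(b)
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)

    events: list[ArrhythmiaEvent] = []
    used_marks: set[float] = set()
    for run in runs:
        onset = run[0].q_onset
        last = run[-1]
        offset = last.qrs_end if last.qrs_end is not None else last.q_onset
        n = len(run)
        # marks may be logged up to ~one ectopic cycle after the last complex
        marks = [m for m in defib_marks if onset <= m <= offset + 200.0]
        used_marks.update(marks)
        if marks:
            events.append(ArrhythmiaEvent(
                kind="defib-TdP", run_length=n, onset_ms=onset,
                offset_ms=offset, shocks=len(marks)))
        elif n >= 6:
            events.append(ArrhythmiaEvent("TdP", n, onset, offset))
        elif n >= 2:
            events.append(ArrhythmiaEvent("mEB", n, onset, offset))
        else:
            events.append(ArrhythmiaEvent("sEB", 1, onset, offset))
    for m in defib_marks:
        if m not in used_marks:
            events.append(ArrhythmiaEvent(
                kind="regular", run_length=1, onset_ms=m, offset_ms=m, orphan=True))
    return sorted(events, key=lambda e: e.onset_ms)


def arrhythmia_score(
    events: Iterable[ArrhythmiaEvent],
    window_start_ms: float = 0.0,
    window_s: float = AS_WINDOW_S,
) -> ASResult:
    """Mean of the three highest event scores in the half-open window
    ``[window_start, window_start + window_s)``; events straddling the end
    count if their onset is inside. Fewer than three events pad with the
    regular-beat score, so an event-free window yields exactly 1.
    """
    lo = window_start_ms
    hi = window_start_ms + window_s * 1000.0
    warnings = []
    in_window = []
    for ev in events:
        if ev.orphan:
            warnings.append(f"orphan defibrillation mark at {ev.onset_ms:.0f} ms")
            continue
        if lo <= ev.onset_ms < hi and ev.kind != "regular":
            in_window.append(ev)
    points = sorted((score_event(ev) for ev in in_window), reverse=True)[:3]
    while len(points) < 3:
        points.append(REGULAR_BEAT_POINTS)
    value = sum(points) / 3.0
    kinds = {ev.kind for ev in in_window}
    return ASResult(
        as_value=value,
        contributing=points,
        window=(lo, hi),
        any_seb="sEB" in kinds,
        any_meb="mEB" in kinds,
        any_tdp=bool(kinds & {"TdP", "defib-TdP"}),
        warnings=warnings,
    )


def incidence_summary(
    per_subject_events: dict[str, Sequence[ArrhythmiaEvent]],
) -> dict[str, float]:
    """Fraction of subjects showing each event kind.

    Defibrillated TdP counts as TdP. Returns fractions for keys
    ``'sEB'``, ``'mEB'``, ``'TdP'``.
    """
    if not per_subject_events:
        raise ValidationError("need at least one subject")
    n = len(per_subject_events)
    counts = {"sEB": 0, "mEB": 0, "TdP": 0}
    for events in per_subject_events.values():
        kinds = {("TdP" if ev.kind == "defib-TdP" else ev.kind)
                 for ev in events if not ev.orphan}
        for k in counts:
            if k in kinds:
                counts[k] += 1
    return {k: c / n for k, c in counts.items()}
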