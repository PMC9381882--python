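"""Core containers shared by every analysis module.

Time convention: milliseconds from recording start, 0-based sample
indexing, intervals half-open ``[onset, offset)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "SignalTrace",
    "BeatAnnotation",
    "Annotations",
    "BEAT_LABELS",
    "TorsadexError",
    "ValidationError",
    "InsufficientDataError",
    "NoBeatsError",
]


class TorsadexError(Exception):
    """Base class for all package errors."""


class ValidationError(TorsadexError):
    """Input violates a documented contract."""


class InsufficientDataError(TorsadexError):
    """Fewer usable beats/cycles than the analysis requires."""


class NoBeatsError(TorsadexError):
    """No beat could be detected in the signal."""


BEAT_LABELS = ("regular", "ectopic", "paced", "defib_artifact")


@dataclass
class SignalTrace:
    """Uniformly sampled multichannel recording.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz.
    channels : dict[str, np.ndarray]
        Channel name -> 1-D sample vector. All channels must be equal length.
    units : dict[str, str]
        Channel name -> physical unit string (e.g. ``"mV"``, ``"mmHg"``).
    """

    fs: float
    channels: dict[str, np.ndarray]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if not self.channels:
            raise ValidationError("trace must contain at least one channel")
        lengths = {name: len(np.asarray(x)) for name, x in self.channels.items()}
        n = max(lengths.values())
        for name, ln in lengths.items():
            if ln != n:
                raise ValidationError(
                    f"channel {name!r} has {ln} samples, expected {n} "
                    "(all channels must be equal length)"
                )
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name in self.channels:
            self.units.setdefault(name, "")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.fs

    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * (1000.0 / self.fs)

    def get(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise ValidationError(
                f"channel {name!r} not present (have {sorted(self.channels)})"
            )
        return self.channels[name]

    def index_of(self, t_ms: float) -> int:
        """Sample index containing time ``t_ms`` (floor convention)."""
        return int(np.floor(t_ms * self.fs / 1000.0))


@dataclass
class BeatAnnotation:
    """Per-beat fiducials (ms from recording start) and a class label.

    Any fiducial may be ``None`` when it is not resolvable for that beat
    (e.g. ectopic complexes carry no T end). Present fiducials must obey
    ``p_onset <= q_onset < qrs_end < t_end``.
    """

    q_onset: float
    qrs_end: Optional[float] = None
    t_end: Optional[float] = None
    p_onset: Optional[float] = None
    map_upstroke: Optional[float] = None
    map_end: Optional[float] = None
    label: str = "regular"
    # generator ground truth, carried through serialization when available
    lv_mapd80: Optional[float] = None
    rv_mapd80: Optional[float] = None

    def __post_init__(self) -> None:
        if self.label not in BEAT_LABELS:
            raise ValidationError(
                f"unknown beat label {self.label!r}; expected one of {BEAT_LABELS}"
            )
        self.validate_order()

    def validate_order(self) -> None:
        if self.p_onset is not None and self.p_onset > self.q_onset:
            raise ValidationError(
                f"P onset {self.p_onset} ms after Q onset {self.q_onset} ms"
            )
        if self.qrs_end is not None and self.qrs_end <= self.q_onset:
            raise ValidationError(
                f"QRS end {self.qrs_end} ms not after Q onset {self.q_onset} ms"
            )
        if self.t_end is not None:
            if self.qrs_end is None:
                raise ValidationError("T end present without QRS end")
            if self.t_end <= self.qrs_end:
                raise ValidationError(
                    f"T end {self.t_end} ms not after QRS end {self.qrs_end} ms"
                )

    @property
    def qt_ms(self) -> Optional[float]:
        if self.t_end is None:
            return None
        return self.t_end - self.q_onset

    @property
    def qrs_ms(self) -> Optional[float]:
        if self.qrs_end is None:
            return None
        return self.qrs_end - self.q_onset


@dataclass
class Annotations:
    """Beat-level and event-level annotation of one recording.

    ``p_onsets`` carries the full atrial train (independent of the
    ventricular beats under AV dissociation); per-beat ``p_onset`` is the
    last atrial onset at or before that beat.
    """

    beats: list[BeatAnnotation] = field(default_factory=list)
    p_onsets: list[float] = field(default_factory=list)
    events: list = field(default_factory=list)  # list[ScheduledEvent-like]
    defib_marks: list[float] = field(default_factory=list)

    def __iter__(self):
        return iter(self.beats)

    def __len__(self) -> int:
        return len(self.beats)


def beats_sorted(beats: Iterable[BeatAnnotation]) -> list[BeatAnnotation]:
    return sorted(beats, key=lambda b: b.q_onset)
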