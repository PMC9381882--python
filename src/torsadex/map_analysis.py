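"""Monophasic action potential duration, short-term variability, and
exclusion filtering.

STV of a duration series D over n consecutive beats:

    STV = sum(|D[k+1] - D[k]|) / (n * sqrt(2))     ('sqrt2' mode, default)
    STV = sum(|D[k+1] - D[k]|) / (n * 2)           ('literal' mode)

The two modes differ by exactly sqrt(2). The default follows the
originating Poincare-dispersion convention; 'literal' reproduces the
plain-text divisor some reports print.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .core import (
    Annotations,
    BeatAnnotation,
    InsufficientDataError,
    SignalTrace,
    TorsadexError,
    ValidationError,
)

__all__ = [
    "DurationSeries",
    "STVResult",
    "mapd",
    "duration_at_repolarization",
    "mapd_series",
    "exclude_beats",
    "stv",
    "delta_mapd",
    "UnresolvedRepolarizationError",
]

P_ON_T_WINDOW_MS = 40.0  # default half-width of the T-end neighbourhood


class UnresolvedRepolarizationError(TorsadexError):
    """The waveform never recrosses the repolarization threshold."""


@dataclass
class DurationSeries:
    """Ordered per-beat durations with an exclusion mask.

    ``mask[k]`` is True when beat k is excluded; ``reasons[k]`` carries a
    machine-readable reason code (``""`` when included).
    """

    durations: np.ndarray
    source: str = "LV-MAP"
    beat_indices: Optional[np.ndarray] = None
    mask: Optional[np.ndarray] = None
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        if np.any(self.durations <= 0):
            raise ValidationError("durations must be positive")
        n = len(self.durations)
        if self.beat_indices is None:
            self.beat_indices = np.arange(n)
        else:
            self.beat_indices = np.asarray(self.beat_indices, dtype=int)
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.mask) != n or len(self.beat_indices) != n:
            raise ValidationError("mask/beat_indices length must match durations")
        if not self.reasons:
            self.reasons = [""] * n
        if len(self.reasons) != n:
            raise ValidationError("reasons length must match durations")

    def __len__(self) -> int:
        return len(self.durations)


@dataclass
class STVResult:
    stv: float
    n_pairs: int
    divisor_mode: str

    def __post_init__(self) -> None:
        if self.stv < 0:
            raise ValidationError("STV cannot be negative")


# ---------------------------------------------------------------------------
# per-beat duration measurement
# ---------------------------------------------------------------------------

def duration_at_repolarization(
    waveform: np.ndarray,
    fs: float,
    fraction: float = 0.80,
    baseline: Optional[float] = None,
    activation_index: Optional[float] = None,
) -> float:
    """Time (ms) from activation to the given repolarization fraction.

    Activation is the steepest upstroke; the duration ends at the first
    crossing of ``baseline + amplitude * (1 - fraction)`` after the peak,
    linearly interpolated between samples. ``baseline`` defaults to the
    median of the pre-upstroke (diastolic) segment.
    """
    if not (0 < fraction <= 1):
        raise ValidationError(f"repolarization fraction must be in (0, 1], got {fraction}")
    x = np.asarray(waveform, dtype=float)
    if len(x) < 4:
        raise ValidationError("waveform too short")
    d = np.diff(x)
    if activation_index is None:
        activation_index = int(np.argmax(d))  # steepest upstroke sample pair
        act = activation_index + 0.5
    else:
        act = float(activation_index)
    if baseline is None:
        pre = x[: max(int(act) - 1, 1)]
        baseline = float(np.median(pre)) if len(pre) else float(x[0])
    peak_idx = int(np.argmax(x[int(act):])) + int(act)
    amplitude = x[peak_idx] - baseline
    if amplitude <= 0:
        raise UnresolvedRepolarizationError("no positive deflection above baseline")
    level = baseline + amplitude * (1.0 - fraction)
    seg = x[peak_idx:]
    below = np.nonzero(seg <= level)[0]
    if len(below) == 0:
        raise UnresolvedRepolarizationError(
            f"waveform never repolarizes to {fraction:.0%} "
            f"(level {level:.3g}) within the beat window"
        )
    k = int(below[0])
    if k == 0:
        cross = float(peak_idx)
    else:
        y0, y1 = seg[k - 1], seg[k]
        frac = (y0 - level) / (y0 - y1)
        cross = peak_idx + (k - 1) + frac
    return (cross - act) * 1000.0 / fs


def mapd(
    waveform: np.ndarray,
    fs: float,
    repolarization_fraction: float = 0.80,
) -> float:
    """MAP duration at the given repolarization fraction (default MAPD80)."""
    return duration_at_repolarization(waveform, fs, repolarization_fraction)


def mapd_series(
    trace: SignalTrace,
    beats: Annotations | Sequence[BeatAnnotation],
    channel: str = "LV-MAP",
    fraction: float = 0.80,
) -> DurationSeries:
    """Measure per-beat MAP durations for every non-ectopic beat.

    Each beat window runs from shortly before the annotated MAP upstroke
    to the next beat's onset (or trace end).
    """
    beat_list = beats.beats if isinstance(beats, Annotations) else list(beats)
    sig = trace.get(channel)
    fs = trace.fs
    durations, indices = [], []
    for i, b in enumerate(beat_list):
        if b.label == "ectopic" or b.map_upstroke is None:
            continue
        start = b.map_upstroke - 30.0
        if i + 1 < len(beat_list):
            stop = beat_list[i + 1].q_onset
        else:
            stop = trace.duration_ms
        i0 = max(int(start * fs / 1000.0), 0)
        i1 = min(int(stop * fs / 1000.0), len(sig))
        if i1 - i0 < 10:
            continue
        try:
            dur = duration_at_repolarization(sig[i0:i1], fs, fraction)
        except UnresolvedRepolarizationError:
            continue
        durations.append(dur)
        indices.append(i)
    if not durations:
        raise InsufficientDataError(f"no measurable beats on channel {channel!r}")
    return DurationSeries(
        durations=np.array(durations),
        source=channel,
        beat_indices=np.array(indices),
    )


# ---------------------------------------------------------------------------
# exclusion filtering
# ---------------------------------------------------------------------------

def exclude_beats(
    series: DurationSeries,
    beats: Annotations | Sequence[BeatAnnotation],
    p_on_t_window_ms: float = P_ON_T_WINDOW_MS,
) -> DurationSeries:
    """Mask ectopic beats and beats with a P wave near the T-wave end.

    A beat is masked with reason ``p_on_t`` when any atrial onset falls
    within ``t_end +/- p_on_t_window_ms``; with reason ``ectopic`` when its
    class label says so. All other beats pass through untouched.
    """
    if isinstance(beats, Annotations):
        beat_list = beats.beats
        p_onsets = np.asarray(beats.p_onsets, dtype=float)
    else:
        beat_list = list(beats)
        p_onsets = np.array([b.p_onset for b in beat_list if b.p_onset is not None],
                            dtype=float)
    if np.max(series.beat_indices, initial=-1) >= len(beat_list):
        raise ValidationError("annotations do not cover the duration series")

    mask = series.mask.copy()
    reasons = list(series.reasons)
    for k, bi in enumerate(series.beat_indices):
        b = beat_list[int(bi)]
        if b.label == "ectopic":
            mask[k] = True
            reasons[k] = "ectopic"
            continue
        if b.t_end is not None and len(p_onsets):
            if np.any(np.abs(p_onsets - b.t_end) <= p_on_t_window_ms):
                mask[k] = True
                reasons[k] = "p_on_t"
    return replace(series, mask=mask, reasons=reasons)


# ---------------------------------------------------------------------------
# short-term variability
# ---------------------------------------------------------------------------

def stv(
    series: DurationSeries | Sequence[float] | np.ndarray,
    n_beats: int = 30,
    divisor_mode: str = "sqrt2",
) -> STVResult:
    """Short-term variability over ``n_beats`` consecutive unmasked pairs.

    Requires ``n_beats + 1`` consecutive unmasked durations; a masked beat
    invalidates both adjacent pairs (exclusions are not bridged). The first
    sufficiently long run is used.
    """
    if divisor_mode not in ("sqrt2", "literal"):
        raise ValidationError(f"unknown divisor mode {divisor_mode!r}")
    if n_beats < 1:
        raise ValidationError("n_beats must be >= 1")
    if not isinstance(series, DurationSeries):
        series = DurationSeries(durations=np.asarray(series, dtype=float))

    runs = _unmasked_runs(series)
    longest = max((len(r) for r in runs), default=0)
    chosen = next((r for r in runs if len(r) >= n_beats + 1), None)
    if chosen is None:
        raise InsufficientDataError(
            f"STV needs {n_beats + 1} consecutive unmasked beats; "
            f"longest available run is {longest}"
        )
    d = series.durations[chosen[: n_beats + 1]]
    total = float(np.sum(np.abs(np.diff(d))))
    divisor = n_beats * (np.sqrt(2.0) if divisor_mode == "sqrt2" else 2.0)
    return STVResult(stv=total / divisor, n_pairs=n_beats, divisor_mode=divisor_mode)


def _unmasked_runs(series: DurationSeries) -> list[np.ndarray]:
    """Maximal runs of unmasked positions that are also consecutive beats."""
    runs: list[list[int]] = []
    cur: list[int] = []
    for k in range(len(series)):
        consecutive = (
            not series.mask[k]
            and (not cur or series.beat_indices[k] == series.beat_indices[cur[-1]] + 1)
        )
        if consecutive:
            cur.append(k)
        else:
            if cur:
                runs.append(cur)
            cur = [k] if not series.mask[k] else []
    if cur:
        runs.append(cur)
    return [np.array(r) for r in runs]


def delta_mapd(lv: float, rv: float) -> float:
    """Spatial dispersion of repolarization: LV MAPD minus RV MAPD (signed)."""
    if not (np.isfinite(lv) and np.isfinite(rv)):
        raise ValidationError("both MAPD values must be finite")
    return lv - rv
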