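"""ECG interval measurement and derived repolarization indices.

T-end delineation uses the tangent method: the tangent at the steepest
point of the terminal T-wave downslope is extended to the isoelectric
baseline. QRS onset/end are refined the same way on the QRS limbs.
Supplied ground-truth annotations always take precedence over the
algorithmic delineator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .core import (
    Annotations,
    BeatAnnotation,
    InsufficientDataError,
    NoBeatsError,
    SignalTrace,
    ValidationError,
)

__all__ = [
    "IntervalSummary",
    "delineate",
    "measure_intervals",
    "jt",
    "qtc_van_de_water",
    "jtc",
    "select_timepoint",
    "VAN_DE_WATER_COEFF",
]

# Van de Water linear rate correction: QTc = QT - 0.087 * (RR - 1000)
VAN_DE_WATER_COEFF = 0.087

_NON_ECTOPIC = ("regular", "paced")


@dataclass
class IntervalSummary:
    """Per-timepoint interval means over consecutive complexes (ms)."""

    rr: float
    qrs: float
    qt: float
    jt: float
    qtc: float
    jtc: float
    pp: Optional[float] = None
    n_complexes: int = 0
    timepoint: str = ""

    def __post_init__(self) -> None:
        # subtraction identities hold exactly by construction; re-assert here
        if abs(self.jt - (self.qt - self.qrs)) > 1e-9:
            raise ValidationError("JT must equal QT - QRS")
        if abs(self.jtc - (self.qtc - self.qrs)) > 1e-9:
            raise ValidationError("JTc must equal QTc - QRS")


def jt(qt: float, qrs: float) -> float:
    """JT interval: QT minus QRS (depolarization excluded)."""
    if qrs < 0 or qt < qrs:
        raise ValidationError(f"need qt >= qrs >= 0, got qt={qt}, qrs={qrs}")
    return qt - qrs


def qtc_van_de_water(qt: float, rr: float) -> float:
    """Rate-corrected QT: ``QTc = QT - 0.087 * (RR - 1000)`` (ms).

    Identity at RR = 1000 ms; monotone decreasing in RR for fixed QT.
    """
    if qt <= 0 or rr <= 0:
        raise ValidationError(f"qt and rr must be positive, got qt={qt}, rr={rr}")
    return qt - VAN_DE_WATER_COEFF * (rr - 1000.0)


def jtc(qtc: float, qrs: float) -> float:
    """JTc interval: QTc minus QRS."""
    if qtc < qrs:
        raise ValidationError(f"need qtc >= qrs, got qtc={qtc}, qrs={qrs}")
    return qtc - qrs


# ---------------------------------------------------------------------------
# delineation
# ---------------------------------------------------------------------------

def delineate(
    trace: SignalTrace,
    annotations: Optional[Annotations | Sequence[BeatAnnotation]] = None,
    channel: str = "ECG",
) -> Annotations:
    """Detect beats and fiducials on the ECG channel.

    When ground-truth ``annotations`` are supplied they are returned
    verbatim (the study set markers manually; supplied markers always win).
    """
    if annotations is not None:
        if isinstance(annotations, Annotations):
            return annotations
        return Annotations(beats=list(annotations))

    ecg = trace.get(channel)
    fs = trace.fs
    if np.ptp(ecg) < 1e-9:
        raise NoBeatsError("flat-line ECG channel: no beats detectable")

    height = 0.45 * float(np.max(np.abs(ecg)))
    peaks, _ = find_peaks(np.abs(ecg), height=height, distance=int(0.18 * fs))
    if len(peaks) == 0:
        raise NoBeatsError("no QRS complexes detected")

    ms_per_sample = 1000.0 / fs
    deriv = _smooth_derivative(ecg, fs)

    beats: list[BeatAnnotation] = []
    for j, pk in enumerate(peaks):
        prev_pk = peaks[j - 1] if j > 0 else None
        next_pk = peaks[j + 1] if j + 1 < len(peaks) else None
        amp = abs(ecg[pk])
        q_onset = _edge_tangent(ecg, deriv, pk, amp, fs, direction=-1)
        qrs_end = _edge_tangent(ecg, deriv, pk, amp, fs, direction=+1)
        if q_onset is None or qrs_end is None or qrs_end <= q_onset:
            continue
        t_end = _t_end_tangent(ecg, deriv, fs, qrs_end, next_pk)
        beats.append(BeatAnnotation(
            q_onset=q_onset * ms_per_sample,
            qrs_end=qrs_end * ms_per_sample,
            t_end=None if t_end is None else t_end * ms_per_sample,
            label="regular",
        ))

    if not beats:
        raise NoBeatsError("no delineatable beats found")

    # coupling-interval heuristic for ectopy: premature relative to median RR
    onsets = np.array([b.q_onset for b in beats])
    if len(onsets) >= 3:
        rr = np.diff(onsets)
        med = float(np.median(rr))
        for i in range(1, len(beats)):
            if onsets[i] - onsets[i - 1] < 0.8 * med:
                beats[i].label = "ectopic"

    p_onsets = _detect_p_waves(ecg, fs, beats)
    for b in beats:
        prior = [t for t in p_onsets if t <= b.q_onset]
        b.p_onset = prior[-1] if prior else None
    return Annotations(beats=beats, p_onsets=p_onsets)


def _smooth_derivative(x: np.ndarray, fs: float, window_ms: float = 7.0) -> np.ndarray:
    w = max(int(round(window_ms * fs / 1000.0)) | 1, 5)
    return savgol_filter(x, w, 2, deriv=1, delta=1.0)


def _edge_tangent(ecg, deriv, pk, amp, fs, direction) -> Optional[float]:
    """Project the steepest limb slope to baseline to locate a QRS edge.

    Returns a fractional sample index, or None if no edge is found within
    a physiologic window.
    """
    span = int(0.12 * fs)  # QRS limbs live within ~120 ms of the peak
    if direction < 0:
        lo, hi = max(pk - span, 0), pk
    else:
        lo, hi = pk, min(pk + span, len(ecg) - 1)
    if hi <= lo:
        return None
    seg = np.arange(lo, hi + 1)
    # steepest slope with the correct sign for this limb and peak polarity
    sign = np.sign(ecg[pk]) * direction
    slopes = deriv[seg] * -sign
    k = seg[int(np.argmax(slopes))]
    slope = deriv[k]
    if abs(slope) < 1e-12:
        return None
    x = k - ecg[k] / slope
    return float(np.clip(x, lo, hi))


def _t_end_tangent(ecg, deriv, fs, qrs_end, next_pk) -> Optional[float]:
    lo = int(qrs_end + 0.02 * fs)
    hi = int(qrs_end + 0.62 * fs)
    if next_pk is not None:
        hi = min(hi, int(next_pk - 0.05 * fs))
    hi = min(hi, len(ecg) - 2)
    if hi <= lo + 3:
        return None
    window = ecg[lo:hi + 1]
    t_peak = lo + int(np.argmax(np.abs(window)))
    if t_peak >= hi:
        return None
    seg = np.arange(t_peak, hi + 1)
    polarity = np.sign(ecg[t_peak]) or 1.0
    slopes = deriv[seg] * -polarity  # steepest return toward baseline
    k = seg[int(np.argmax(slopes))]
    slope = deriv[k]
    if abs(slope) < 1e-12:
        return None
    x = k - ecg[k] / slope
    if not (t_peak <= x <= hi + 0.25 * fs):
        return None
    return float(x)


def _detect_p_waves(ecg, fs, beats) -> list[float]:
    """Low-amplitude rounded deflections outside the QRS-T spans."""
    mask = np.ones(len(ecg), dtype=bool)
    for b in beats:
        lo = int((b.q_onset - 15.0) * fs / 1000.0)
        hi = int(((b.t_end if b.t_end is not None else b.qrs_end or b.q_onset) + 30.0)
                 * fs / 1000.0)
        mask[max(lo, 0):min(hi, len(ecg))] = False
    masked = np.where(mask, ecg, 0.0)
    amp = float(np.max(masked)) if np.any(mask) else 0.0
    if amp < 1e-6:
        return []
    peaks, props = find_peaks(masked, height=0.5 * amp, distance=int(0.12 * fs))
    onsets = []
    for pk in peaks:
        h = masked[pk]
        i = pk
        while i > 0 and masked[i] > 0.05 * h and mask[i]:
            i -= 1
        onsets.append(i * 1000.0 / fs)
    return sorted(onsets)


# ---------------------------------------------------------------------------
# interval summaries
# ---------------------------------------------------------------------------

def measure_intervals(
    beats: Annotations | Sequence[BeatAnnotation],
    n: int = 5,
    p_onsets: Optional[Sequence[float]] = None,
    timepoint: str = "",
    window_ms: Optional[tuple[float, float]] = None,
) -> IntervalSummary:
    """Interval means over exactly ``n`` consecutive usable complexes.

    Ectopic complexes break consecutiveness; the first window of ``n``
    adjacent non-ectopic beats with full fiducials is used. RR/PP means
    use the ``n - 1`` successive onset differences inside the window.
    """
    if isinstance(beats, Annotations):
        if p_onsets is None:
            p_onsets = beats.p_onsets
        beat_list = beats.beats
    else:
        beat_list = list(beats)
    if window_ms is not None:
        lo, hi = window_ms
        beat_list = [b for b in beat_list if lo <= b.q_onset < hi]

    usable = [
        (i, b) for i, b in enumerate(beat_list)
        if b.label in _NON_ECTOPIC and b.t_end is not None and b.qrs_end is not None
    ]
    window = _first_consecutive_window(usable, n)
    if window is None:
        raise InsufficientDataError(
            f"need {n} consecutive usable complexes, have {len(usable)} usable "
            f"of {len(beat_list)} total (longest consecutive run "
            f"{_longest_run(usable)})"
        )

    qts = np.array([b.qt_ms for b in window])
    qrss = np.array([b.qrs_ms for b in window])
    onsets = np.array([b.q_onset for b in window])
    rr_mean = float(np.mean(np.diff(onsets))) if len(onsets) > 1 else float("nan")
    qt_mean = float(np.mean(qts))
    qrs_mean = float(np.mean(qrss))

    pp_mean: Optional[float] = None
    if p_onsets:
        lo, hi = onsets[0] - rr_mean if len(onsets) > 1 else onsets[0], onsets[-1]
        ps = [t for t in p_onsets if lo <= t <= hi]
        diffs = np.diff(ps)[: max(n - 1, 1)]
        if len(diffs):
            pp_mean = float(np.mean(diffs))

    qtc = qtc_van_de_water(qt_mean, rr_mean) if np.isfinite(rr_mean) else qt_mean
    return IntervalSummary(
        rr=rr_mean,
        pp=pp_mean,
        qrs=qrs_mean,
        qt=qt_mean,
        jt=jt(qt_mean, qrs_mean),
        qtc=qtc,
        jtc=jtc(qtc, qrs_mean),
        n_complexes=n,
        timepoint=timepoint,
    )


def _first_consecutive_window(usable, n):
    run: list = []
    for i, b in usable:
        if run and i != run[-1][0] + 1:
            run = []
        run.append((i, b))
        if len(run) == n:
            return [b for _, b in run]
    return None


def _longest_run(usable) -> int:
    best = cur = 0
    prev = None
    for i, _ in usable:
        cur = cur + 1 if prev is not None and i == prev + 1 else 1
        best = max(best, cur)
        prev = i
    return best


def select_timepoint(
    trace: SignalTrace,
    annotations: Annotations | Sequence[BeatAnnotation],
    infusion_onset_ms: float,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Baseline and drug-challenge analysis windows.

    The challenge window is anchored at 5 min after infusion onset, or at
    the first ectopic beat within those 5 min, whichever comes first.
    Returns half-open windows ``(0, onset)`` and ``(onset, anchor)``.
    """
    if not (0 <= infusion_onset_ms < trace.duration_ms):
        raise ValidationError(
            f"infusion onset {infusion_onset_ms} ms outside trace "
            f"[0, {trace.duration_ms:.0f}) ms"
        )
    beat_list = annotations.beats if isinstance(annotations, Annotations) else list(annotations)
    limit = infusion_onset_ms + 300_000.0
    anchor = limit
    for b in beat_list:
        if b.label == "ectopic" and infusion_onset_ms < b.q_onset <= limit:
            anchor = b.q_onset
            break
    anchor = min(anchor, trace.duration_ms)
    return (0.0, infusion_onset_ms), (infusion_onset_ms, anchor)
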