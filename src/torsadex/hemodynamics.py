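"""LV pressure cycle metrics and the electromechanical window."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .core import InsufficientDataError, SignalTrace, TorsadexError, ValidationError

__all__ = [
    "PressureCycleMetrics",
    "dpdt_extrema",
    "qlvp_end",
    "emw",
    "UnresolvedCycleError",
]

# derivative smoothing: odd Savitzky-Golay window (ms), polynomial order 2
DERIV_WINDOW_MS = 15.0
# cycle end: descending crossing of baseline + 5% of cycle amplitude
CYCLE_END_FRACTION = 0.05


class UnresolvedCycleError(TorsadexError):
    """Pressure never returns to its diastolic baseline."""


@dataclass
class PressureCycleMetrics:
    dpdt_max: float  # mmHg/s
    dpdt_min: float  # mmHg/s
    qlvp_end: Optional[float] = None  # ms
    emw: Optional[float] = None  # ms
    n_cycles: int = 0


def _smooth_dpdt(pressure: np.ndarray, fs: float, window_ms: float = DERIV_WINDOW_MS) -> np.ndarray:
    """Smoothed first derivative in mmHg/s."""
    w = max(int(round(window_ms * fs / 1000.0)) | 1, 5)
    if w >= len(pressure):
        w = (len(pressure) - 1) | 1
        if w < 5:
            raise InsufficientDataError("pressure segment too short for derivative")
    return savgol_filter(pressure, w, 2, deriv=1, delta=1.0 / fs)


def dpdt_extrema(
    segment: SignalTrace | np.ndarray,
    fs: Optional[float] = None,
    n_cycles: int = 5,
    channel: str = "LV-P",
) -> tuple[float, float]:
    """Mean per-cycle dP/dt max and min over ``n_cycles`` consecutive cycles.

    Cycles are located from prominent pressure peaks; when fewer than
    ``n_cycles`` complete cycles are present an error reports the count.
    A constant segment returns ``(0.0, 0.0)``.
    """
    if isinstance(segment, SignalTrace):
        pressure = segment.get(channel)
        fs = segment.fs
    else:
        pressure = np.asarray(segment, dtype=float)
        if fs is None:
            raise ValidationError("fs required when passing a bare array")

    if np.ptp(pressure) < 1e-12:
        return 0.0, 0.0

    dpdt = _smooth_dpdt(pressure, fs)
    amp = float(np.ptp(pressure))
    peaks, _ = find_peaks(pressure, prominence=0.5 * amp, distance=int(0.2 * fs))
    if len(peaks) < n_cycles:
        raise InsufficientDataError(
            f"need {n_cycles} complete pressure cycles, found {len(peaks)}"
        )
    maxima, minima = [], []
    bounds = _cycle_bounds(pressure, peaks, fs)
    for (lo, hi), pk in zip(bounds[:n_cycles], peaks[:n_cycles]):
        maxima.append(float(np.max(dpdt[lo:pk + 1])))
        minima.append(float(np.min(dpdt[pk:hi])))
    return float(np.mean(maxima)), float(np.mean(minima))


def _cycle_bounds(pressure: np.ndarray, peaks: np.ndarray, fs: float) -> list[tuple[int, int]]:
    bounds = []
    for j, pk in enumerate(peaks):
        lo = peaks[j - 1] if j > 0 else 0
        hi = peaks[j + 1] if j + 1 < len(peaks) else len(pressure) - 1
        # narrow to the valley on each side of the peak
        lo = lo + int(np.argmin(pressure[lo:pk + 1]))
        hi = pk + int(np.argmin(pressure[pk:hi + 1]))
        bounds.append((lo, max(hi, pk + 1)))
    return bounds


def qlvp_end(
    qrs_onset_ms: float,
    pressure: SignalTrace | np.ndarray,
    fs: Optional[float] = None,
    channel: str = "LV-P",
    end_fraction: float = CYCLE_END_FRACTION,
) -> float:
    """Duration (ms) from QRS onset to the end of the pressure cycle.

    Cycle end is the descending crossing of ``baseline + end_fraction *
    amplitude``, linearly interpolated. The cycle considered is the first
    one peaking after QRS onset.
    """
    if isinstance(pressure, SignalTrace):
        sig = pressure.get(channel)
        fs = pressure.fs
    else:
        sig = np.asarray(pressure, dtype=float)
        if fs is None:
            raise ValidationError("fs required when passing a bare array")
    start = int(qrs_onset_ms * fs / 1000.0)
    if not (0 <= start < len(sig) - 2):
        raise ValidationError(f"QRS onset {qrs_onset_ms} ms outside the pressure segment")

    seg = sig[start:]
    # denoise before threshold search; a 2nd-order Savitzky-Golay filter is
    # exact on the (piecewise-linear/half-sine-like) limbs away from corners
    w = max(int(round(21.0 * fs / 1000.0)) | 1, 5)
    if len(seg) > w:
        seg = savgol_filter(seg, w, 2)
    # baseline from the median: most of the segment is diastolic
    baseline = float(np.median(seg))
    amp = float(np.max(seg)) - baseline
    if amp <= 0:
        raise UnresolvedCycleError("flat pressure segment: no cycle after QRS onset")
    level = baseline + end_fraction * amp
    pk = int(np.argmax(seg))
    below = np.nonzero(seg[pk:] <= level)[0]
    if len(below) == 0:
        raise UnresolvedCycleError(
            "pressure does not return to the diastolic baseline after the peak"
        )
    k = int(below[0])
    if k == 0:
        cross = float(pk)
    else:
        y0, y1 = seg[pk + k - 1], seg[pk + k]
        cross = pk + k - 1 + (y0 - level) / (y0 - y1)
    return cross * 1000.0 / fs


def emw(qlvp_end_ms: float, qt_ms: float) -> float:
    """Electromechanical window: QLVPend minus QT (ms, may be negative)."""
    if not (np.isfinite(qlvp_end_ms) and np.isfinite(qt_ms)):
        raise ValidationError("both durations must be finite")
    return qlvp_end_ms - qt_ms


def pressure_metrics(
    segment: SignalTrace,
    qrs_onset_ms: Optional[float] = None,
    qt_ms: Optional[float] = None,
    n_cycles: int = 5,
    channel: str = "LV-P",
) -> PressureCycleMetrics:
    """Convenience bundle of all pressure-derived indices."""
    dmax, dmin = dpdt_extrema(segment, n_cycles=n_cycles, channel=channel)
    q_end = e = None
    if qrs_onset_ms is not None:
        q_end = qlvp_end(qrs_onset_ms, segment, channel=channel)
        if qt_ms is not None:
            e = emw(q_end, qt_ms)
    return PressureCycleMetrics(dpdt_max=dmax, dpdt_min=dmin, qlvp_end=q_end,
                                emw=e, n_cycles=n_cycles)
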