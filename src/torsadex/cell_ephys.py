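"""Patch-clamp current decomposition and cellular action-potential metrics.

Drug-subtraction scheme: the slow delayed-rectifier component is the
current removed by HMR-1556, and the fast component is the current
additionally removed by dofetilide; the remainder is residual. Tail
amplitudes are measured at the -50 mV segment after the +60 mV step,
relative to the settled level (mean of the segment's final 10%) — the
source reports do not state a baseline convention, so the settled-level
reference is a documented choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import InsufficientDataError, SignalTrace, TorsadexError, ValidationError
from .map_analysis import DurationSeries, duration_at_repolarization, stv as _stv
from .synthetic_signals import PatchClampRecording

__all__ = [
    "VoltageProtocol",
    "PatchClampRecording",
    "APMetrics",
    "tail_current",
    "current_density",
    "decompose_currents",
    "decompose_tail_values",
    "CurrentDecomposition",
    "ap_metrics",
    "ProtocolMismatchError",
    "RundownWarning",
]

SETTLED_FRACTION = 0.10  # final fraction of the tail segment taken as settled
HEADLINE_STEP_MV = 60


class ProtocolMismatchError(TorsadexError):
    """Recording does not contain the required protocol step."""


class RundownWarning(UserWarning):
    """A subtraction produced a negative component beyond noise tolerance."""


@dataclass(frozen=True)
class VoltageProtocol:
    """Ordered fixed steps plus a variable-step family.

    ``steps`` lists (level_mV, duration_ms) with ``None`` marking the
    variable step; ``step_levels_mv`` enumerates its levels.
    """

    steps: tuple[tuple[Optional[float], float], ...]
    step_levels_mv: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(d <= 0 for _, d in self.steps):
            raise ValidationError("all step durations must be positive")
        if sum(1 for lvl, _ in self.steps if lvl is None) != 1:
            raise ValidationError("protocol needs exactly one variable step")
        if not self.step_levels_mv:
            raise ValidationError("variable step needs at least one level")

    @classmethod
    def default(cls) -> "VoltageProtocol":
        """Standard tail protocol: -80 (100), -40 (500), variable -20..+60
        in 10 mV increments (2000), -50 (1000), -80 (150), -100 (200), -80 (100)."""
        return cls(
            steps=(
                (-80.0, 100.0),
                (-40.0, 500.0),
                (None, 2000.0),
                (-50.0, 1000.0),
                (-80.0, 150.0),
                (-100.0, 200.0),
                (-80.0, 100.0),
            ),
            step_levels_mv=tuple(range(-20, 61, 10)),
        )

    @property
    def total_duration_ms(self) -> float:
        return sum(d for _, d in self.steps)

    def tail_window_ms(self) -> tuple[float, float]:
        """Start/end (ms) of the repolarizing segment following the variable step."""
        t = 0.0
        seen_variable = False
        for lvl, dur in self.steps:
            if seen_variable:
                return t, t + dur
            if lvl is None:
                seen_variable = True
            t += dur
        raise ValidationError("protocol lacks a segment after the variable step")


@dataclass
class APMetrics:
    apd90: float
    apd50: float
    stv: Optional[float] = None
    n_aps: int = 0

    def __post_init__(self) -> None:
        if not (self.apd90 >= self.apd50 > 0):
            raise ValidationError(
                f"need apd90 >= apd50 > 0, got {self.apd90}, {self.apd50}"
            )


# ---------------------------------------------------------------------------
# tail currents
# ---------------------------------------------------------------------------

def tail_current(
    recording: PatchClampRecording,
    condition: str,
    step_mv: int = HEADLINE_STEP_MV,
) -> float:
    """Peak tail current (pA) relative to the settled level, sign-preserving.

    Measured on the repolarizing segment after the given depolarizing step
    (headline: +60 mV). The settled level is the mean of the segment's
    final 10%.
    """
    if condition not in recording.sweeps:
        raise ValidationError(
            f"condition {condition!r} absent (have {sorted(recording.sweeps)})"
        )
    per_step = recording.sweeps[condition]
    if step_mv not in per_step:
        raise ProtocolMismatchError(
            f"no sweep for the {step_mv:+d} mV step in condition {condition!r}"
        )
    sweep = np.asarray(per_step[step_mv], dtype=float)
    on_ms, off_ms = recording.protocol.tail_window_ms()
    i0 = int(round(on_ms * recording.fs / 1000.0))
    i1 = min(int(round(off_ms * recording.fs / 1000.0)), len(sweep))
    seg = sweep[i0:i1]
    if len(seg) < 10:
        raise ProtocolMismatchError("tail segment missing or too short in sweep")
    n_settle = max(int(len(seg) * SETTLED_FRACTION), 1)
    settled = float(np.mean(seg[-n_settle:]))
    rel = seg - settled
    k = int(np.argmax(np.abs(rel)))
    return float(rel[k])


def current_density(tail_pa: float, capacitance_pf: float) -> float:
    """Capacitance-normalized current (pA/pF)."""
    if capacitance_pf <= 0:
        raise ValidationError(f"capacitance must be positive, got {capacitance_pf}")
    return tail_pa / capacitance_pf


@dataclass
class CurrentDecomposition:
    iks: float
    ikr: float
    residual: float
    total: float
    fractions: dict[str, float]
    unit: str = "pA/pF"
    rundown_flags: list[str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rundown_flags is None:
            self.rundown_flags = []


def decompose_currents(
    recording: PatchClampRecording,
    step_mv: int = HEADLINE_STEP_MV,
    noise_tolerance_pa: float = 0.0,
    normalize: bool = True,
) -> CurrentDecomposition:
    """Pharmacological subtraction into slow/fast components and residual.

    ``slow = baseline - hmr1556``; ``fast = hmr1556 - hmr1556_dofetilide``;
    ``residual = hmr1556_dofetilide``. Fractions are each component over
    the baseline tail. Components telescope to the baseline tail exactly.
    A negative component beyond ``noise_tolerance_pa`` raises a
    RundownWarning (flagged, never clipped).
    """
    required = PatchClampRecording.CONDITIONS
    missing = [c for c in required if c not in recording.sweeps]
    if missing:
        raise ValidationError(f"missing drug conditions: {missing}")
    tails = {c: tail_current(recording, c, step_mv) for c in required}
    iks = tails["baseline"] - tails["hmr1556"]
    ikr = tails["hmr1556"] - tails["hmr1556_dofetilide"]
    residual = tails["hmr1556_dofetilide"]
    total = tails["baseline"]

    flags = []
    for name, val in (("slow (HMR-sensitive)", iks), ("fast (dofetilide-sensitive)", ikr)):
        if val < -abs(noise_tolerance_pa):
            msg = f"{name} component negative ({val:.2f} pA): possible rundown"
            flags.append(msg)
            warnings.warn(msg, RundownWarning)

    if total != 0:
        fractions = {"iks": iks / total, "ikr": ikr / total, "residual": residual / total}
    else:
        fractions = {"iks": float("nan"), "ikr": float("nan"), "residual": float("nan")}

    scale = recording.capacitance_pf if normalize else 1.0
    return CurrentDecomposition(
        iks=iks / scale,
        ikr=ikr / scale,
        residual=residual / scale,
        total=total / scale,
        fractions=fractions,
        unit="pA/pF" if normalize else "pA",
        rundown_flags=flags,
    )


def decompose_tail_values(
    baseline: float, hmr1556: float, hmr1556_dofetilide: float
) -> tuple[float, float, float, dict[str, float]]:
    """Pure arithmetic form of the subtraction scheme on three tail values.

    Returns (slow, fast, residual, fractions-of-baseline).
    """
    iks = baseline - hmr1556
    ikr = hmr1556 - hmr1556_dofetilide
    residual = hmr1556_dofetilide
    fractions = (
        {"iks": iks / baseline, "ikr": ikr / baseline, "residual": residual / baseline}
        if baseline != 0
        else {"iks": float("nan"), "ikr": float("nan"), "residual": float("nan")}
    )
    return iks, ikr, residual, fractions


# ---------------------------------------------------------------------------
# action potentials
# ---------------------------------------------------------------------------

def ap_metrics(
    trace: SignalTrace | np.ndarray,
    fs: Optional[float] = None,
    channel: str = "AP",
    period_ms: float = 2000.0,
    stv_beats: int = 30,
) -> APMetrics:
    """APD90/APD50 (mean over the train) and STV of the APD90 series.

    The train is segmented at the stimulation period; each AP is measured
    with the same threshold-crossing rule as MAP durations. STV requires
    at least ``stv_beats + 1`` action potentials and is reported as None
    on shorter (but >= 1 AP) trains.
    """
    if isinstance(trace, SignalTrace):
        sig = trace.get(channel)
        fs = trace.fs
    else:
        sig = np.asarray(trace, dtype=float)
        if fs is None:
            raise ValidationError("fs required when passing a bare array")
    samples_per_ap = int(round(period_ms * fs / 1000.0))
    n_aps = len(sig) // samples_per_ap
    if n_aps < 1:
        raise InsufficientDataError("trace shorter than one stimulation period")

    apd90s, apd50s = [], []
    for k in range(n_aps):
        seg = sig[k * samples_per_ap:(k + 1) * samples_per_ap]
        apd90s.append(duration_at_repolarization(seg, fs, 0.90))
        apd50s.append(duration_at_repolarization(seg, fs, 0.50))
    apd90s = np.array(apd90s)
    apd50s = np.array(apd50s)

    stv_val: Optional[float] = None
    if n_aps >= stv_beats + 1:
        stv_val = _stv(DurationSeries(durations=apd90s, source="cellular-AP"),
                       n_beats=stv_beats).stv
    return APMetrics(
        apd90=float(np.mean(apd90s)),
        apd50=float(np.mean(apd50s)),
        stv=stv_val,
        n_aps=n_aps,
    )
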