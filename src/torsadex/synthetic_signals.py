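"""Seeded in-silico recordings with exact ground truth.

Generates paced bradycardic rhythms with AV dissociation, drug-induced
repolarization prolongation with growing beat-to-beat variability,
scheduled ectopy / tachyarrhythmia runs, LV pressure cycles, and
voltage-clamp sweep sets with configurable current components.

Beat morphology is piecewise analytic (triangular QRS, half-cosine rise +
linear-descent T wave, trapezoidal MAP) so that every fiducial has an
exact closed-form location. The terminal T-wave limb is linear, which
makes the tangent delineation method exact on noiseless signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .core import Annotations, BeatAnnotation, SignalTrace, ValidationError

__all__ = [
    "DrugRamp",
    "RhythmSpec",
    "ScheduledEvent",
    "EventSchedule",
    "SweepSpec",
    "generate_rhythm",
    "generate_pressure",
    "generate_sweeps",
    "generate_ap_train",
    "ar1_series",
    "ar1_sigma_for_stv",
    "expected_stv",
    "EVENT_KINDS",
]

EVENT_KINDS = ("sEB", "mEB", "TdP", "defib-TdP")

# cycle length of ectopic complexes inside a run (ms)
ECTOPIC_CYCLE_MS = 250.0
# refractory pause inserted after an ectopic run before the paced grid resumes
POST_EVENT_PAUSE_MS = 400.0
# first paced beat is offset from t=0 so every beat has a diastolic baseline
GRID_PAD_MS = 40.0

_MAP_RISE_MS = 6.0  # half-cosine upstroke duration
_MAP_LATENCY_MS = 2.0  # MAP upstroke lag behind Q onset
_MAP_AMPLITUDE = 25.0
_T_DOWNSTROKE_MS = 60.0  # linear terminal limb of the T wave
_T_RISE_MS = 80.0
_T_AMPLITUDE = 0.35
_R_AMPLITUDE = 1.1
_P_WIDTH_MS = 70.0
_P_AMPLITUDE = 0.15


class DrugRamp(BaseModel):
    """Exponential saturation of the QT/MAPD increment after infusion onset.

    The underlying study reports only endpoint means, not a time course;
    the saturating-exponential shape is a documented stand-in.
    """

    onset_s: float = Field(ge=0)
    qt_increment_ms: float = Field(ge=0)
    tau_s: float = Field(gt=0)

    def increment_at(self, t_ms: float) -> float:
        dt = t_ms / 1000.0 - self.onset_s
        if dt <= 0:
            return 0.0
        return self.qt_increment_ms * (1.0 - math.exp(-dt / self.tau_s))


class RhythmSpec(BaseModel):
    """Parameters of a synthetic paced rhythm."""

    ventricular_rate: float = Field(default=60.0, gt=0, description="beats/min")
    atrial_rate: Optional[float] = Field(
        default=None, gt=0, description="beats/min; None disables the P train"
    )
    duration_s: float = Field(gt=0)
    qt_baseline_ms: float = Field(default=360.0, gt=0)
    qrs_width_ms: float = Field(default=60.0, gt=0)
    stv_target_ms: float = Field(default=0.0, ge=0)
    ar_phi: float = Field(default=0.4, gt=-1, lt=1)
    drug_ramp: Optional[DrugRamp] = None
    mapd_lv_base_ms: float = Field(default=250.0, gt=0)
    mapd_rv_base_ms: float = Field(default=222.0, gt=0)
    noise_sd: float = Field(default=0.0, ge=0, description="additive Gaussian SD, signal units")
    seed: int = 0

    @model_validator(mode="after")
    def _check_intervals(self) -> "RhythmSpec":
        rr = 60000.0 / self.ventricular_rate
        if self.qt_baseline_ms >= rr:
            raise ValueError(
                f"qt_baseline_ms ({self.qt_baseline_ms}) must be shorter than "
                f"the ventricular cycle length ({rr:.1f} ms)"
            )
        if self.qt_baseline_ms < self.qrs_width_ms + _T_RISE_MS + _T_DOWNSTROKE_MS + 20:
            raise ValueError("qt_baseline_ms too short for the QRS/T-wave templates")
        return self

    @property
    def rr_ms(self) -> float:
        return 60000.0 / self.ventricular_rate


class ScheduledEvent(BaseModel):
    onset_s: float = Field(ge=0)
    kind: str
    run_length: int = Field(ge=1)
    shocks: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "ScheduledEvent":
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}; expected {EVENT_KINDS}")
        if self.kind == "sEB" and self.run_length != 1:
            raise ValueError("sEB must have run_length 1")
        if self.kind == "mEB" and not (2 <= self.run_length <= 5):
            raise ValueError("mEB must have run_length 2..5")
        if self.kind == "TdP" and self.run_length < 6:
            raise ValueError("TdP requires run_length >= 6")
        if self.kind == "defib-TdP":
            if self.shocks < 1:
                raise ValueError("defib-TdP requires shocks >= 1")
            if self.run_length * ECTOPIC_CYCLE_MS <= 10_000:
                raise ValueError(
                    "defib-TdP must last > 10 s: needs run_length > "
                    f"{int(10_000 / ECTOPIC_CYCLE_MS)} at {ECTOPIC_CYCLE_MS:.0f} ms cycle length"
                )
        return self

    @property
    def span_ms(self) -> tuple[float, float]:
        onset = self.onset_s * 1000.0
        return onset, onset + self.run_length * ECTOPIC_CYCLE_MS


class EventSchedule(BaseModel):
    events: list[ScheduledEvent] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check_overlap(self) -> "EventSchedule":
        spans = sorted(ev.span_ms for ev in self.events)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1 + POST_EVENT_PAUSE_MS:
                raise ValueError(
                    f"events overlap: [{a0:.0f}, {a1:.0f}) ms and [{b0:.0f}, {b1:.0f}) ms"
                )
        return self

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)


class SweepSpec(BaseModel):
    """Ground-truth composition of a voltage-clamp sweep set."""

    capacitance_pf: float = Field(gt=0)
    iks_amplitude_pa: float = Field(ge=0)
    ikr_amplitude_pa: float = Field(ge=0)
    leak_amplitude_pa: float = Field(default=0.0, ge=0)
    noise_sd_pa: float = Field(default=0.0, ge=0)
    seed: int = 0


# ---------------------------------------------------------------------------
# beat-to-beat variability model
# ---------------------------------------------------------------------------

def ar1_series(n: int, sigma: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary zero-mean AR(1) sequence x_{k+1} = phi*x_k + eps, eps~N(0, sigma^2)."""
    x = np.empty(n)
    if n == 0:
        return x
    if sigma == 0:
        x[:] = 0.0
        return x
    x[0] = rng.normal(0.0, sigma / math.sqrt(1.0 - phi * phi))
    eps = rng.normal(0.0, sigma, size=n - 1)
    for k in range(1, n):
        x[k] = phi * x[k - 1] + eps[k - 1]
    return x


def expected_stv(sigma: float, phi: float, mode: str = "sqrt2") -> float:
    """Closed-form expected STV of a stationary AR(1) duration series.

    Successive differences are Gaussian with variance ``2*sigma^2/(1+phi)``;
    for centered Gaussian Z, ``E|Z| = sd * sqrt(2/pi)``. STV divides the mean
    absolute difference by sqrt(2) (``sqrt2`` mode) or 2 (``literal`` mode).
    """
    sd_diff = math.sqrt(2.0 * sigma * sigma / (1.0 + phi))
    mean_abs = sd_diff * math.sqrt(2.0 / math.pi)
    if mode == "sqrt2":
        return mean_abs / math.sqrt(2.0)
    if mode == "literal":
        return mean_abs / 2.0
    raise ValidationError(f"unknown STV divisor mode {mode!r}")


def ar1_sigma_for_stv(stv_target: float, phi: float, mode: str = "sqrt2") -> float:
    """Innovation SD that gives the requested expected STV (inverse of expected_stv)."""
    if stv_target == 0:
        return 0.0
    unit = expected_stv(1.0, phi, mode)
    return stv_target / unit


# ---------------------------------------------------------------------------
# waveform primitives (each writes into `sig` in place)
# ---------------------------------------------------------------------------

def _add_triangle(sig: np.ndarray, fs: float, onset_ms: float, width_ms: float,
                  amplitude: float) -> None:
    """Isoceles triangle: 0 at onset, peak at midpoint, 0 at onset+width."""
    t0 = onset_ms * fs / 1000.0
    t1 = (onset_ms + width_ms) * fs / 1000.0
    i0, i1 = int(math.ceil(t0)), int(math.floor(t1))
    i0 = max(i0, 0)
    i1 = min(i1, len(sig) - 1)
    if i1 < i0:
        return
    idx = np.arange(i0, i1 + 1)
    frac = (idx - t0) / (t1 - t0)
    sig[idx] += amplitude * (1.0 - np.abs(2.0 * frac - 1.0))


def _add_raised_cosine(sig: np.ndarray, fs: float, onset_ms: float, width_ms: float,
                       amplitude: float) -> None:
    t0 = onset_ms * fs / 1000.0
    t1 = (onset_ms + width_ms) * fs / 1000.0
    i0, i1 = max(int(math.ceil(t0)), 0), min(int(math.floor(t1)), len(sig) - 1)
    if i1 < i0:
        return
    idx = np.arange(i0, i1 + 1)
    frac = (idx - t0) / (t1 - t0)
    sig[idx] += amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * frac))


def _add_t_wave(sig: np.ndarray, fs: float, t_end_ms: float, amplitude: float) -> None:
    """Half-cosine rise to the peak, then a linear limb hitting 0 exactly at t_end."""
    peak_ms = t_end_ms - _T_DOWNSTROKE_MS
    rise0 = peak_ms - _T_RISE_MS
    # rise: 0 -> A over [rise0, peak]
    t0 = rise0 * fs / 1000.0
    t1 = peak_ms * fs / 1000.0
    i0, i1 = max(int(math.ceil(t0)), 0), min(int(math.floor(t1)), len(sig) - 1)
    if i1 >= i0:
        idx = np.arange(i0, i1 + 1)
        frac = (idx - t0) / (t1 - t0)
        sig[idx] += amplitude * 0.5 * (1.0 - np.cos(np.pi * frac))
    # linear descent: A -> 0 over [peak, t_end]
    t2 = t_end_ms * fs / 1000.0
    j0, j1 = max(int(math.floor(t1)) + 1, 0), min(int(math.floor(t2)), len(sig) - 1)
    if j1 >= j0:
        idx = np.arange(j0, j1 + 1)
        frac = (idx - t1) / (t2 - t1)
        sig[idx] += amplitude * (1.0 - frac)


def _add_map_beat(sig: np.ndarray, fs: float, upstroke_ms: float, mapd80_ms: float,
                  amplitude: float = _MAP_AMPLITUDE) -> tuple[float, float]:
    """Trapezoidal MAP: half-cosine rise, flat plateau, linear repolarization.

    ``mapd80_ms`` is exact by construction: activation (steepest upstroke) is
    the rise midpoint; the 20%-amplitude level is crossed at
    activation + mapd80. Returns (activation_ms, map_end_ms).
    """
    act = upstroke_ms + _MAP_RISE_MS / 2.0
    plateau_len = 0.5 * mapd80_ms
    # the 0.2*A level is crossed 0.8*decay_len after plateau end; choose
    # decay_len so that plateau_len + 0.8*decay_len == mapd80_ms
    decay_len = (mapd80_ms - plateau_len) / 0.8
    plateau_end = act + plateau_len
    map_end = plateau_end + decay_len

    # rise
    t0 = upstroke_ms * fs / 1000.0
    t1 = (upstroke_ms + _MAP_RISE_MS) * fs / 1000.0
    i0, i1 = max(int(math.ceil(t0)), 0), min(int(math.floor(t1)), len(sig) - 1)
    if i1 >= i0:
        idx = np.arange(i0, i1 + 1)
        frac = (idx - t0) / (t1 - t0)
        sig[idx] += amplitude * 0.5 * (1.0 - np.cos(np.pi * frac))
    # plateau
    t2 = plateau_end * fs / 1000.0
    j0, j1 = max(int(math.floor(t1)) + 1, 0), min(int(math.floor(t2)), len(sig) - 1)
    if j1 >= j0:
        sig[j0:j1 + 1] += amplitude
    # linear decay to baseline
    t3 = map_end * fs / 1000.0
    k0, k1 = max(int(math.floor(t2)) + 1, 0), min(int(math.floor(t3)), len(sig) - 1)
    if k1 >= k0:
        idx = np.arange(k0, k1 + 1)
        frac = (idx - t2) / (t3 - t2)
        sig[idx] += amplitude * (1.0 - frac)
    return act, map_end


# ---------------------------------------------------------------------------
# rhythm generation
# ---------------------------------------------------------------------------

def _regular_grid(spec: RhythmSpec) -> np.ndarray:
    """Q-onset times of the underlying paced grid (before event insertion)."""
    rr = spec.rr_ms
    dur = spec.duration_s * 1000.0
    tail_margin = spec.qt_baseline_ms + 150.0
    if spec.drug_ramp is not None:
        tail_margin += spec.drug_ramp.qt_increment_ms
    n = int(math.floor((dur - GRID_PAD_MS - tail_margin) / rr)) + 1
    if n < 1:
        raise ValidationError(
            f"duration {spec.duration_s} s too short for a single beat "
            f"(cycle {rr:.0f} ms + repolarization margin {tail_margin:.0f} ms)"
        )
    return GRID_PAD_MS + rr * np.arange(n)


def generate_rhythm(
    spec: RhythmSpec,
    schedule: EventSchedule | Sequence[ScheduledEvent] | None = None,
) -> tuple[SignalTrace, Annotations]:
    """Generate ECG + LV/RV MAP channels with ground-truth annotations.

    The duration series carries the configured mean exactly (the AR(1)
    deviations are demeaned, which leaves successive differences — and
    hence STV — untouched).
    """
    if schedule is None:
        schedule = EventSchedule()
    elif not isinstance(schedule, EventSchedule):
        schedule = EventSchedule(events=list(schedule))

    dur_ms = spec.duration_s * 1000.0
    for ev in schedule:
        on, off = ev.span_ms
        if off + POST_EVENT_PAUSE_MS > dur_ms:
            raise ValidationError(
                f"scheduled {ev.kind} at {ev.onset_s} s does not fit within the "
                f"{spec.duration_s} s recording"
            )

    fs = 1000.0
    n_samples = int(round(dur_ms * fs / 1000.0))
    rng = np.random.default_rng(spec.seed)

    grid = _regular_grid(spec)

    # drop paced beats shadowed by a scheduled event (with refractory pause)
    keep = np.ones(len(grid), dtype=bool)
    rr = spec.rr_ms
    for ev in schedule:
        on, off = ev.span_ms
        keep &= ~((grid + spec.qt_baseline_ms + 200.0 > on) & (grid < off + POST_EVENT_PAUSE_MS))
    onsets = grid[keep]
    n_beats = len(onsets)
    if n_beats < 1:
        raise ValidationError("schedule leaves no regular beats in the recording")

    sigma = ar1_sigma_for_stv(spec.stv_target_ms, spec.ar_phi)
    dev_qt = ar1_series(n_beats, sigma, spec.ar_phi, rng)
    dev_lv = ar1_series(n_beats, sigma, spec.ar_phi, rng)
    dev_rv = ar1_series(n_beats, sigma, spec.ar_phi, rng)
    for d in (dev_qt, dev_lv, dev_rv):
        if len(d):
            d -= d.mean()

    ramp = spec.drug_ramp
    qt = np.array([
        spec.qt_baseline_ms + (ramp.increment_at(t) if ramp else 0.0) + dev_qt[i]
        for i, t in enumerate(onsets)
    ])
    lv_mapd = np.array([
        spec.mapd_lv_base_ms + (0.8 * ramp.increment_at(t) if ramp else 0.0) + dev_lv[i]
        for i, t in enumerate(onsets)
    ])
    rv_mapd = np.array([
        spec.mapd_rv_base_ms + (0.6 * ramp.increment_at(t) if ramp else 0.0) + dev_rv[i]
        for i, t in enumerate(onsets)
    ])

    ecg = np.zeros(n_samples)
    lv_map = np.zeros(n_samples)
    rv_map = np.zeros(n_samples)

    # independent atrial train (AV dissociation)
    p_onsets: list[float] = []
    if spec.atrial_rate is not None:
        pp = 60000.0 / spec.atrial_rate
        t = GRID_PAD_MS / 2.0
        while t + _P_WIDTH_MS < dur_ms:
            p_onsets.append(t)
            _add_raised_cosine(ecg, fs, t, _P_WIDTH_MS, _P_AMPLITUDE)
            t += pp

    beats: list[BeatAnnotation] = []
    for i, t0 in enumerate(onsets):
        _add_triangle(ecg, fs, t0, spec.qrs_width_ms, _R_AMPLITUDE)
        t_end = t0 + qt[i]
        _add_t_wave(ecg, fs, t_end, _T_AMPLITUDE)
        act_lv, end_lv = _add_map_beat(lv_map, fs, t0 + _MAP_LATENCY_MS, lv_mapd[i])
        act_rv, end_rv = _add_map_beat(rv_map, fs, t0 + _MAP_LATENCY_MS + 4.0, rv_mapd[i])
        p_before = _last_at_or_before(p_onsets, t0)
        beats.append(BeatAnnotation(
            q_onset=float(t0),
            qrs_end=float(t0 + spec.qrs_width_ms),
            t_end=float(t_end),
            p_onset=p_before,
            map_upstroke=float(act_lv),
            map_end=float(end_lv),
            label="paced",
            lv_mapd80=float(lv_mapd[i]),
            rv_mapd80=float(rv_mapd[i]),
        ))

    # scheduled ectopy: fast, amplitude/axis-modulated complexes, no T wave
    defib_marks: list[float] = []
    for ev in schedule:
        on, _ = ev.span_ms
        width = 80.0
        for k in range(ev.run_length):
            t0 = on + k * ECTOPIC_CYCLE_MS
            amp = _R_AMPLITUDE * (0.55 + 0.45 * abs(math.sin(math.pi * k / 6.0)))
            sign = 1.0 if (k // 6) % 2 == 0 else -1.0
            _add_triangle(ecg, fs, t0, width, sign * amp)
            beats.append(BeatAnnotation(
                q_onset=float(t0),
                qrs_end=float(t0 + width),
                label="ectopic",
            ))
        if ev.kind == "defib-TdP":
            # shocks delivered around the end of the run
            off = ev.span_ms[1]
            defib_marks.extend(off - 100.0 - 20.0 * s for s in range(ev.shocks))

    beats.sort(key=lambda b: b.q_onset)

    if spec.noise_sd > 0:
        ecg += rng.normal(0.0, spec.noise_sd, n_samples)
        lv_map += rng.normal(0.0, spec.noise_sd, n_samples)
        rv_map += rng.normal(0.0, spec.noise_sd, n_samples)

    trace = SignalTrace(
        fs=fs,
        channels={"ECG": ecg, "LV-MAP": lv_map, "RV-MAP": rv_map},
        units={"ECG": "mV", "LV-MAP": "mV", "RV-MAP": "mV"},
    )
    ann = Annotations(
        beats=beats,
        p_onsets=p_onsets,
        events=list(schedule),
        defib_marks=sorted(defib_marks),
    )
    return trace, ann


def _last_at_or_before(times: Sequence[float], t: float) -> Optional[float]:
    idx = np.searchsorted(times, t, side="right") - 1
    if idx < 0:
        return None
    return float(times[idx])


# ---------------------------------------------------------------------------
# pressure generation
# ---------------------------------------------------------------------------

def generate_pressure(
    spec: RhythmSpec,
    contractility: float,
    systole_ms: float = 350.0,
    emd_ms: float = 30.0,
    noise_sd: float = 0.0,
) -> SignalTrace:
    """One half-sine pressure cycle per paced beat.

    ``contractility`` is the ground-truth dP/dt_max in mmHg/s. For a
    half-sine of amplitude A and half-period T, dP/dt_max = A*pi/T, so the
    amplitude is ``contractility * (systole_ms/1000) / pi``.
    """
    if contractility <= 0:
        raise ValidationError(f"contractility must be positive, got {contractility}")
    fs = 1000.0
    n_samples = int(round(spec.duration_s * 1000.0))
    sig = np.zeros(n_samples)
    amplitude = contractility * (systole_ms / 1000.0) / math.pi
    for t0 in _regular_grid(spec):
        on = t0 + emd_ms
        i0 = max(int(math.ceil(on * fs / 1000.0)), 0)
        i1 = min(int(math.floor((on + systole_ms) * fs / 1000.0)), n_samples - 1)
        if i1 < i0:
            continue
        idx = np.arange(i0, i1 + 1)
        frac = (idx - on * fs / 1000.0) / (systole_ms * fs / 1000.0)
        sig[idx] += amplitude * np.sin(np.pi * frac)
    if noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 1)
        sig += rng.normal(0.0, noise_sd, n_samples)
    return SignalTrace(fs=fs, channels={"LV-P": sig}, units={"LV-P": "mmHg"})


# ---------------------------------------------------------------------------
# voltage-clamp sweeps
# ---------------------------------------------------------------------------

_IKS_TAU_MS = 300.0
_IKR_TAU_MS = 120.0


def _tail_shape(t_ms: np.ndarray, tau: float, seg_len: float) -> np.ndarray:
    """Exponential decay, faded linearly to exactly 0 by 85% of the segment.

    The last 10% of the tail segment is therefore exactly at the settled
    (leak) level, which makes peak-minus-settled recover the configured
    amplitude to numerical precision on noiseless sweeps.
    """
    g = np.exp(-t_ms / tau)
    fade0, fade1 = 0.80 * seg_len, 0.85 * seg_len
    fade = np.clip((fade1 - t_ms) / (fade1 - fade0), 0.0, 1.0)
    return g * fade


def _activation(v_mv: float, v_half: float, slope: float) -> float:
    return 1.0 / (1.0 + math.exp(-(v_mv - v_half) / slope))


@dataclass
class PatchClampRecording:
    """Voltage-clamp sweep sets (one per drug condition) sharing a protocol."""

    fs: float
    capacitance_pf: float
    protocol: "VoltageProtocol"
    sweeps: dict[str, dict[int, np.ndarray]]
    truth: dict[str, float] = field(default_factory=dict)

    CONDITIONS = ("baseline", "hmr1556", "hmr1556_dofetilide")

    def __post_init__(self) -> None:
        if self.capacitance_pf <= 0:
            raise ValidationError(
                f"capacitance must be positive, got {self.capacitance_pf}"
            )
        for cond in self.sweeps:
            if cond not in self.CONDITIONS:
                raise ValidationError(
                    f"unknown condition {cond!r}; expected one of {self.CONDITIONS}"
                )


def generate_sweeps(spec: SweepSpec, protocol: "VoltageProtocol | None" = None) -> PatchClampRecording:
    """Three-condition sweep set: HMR-1556 removes the slow component, the
    subsequent dofetilide addition removes the fast one as well.

    Configured amplitudes are the peak tail currents (relative to the
    settled level) after the +60 mV step.
    """
    from .cell_ephys import VoltageProtocol  # local import avoids a cycle

    if protocol is None:
        protocol = VoltageProtocol.default()
    fs = 1000.0
    rng = np.random.default_rng(spec.seed)
    n = int(round(protocol.total_duration_ms * fs / 1000.0))
    tail_on, tail_off = protocol.tail_window_ms()
    seg_len = tail_off - tail_on

    sweeps: dict[str, dict[int, np.ndarray]] = {}
    components = {
        "baseline": (spec.iks_amplitude_pa, spec.ikr_amplitude_pa),
        "hmr1556": (0.0, spec.ikr_amplitude_pa),
        "hmr1556_dofetilide": (0.0, 0.0),
    }
    g60_ks = _activation(60.0, 20.0, 12.0)
    g60_kr = _activation(60.0, 0.0, 9.0)
    for cond, (a_ks, a_kr) in components.items():
        per_step: dict[int, np.ndarray] = {}
        for v in protocol.step_levels_mv:
            sig = np.full(n, spec.leak_amplitude_pa)
            i0 = int(round(tail_on * fs / 1000.0))
            i1 = int(round(tail_off * fs / 1000.0))
            t = (np.arange(i0, min(i1, n)) - i0) * 1000.0 / fs
            scale_ks = _activation(v, 20.0, 12.0) / g60_ks
            scale_kr = _activation(v, 0.0, 9.0) / g60_kr
            tail = (a_ks * scale_ks * _tail_shape(t, _IKS_TAU_MS, seg_len)
                    + a_kr * scale_kr * _tail_shape(t, _IKR_TAU_MS, seg_len))
            sig[i0:i0 + len(t)] += tail
            if spec.noise_sd_pa > 0:
                sig = sig + rng.normal(0.0, spec.noise_sd_pa, n)
            per_step[int(v)] = sig
        sweeps[cond] = per_step

    return PatchClampRecording(
        fs=fs,
        capacitance_pf=spec.capacitance_pf,
        protocol=protocol,
        sweeps=sweeps,
        truth={
            "iks_pa": spec.iks_amplitude_pa,
            "ikr_pa": spec.ikr_amplitude_pa,
            "leak_pa": spec.leak_amplitude_pa,
        },
    )


# ---------------------------------------------------------------------------
# cellular action potentials
# ---------------------------------------------------------------------------

def generate_ap_train(
    n_aps: int,
    apd90_base_ms: float = 300.0,
    stv_target_ms: float = 0.0,
    amplitude_mv: float = 120.0,
    rest_mv: float = -80.0,
    period_ms: float = 2000.0,
    ar_phi: float = 0.4,
    seed: int = 0,
) -> SignalTrace:
    """Current-clamp AP train at a fixed stimulation period (0.5 Hz default).

    Each AP is an instantaneous-rise, linear-repolarization template whose
    APD90 equals the per-beat value of an AR(1) duration series (demeaned,
    so the train mean equals ``apd90_base_ms`` exactly).
    """
    if n_aps < 1:
        raise ValidationError("need at least one action potential")
    fs = 1000.0
    n = int(round(n_aps * period_ms * fs / 1000.0))
    sig = np.full(n, rest_mv)
    rng = np.random.default_rng(seed)
    sigma = ar1_sigma_for_stv(stv_target_ms, ar_phi)
    dev = ar1_series(n_aps, sigma, ar_phi, rng)
    if len(dev):
        dev -= dev.mean()
    for k in range(n_aps):
        apd90 = apd90_base_ms + dev[k]
        repol_len = apd90 / 0.9  # linear decay: 90% level crossed at 0.9*length
        t0 = k * period_ms + 100.0
        i0 = int(math.ceil(t0 * fs / 1000.0))
        i1 = min(int(math.floor((t0 + repol_len) * fs / 1000.0)), n - 1)
        if i1 < i0:
            continue
        idx = np.arange(i0, i1 + 1)
        frac = (idx - t0 * fs / 1000.0) / (repol_len * fs / 1000.0)
        sig[idx] = rest_mv + amplitude_mv * (1.0 - frac)
    return SignalTrace(fs=fs, channels={"AP": sig}, units={"AP": "mV"})
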