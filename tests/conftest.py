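import numpy as np
import pytest

from torsadex import synthetic_signals as ss


@pytest.fixture(scope="session")
def paced_rhythm():
    """60 s of clean paced rhythm at 60 bpm with an atrial train at 110/min."""
    spec = ss.RhythmSpec(duration_s=60.0, atrial_rate=110.0, seed=11)
    trace, ann = ss.generate_rhythm(spec)
    return spec, trace, ann


@pytest.fixture(scope="session")
def quiet_rhythm():
    """60 s paced rhythm, no atrial train, mild variability."""
    spec = ss.RhythmSpec(duration_s=60.0, stv_target_ms=1.0, seed=5)
    trace, ann = ss.generate_rhythm(spec)
    return spec, trace, ann


@pytest.fixture(scope="session")
def eventful_rhythm():
    """120 s rhythm with one event of each kind."""
    schedule = ss.EventSchedule(events=[
        ss.ScheduledEvent(onset_s=20.0, kind="sEB", run_length=1),
        ss.ScheduledEvent(onset_s=40.0, kind="mEB", run_length=3),
        ss.ScheduledEvent(onset_s=60.0, kind="TdP", run_length=8),
        ss.ScheduledEvent(onset_s=90.0, kind="defib-TdP", run_length=45, shocks=1),
    ])
    spec = ss.RhythmSpec(duration_s=120.0, seed=7)
    trace, ann = ss.generate_rhythm(spec, schedule)
    return spec, schedule, trace, ann


def make_beat_window(fs=1000.0, baseline=0.0, amplitude=1.0, pre=100,
                     decay_samples=300):
    """Instantaneous upstroke to `amplitude`, linear decay to baseline."""
    x = np.full(pre, baseline)
    decay = baseline + amplitude * (1.0 - np.arange(decay_samples + 1) / decay_samples)
    return np.concatenate([x, decay])
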