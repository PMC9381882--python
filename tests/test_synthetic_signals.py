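import math

import numpy as np
import pytest

from torsadex import map_analysis as ma
from torsadex import synthetic_signals as ss
from torsadex.core import ValidationError


class TestRhythmSpecValidation:
    def test_qt_longer_than_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle length"):
            ss.RhythmSpec(ventricular_rate=120.0, duration_s=10.0, qt_baseline_ms=600.0)

    def test_negative_stv_rejected(self):
        with pytest.raises(ValueError):
            ss.RhythmSpec(duration_s=10.0, stv_target_ms=-1.0)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            ss.RhythmSpec(ventricular_rate=0.0, duration_s=10.0)


class TestEventSchedule:
    def test_overlapping_events_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ss.EventSchedule(events=[
                ss.ScheduledEvent(onset_s=10.0, kind="TdP", run_length=8),
                ss.ScheduledEvent(onset_s=11.0, kind="sEB", run_length=1),
            ])

    def test_tdp_run_length_floor(self):
        with pytest.raises(ValueError, match="run_length >= 6"):
            ss.ScheduledEvent(onset_s=0.0, kind="TdP", run_length=5)

    def test_defib_requires_shock(self):
        with pytest.raises(ValueError, match="shocks >= 1"):
            ss.ScheduledEvent(onset_s=0.0, kind="defib-TdP", run_length=50, shocks=0)

    def test_defib_requires_long_run(self):
        with pytest.raises(ValueError, match="10 s"):
            ss.ScheduledEvent(onset_s=0.0, kind="defib-TdP", run_length=10, shocks=1)


class TestGenerateRhythm:
    def test_seeded_determinism_bit_identical(self):
        spec = ss.RhythmSpec(duration_s=20.0, stv_target_ms=1.5, noise_sd=0.01, seed=42)
        t1, a1 = ss.generate_rhythm(spec)
        t2, a2 = ss.generate_rhythm(spec)
        for name in t1.channels:
            np.testing.assert_array_equal(t1.channels[name], t2.channels[name])
        assert [b.q_onset for b in a1.beats] == [b.q_onset for b in a2.beats]

    def test_60bpm_60s_gives_60_beats_rr_1000(self):
        spec = ss.RhythmSpec(ventricular_rate=60.0, duration_s=60.0)
        _, ann = ss.generate_rhythm(spec)
        assert len(ann.beats) == 60
        onsets = np.array([b.q_onset for b in ann.beats])
        np.testing.assert_array_equal(np.diff(onsets), 1000.0)
        assert all(b.label == "paced" for b in ann.beats)

    def test_mean_qt_matches_configuration(self):
        spec = ss.RhythmSpec(duration_s=120.0, qt_baseline_ms=340.0,
                             stv_target_ms=2.0, seed=9)
        _, ann = ss.generate_rhythm(spec)
        qts = np.array([b.qt_ms for b in ann.beats])
        assert abs(qts.mean() - 340.0) < 1.0  # within one sample

    def test_stv_recovered_downstream_within_15pct(self):
        spec = ss.RhythmSpec(duration_s=1000.0, stv_target_ms=2.0, seed=3)
        trace, ann = ss.generate_rhythm(spec)
        series = ma.mapd_series(trace, ann, channel="LV-MAP")
        assert len(series) >= 1000
        res = ma.stv(series, n_beats=len(series) - 1)
        assert res.stv == pytest.approx(2.0, rel=0.15)

    def test_scheduled_events_annotated_with_exact_run_lengths(self):
        schedule = ss.EventSchedule(events=[
            ss.ScheduledEvent(onset_s=15.0, kind="mEB", run_length=4),
            ss.ScheduledEvent(onset_s=30.0, kind="TdP", run_length=7),
        ])
        spec = ss.RhythmSpec(duration_s=60.0, seed=1)
        _, ann = ss.generate_rhythm(spec, schedule)
        ect = [b for b in ann.beats if b.label == "ectopic"]
        assert len(ect) == 11
        assert len(ann.events) == 2

    def test_schedule_beyond_duration_rejected(self):
        spec = ss.RhythmSpec(duration_s=20.0)
        with pytest.raises(ValidationError, match="does not fit"):
            ss.generate_rhythm(spec, [ss.ScheduledEvent(onset_s=19.0, kind="TdP",
                                                        run_length=8)])

    def test_duration_too_short_rejected(self):
        with pytest.raises(ValidationError, match="too short"):
            ss.generate_rhythm(ss.RhythmSpec(duration_s=0.3))

    def test_av_dissociated_p_train_independent(self):
        spec = ss.RhythmSpec(duration_s=30.0, atrial_rate=120.0, seed=2)
        _, ann = ss.generate_rhythm(spec)
        pp = np.diff(ann.p_onsets)
        np.testing.assert_allclose(pp, 500.0)

    def test_fiducials_consistent(self, quiet_rhythm):
        _, _, ann = quiet_rhythm
        for b in ann.beats:
            assert b.q_onset < b.qrs_end < b.t_end
            assert b.lv_mapd80 > 0 and b.rv_mapd80 > 0


class TestVariabilityModel:
    def test_expected_stv_closed_form_matches_monte_carlo(self):
        # oracle: direct Monte-Carlo of E|D_{n+1}-D_n|/sqrt(2) on the AR(1) model
        rng = np.random.default_rng(0)
        sigma, phi = 1.3, 0.4
        x = ss.ar1_series(200_000, sigma, phi, rng)
        mc = np.mean(np.abs(np.diff(x))) / math.sqrt(2.0)
        assert ss.expected_stv(sigma, phi) == pytest.approx(mc, rel=0.01)

    def test_sigma_inversion_round_trip(self):
        sigma = ss.ar1_sigma_for_stv(2.0, 0.4)
        assert ss.expected_stv(sigma, 0.4) == pytest.approx(2.0, rel=1e-12)

    def test_zero_target_gives_constant_series(self):
        rng = np.random.default_rng(1)
        assert np.all(ss.ar1_series(100, 0.0, 0.4, rng) == 0.0)


class TestGeneratePressure:
    def test_half_sine_dpdt_closed_form(self):
        # analytic template: amplitude A, half-period T -> dP/dt_max = A*pi/T
        from torsadex import hemodynamics as hd
        contractility = 1500.0
        trace = ss.generate_pressure(ss.RhythmSpec(duration_s=20.0), contractility)
        dmax, dmin = hd.dpdt_extrema(trace)
        assert dmax == pytest.approx(contractility, rel=0.01)
        assert dmin == pytest.approx(-contractility, rel=0.01)

    def test_zero_contractility_rejected(self):
        with pytest.raises(ValidationError):
            ss.generate_pressure(ss.RhythmSpec(duration_s=10.0), 0.0)

    def test_deterministic_without_noise(self):
        spec = ss.RhythmSpec(duration_s=10.0, seed=4)
        a = ss.generate_pressure(spec, 1200.0)
        b = ss.generate_pressure(spec, 1200.0)
        np.testing.assert_array_equal(a.channels["LV-P"], b.channels["LV-P"])


class TestGenerateSweeps:
    def test_zero_iks_makes_baseline_equal_hmr(self):
        spec = ss.SweepSpec(capacitance_pf=100.0, iks_amplitude_pa=0.0,
                            ikr_amplitude_pa=350.0)
        rec = ss.generate_sweeps(spec)
        np.testing.assert_array_equal(rec.sweeps["baseline"][60],
                                      rec.sweeps["hmr1556"][60])

    def test_noiseless_amplitudes_exact(self):
        from torsadex.cell_ephys import tail_current
        spec = ss.SweepSpec(capacitance_pf=100.0, iks_amplitude_pa=300.0,
                            ikr_amplitude_pa=400.0, leak_amplitude_pa=30.0)
        rec = ss.generate_sweeps(spec)
        base = tail_current(rec, "baseline")
        hmr = tail_current(rec, "hmr1556")
        both = tail_current(rec, "hmr1556_dofetilide")
        assert base - hmr == pytest.approx(300.0, abs=1e-9)
        assert hmr - both == pytest.approx(400.0, abs=1e-9)

    def test_noisy_recovery_unbiased(self):
        # oracle: 20 seeded replicates; the mean recovered amplitude must sit
        # within 2 standard errors of the configured truth
        from torsadex.cell_ephys import tail_current
        iks = np.empty(20)
        for i in range(20):
            spec = ss.SweepSpec(capacitance_pf=100.0, iks_amplitude_pa=300.0,
                                ikr_amplitude_pa=400.0, noise_sd_pa=5.0, seed=i)
            rec = ss.generate_sweeps(spec)
            iks[i] = tail_current(rec, "baseline") - tail_current(rec, "hmr1556")
        se = iks.std(ddof=1) / math.sqrt(len(iks))
        assert abs(iks.mean() - 300.0) <= 2.0 * se + 1e-9

    def test_seeded_determinism(self):
        spec = ss.SweepSpec(capacitance_pf=80.0, iks_amplitude_pa=100.0,
                            ikr_amplitude_pa=200.0, noise_sd_pa=3.0, seed=9)
        r1 = ss.generate_sweeps(spec)
        r2 = ss.generate_sweeps(spec)
        np.testing.assert_array_equal(r1.sweeps["baseline"][60],
                                      r2.sweeps["baseline"][60])


class TestApTrain:
    def test_linear_repolarization_thresholds(self):
        # amplitude 120 mV, APD90 300 -> linear decay over 333.3 ms, APD50 = 166.7
        from torsadex.cell_ephys import ap_metrics
        trace = ss.generate_ap_train(5, apd90_base_ms=300.0)
        m = ap_metrics(trace)
        assert m.apd90 == pytest.approx(300.0, abs=1.0)
        assert m.apd50 == pytest.approx(300.0 / 0.9 * 0.5, abs=1.0)
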