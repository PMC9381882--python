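import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from torsadex import arrhythmia_scoring as ar
from torsadex.core import BeatAnnotation, ValidationError


def _beats(labels, rr=1000.0):
    out = []
    for i, lab in enumerate(labels):
        t0 = rr * i
        out.append(BeatAnnotation(q_onset=t0, qrs_end=t0 + 80.0,
                                  label="ectopic" if lab == "E" else "regular"))
    return out


def _event(kind, run_length, shocks=0, onset=0.0, duration_s=None):
    if duration_s is None:
        duration_s = run_length * 0.25
    return ar.ArrhythmiaEvent(kind=kind, run_length=run_length, onset_ms=onset,
                              offset_ms=onset + duration_s * 1000.0, shocks=shocks)


def brute_force_as(points):
    """Oracle: maximum mean over all 3-subsets of the padded score list."""
    padded = list(points) + [1.0, 1.0, 1.0]
    return max(sum(c) for c in itertools.combinations(padded, 3)) / 3.0


class TestScoreEvent:
    def test_seb_scores_2(self):
        assert ar.score_event(_event("sEB", 1)) == 2.0

    @pytest.mark.parametrize("run,points", [(2, 3.0), (3, 4.0), (4, 5.0), (5, 5.0)])
    def test_meb_mapping(self, run, points):
        assert ar.score_event(_event("mEB", run)) == points

    @pytest.mark.parametrize("run,points", [(6, 6.0), (17, 17.0), (49, 49.0), (80, 49.0)])
    def test_tdp_mapping_run_length_capped_at_49(self, run, points):
        assert ar.score_event(_event("TdP", run)) == points

    @pytest.mark.parametrize("shocks,points", [(1, 50.0), (2, 75.0), (3, 100.0), (5, 100.0)])
    def test_defib_shock_mapping(self, shocks, points):
        ev = _event("defib-TdP", 50, shocks=shocks, duration_s=12.0)
        assert ar.score_event(ev) == points

    def test_regular_scores_1(self):
        assert ar.score_event(_event("regular", 1)) == 1.0

    def test_inconsistent_kind_run_rejected(self):
        with pytest.raises(ValidationError):
            _event("sEB", 3)
        with pytest.raises(ValidationError):
            _event("mEB", 7)
        with pytest.raises(ValidationError):
            _event("TdP", 4)

    def test_defib_requires_duration_over_10s(self):
        with pytest.raises(ValidationError, match="10 s"):
            _event("defib-TdP", 50, shocks=1, duration_s=8.0)

    @given(st.integers(2, 60), st.integers(1, 10))
    @settings(max_examples=60)
    def test_score_nondecreasing_in_run_and_shocks(self, run, run_delta):
        def kind_for(r):
            return "sEB" if r == 1 else ("mEB" if r <= 5 else "TdP")

        a = ar.score_event(_event(kind_for(run), run))
        b = ar.score_event(_event(kind_for(run + run_delta), run + run_delta))
        assert b >= a

    def test_shock_monotonicity(self):
        scores = [ar.score_event(_event("defib-TdP", 50, shocks=s, duration_s=12.0))
                  for s in (1, 2, 3, 4)]
        assert scores == sorted(scores)


class TestClassifyRuns:
    def test_single_ectopic_is_seb(self):
        events = ar.classify_runs(_beats("RRER"))
        assert [e.kind for e in events] == ["sEB"]

    def test_run_of_6_is_tdp(self):
        events = ar.classify_runs(_beats("R" + "E" * 6 + "R"))
        assert [e.kind for e in events] == ["TdP"]
        assert events[0].run_length == 6

    def test_run_of_2_to_5_is_meb(self):
        for k in (2, 3, 4, 5):
            events = ar.classify_runs(_beats("R" + "E" * k + "R"))
            assert [e.kind for e in events] == ["mEB"]
            assert events[0].run_length == k

    def test_defib_mark_upgrades_event(self):
        # 48 fast complexes at 250 ms -> 12 s run, one shock at the end
        beats = []
        for i in range(5):
            beats.append(BeatAnnotation(q_onset=1000.0 * i, qrs_end=1000.0 * i + 80))
        t0 = 6000.0
        for k in range(48):
            beats.append(BeatAnnotation(q_onset=t0 + 250.0 * k,
                                        qrs_end=t0 + 250.0 * k + 80.0,
                                        label="ectopic"))
        events = ar.classify_runs(beats, defib_marks=[t0 + 47 * 250.0 + 60.0])
        assert [e.kind for e in events] == ["defib-TdP"]
        assert events[0].shocks == 1
        assert events[0].duration_s > 10.0

    def test_orphan_mark_produces_warning_record(self):
        events = ar.classify_runs(_beats("RRRR"), defib_marks=[1500.0])
        assert len(events) == 1
        assert events[0].orphan

    def test_multiple_runs_separate_events(self):
        events = ar.classify_runs(_beats("RERREER" + "E" * 7 + "R"))
        assert [e.kind for e in events] == ["sEB", "mEB", "TdP"]

    def test_generated_schedule_recovered_exactly(self, eventful_rhythm):
        _, schedule, _, ann = eventful_rhythm
        events = [e for e in ar.classify_runs(ann) if not e.orphan]
        assert [(e.kind, e.run_length) for e in events] == [
            (ev.kind, ev.run_length) for ev in schedule
        ]
        defib = [e for e in events if e.kind == "defib-TdP"]
        assert defib[0].shocks == 1


class TestArrhythmiaScore:
    def test_event_free_window_scores_1(self):
        res = ar.arrhythmia_score([])
        assert res.as_value == 1.0
        assert res.contributing == [1.0, 1.0, 1.0]

    def test_printed_defib_dog_1867(self):
        events = [_event("defib-TdP", 50, shocks=1, duration_s=12.0),
                  _event("mEB", 2, onset=20_000.0),
                  _event("mEB", 2, onset=40_000.0)]
        res = ar.arrhythmia_score(events)
        assert res.as_value == pytest.approx(56.0 / 3.0)
        assert round(res.as_value, 1) == 18.7

    def test_printed_self_terminating_dog_767(self):
        events = [_event("TdP", 9, onset=1000.0),
                  _event("TdP", 8, onset=30_000.0),
                  _event("TdP", 6, onset=60_000.0)]
        res = ar.arrhythmia_score(events)
        assert res.as_value == pytest.approx(23.0 / 3.0)
        assert round(res.as_value, 1) == 7.7

    def test_single_event_padded_with_regular(self):
        res = ar.arrhythmia_score([_event("sEB", 1)])
        assert res.as_value == pytest.approx(4.0 / 3.0)

    def test_events_outside_window_ignored(self):
        inside = _event("sEB", 1, onset=1000.0)
        outside = _event("TdP", 20, onset=700_000.0)
        res = ar.arrhythmia_score([inside, outside])
        assert res.as_value == pytest.approx((2.0 + 1.0 + 1.0) / 3.0)

    def test_onset_inside_offset_outside_counts(self):
        ev = _event("TdP", 48, onset=599_000.0)  # straddles the boundary
        res = ar.arrhythmia_score([ev])
        assert res.as_value == pytest.approx((48.0 + 2.0) / 3.0)

    def test_bounds(self):
        res = ar.arrhythmia_score(
            [_event("defib-TdP", 60, shocks=4, duration_s=15.0, onset=1000.0 * i)
             for i in range(3)])
        assert res.as_value == 100.0

    @given(st.lists(st.integers(0, 4), max_size=8))
    @settings(max_examples=200)
    def test_oracle_equivalence_random_event_lists(self, choices):
        kinds = [("sEB", 1, 0), ("mEB", 3, 0), ("TdP", 10, 0),
                 ("defib-TdP", 50, 1), ("defib-TdP", 55, 3)]
        events = []
        for i, c in enumerate(choices):
            kind, run, shocks = kinds[c]
            events.append(_event(kind, run, shocks=shocks, onset=500.0 * i,
                                 duration_s=13.0 if kind == "defib-TdP" else None))
        res = ar.arrhythmia_score(events)
        assert res.as_value == pytest.approx(
            brute_force_as([ar.score_event(e) for e in events]))

    @given(st.lists(st.integers(6, 49), min_size=1, max_size=6))
    @settings(max_examples=100)
    def test_monotone_in_added_events(self, runs):
        events = [_event("TdP", r, onset=1000.0 * i) for i, r in enumerate(runs)]
        base = ar.arrhythmia_score(events[:-1]).as_value if len(events) > 1 else 1.0
        assert ar.arrhythmia_score(events).as_value >= base


class TestIncidence:
    def test_30pct_seb_20pct_tdp(self):
        cohort = {f"dog{i}": [] for i in range(10)}
        cohort["dog0"] = [_event("sEB", 1)]
        cohort["dog1"] = [_event("sEB", 1), _event("mEB", 3, onset=2000.0),
                          _event("TdP", 8, onset=5000.0)]
        cohort["dog2"] = [_event("sEB", 1), _event("mEB", 2, onset=2000.0),
                          _event("TdP", 12, onset=5000.0)]
        frac = ar.incidence_summary(cohort)
        assert frac["sEB"] == pytest.approx(0.3)
        assert frac["mEB"] == pytest.approx(0.2)
        assert frac["TdP"] == pytest.approx(0.2)

    def test_no_events_all_zero(self):
        frac = ar.incidence_summary({"a": [], "b": []})
        assert frac == {"sEB": 0.0, "mEB": 0.0, "TdP": 0.0}

    def test_single_subject_tdp_only(self):
        frac = ar.incidence_summary({"a": [_event("TdP", 10)]})
        assert frac["TdP"] == 1.0

    def test_defib_counts_as_tdp(self):
        frac = ar.incidence_summary(
            {"a": [_event("defib-TdP", 50, shocks=2, duration_s=12.0)]})
        assert frac["TdP"] == 1.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            ar.incidence_summary({})
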