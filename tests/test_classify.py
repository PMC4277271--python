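"""RIFLE/AKIN/KDIGO detection and staging rule engines."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cardiorenal import (
    BaselineEstimate,
    Cohort,
    classify_cohort,
    classify_patient,
    detect_akin,
    detect_kdigo,
    detect_rifle,
    estimate_baseline,
    stage_classification,
)
from cardiorenal.classify import ABSOLUTE_RISE_UMOL, PAIR_WINDOW_HOURS
from cardiorenal.cohort import IntegrityError

from conftest import make_patient


def akin_pair_enumeration(times, values, window=PAIR_WINDOW_HOURS, horizon=168.0):
    """Independent brute-force oracle: enumerate every ordered pair."""
    keep = [(t, v) for t, v in zip(times, values) if 0 <= t <= horizon]
    onset = None
    for ti, vi in keep:
        for tj, vj in keep:
            if 0 < tj - ti <= window and (vj - vi >= 26.5 or vj >= 1.5 * vi):
                onset = tj if onset is None else min(onset, tj)
    return (onset is not None), onset


class TestRifleDetection:
    def test_detects_at_earliest_crossing(self):
        det, onset = detect_rifle([24.0, 96.0], [100.0, 140.0], baseline=88.4)
        assert det and onset == 96.0  # 140 >= 1.5 * 88.4 = 132.6

    def test_below_threshold_not_detected(self):
        det, onset = detect_rifle([24.0, 96.0], [100.0, 130.0], baseline=88.4)
        assert not det and onset is None

    def test_constant_series_at_baseline_negative(self):
        det, _ = detect_rifle([0.0, 48.0, 96.0], [90.0, 90.0, 90.0], baseline=90.0)
        assert not det

    def test_crossing_outside_window_ignored(self):
        det, _ = detect_rifle([0.0, 200.0], [90.0, 200.0], baseline=90.0)
        assert not det


class TestAkinDetection:
    def test_absolute_rise_within_48h(self):
        det, onset, trig = detect_akin([0.0, 36.0], [100.0, 128.0])
        assert (det, onset, trig) == (True, 36.0, "absolute_48h")

    def test_slow_rise_not_detected(self):
        det, onset, trig = detect_akin([0.0, 48.0, 72.0], [100.0, 112.0, 130.0])
        assert not det  # within-48h rises are 12 and 18; ratios 1.12, 1.16

    def test_single_measurement_not_detected(self):
        det, _, _ = detect_akin([10.0], [300.0])
        assert not det

    def test_relative_pair_trigger(self):
        # rise 25 < 26.5 but ratio 65/40 = 1.625 >= 1.5
        det, onset, trig = detect_akin([0.0, 30.0], [40.0, 65.0])
        assert (det, onset, trig) == (True, 30.0, "relative_48h")

    def test_absolute_beats_relative_on_tied_onset(self):
        # both clauses qualify at t=24
        det, onset, trig = detect_akin([0.0, 24.0], [60.0, 95.0])
        assert (det, onset, trig) == (True, 24.0, "absolute_48h")

    def test_pairs_spanning_more_than_48h_ignored(self):
        det, _, _ = detect_akin([0.0, 60.0], [100.0, 180.0])
        assert not det

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0, max_value=168),
                st.floats(min_value=30, max_value=500),
            ),
            min_size=1,
            max_size=12,
        )
    )
    def test_matches_pair_enumeration(self, pairs):
        pairs = sorted(pairs)
        t = np.array([p[0] for p in pairs])
        v = np.array([round(p[1], 1) for p in pairs])
        det, onset, _ = detect_akin(t, v)
        det_ref, onset_ref = akin_pair_enumeration(t, v)
        assert det == det_ref
        if det:
            assert onset == pytest.approx(onset_ref)

    def test_baseline_referenced_variant(self):
        # dip-then-partial-recovery: pair reading fires, baseline reading does not
        t, v = [0.0, 50.0, 80.0], [100.0, 40.0, 65.0]
        det_pair, _, _ = detect_akin(t, v, relative_reference="pair")
        det_base, _, _ = detect_akin(t, v, relative_reference="baseline", baseline=100.0)
        assert det_pair and not det_base


class TestKdigoDetection:
    def test_seven_day_relative_clause_catches_akin_negative(self):
        # AKIN-negative slow rise, but 130 >= 1.5 * 80 within 7 d: K(+)A(-)
        t, v = [0.0, 48.0, 72.0], [100.0, 112.0, 130.0]
        det_a, _, _ = detect_akin(t, v)
        det_k, onset, trig = detect_kdigo(t, v, baseline=80.0)
        assert not det_a and det_k
        assert (onset, trig) == (72.0, "relative_7d")

    def test_absolute_clause_catches_rifle_negative(self):
        # rise 28 in 36h but peak/baseline = 1.28: K(+)R(-)
        t, v = [0.0, 36.0], [100.0, 128.0]
        det_r, _ = detect_rifle(t, v, baseline=100.0)
        det_k, onset, trig = detect_kdigo(t, v, baseline=100.0)
        assert not det_r and det_k
        assert (onset, trig) == (36.0, "absolute_48h")

    def test_flat_series_negative(self):
        det, _, _ = detect_kdigo([0.0, 24.0, 48.0], [90.0, 90.0, 90.0], baseline=90.0)
        assert not det

    def test_onset_is_earliest_across_clauses(self):
        # relative clause fires first: 120 >= 1.5 * 75 at t=24 with rise 20
        # < 26.5; the absolute clause only fires at t=60 (rise 30 over 36 h)
        t, v = [0.0, 24.0, 60.0], [100.0, 120.0, 150.0]
        det, onset, trig = detect_kdigo(t, v, baseline=75.0)
        assert det and onset == 24.0 and trig == "relative_7d"


class TestStaging:
    @pytest.mark.parametrize(
        "criterion,baseline,values,rrt,expected",
        [
            # ratio tiers shared by all criteria
            ("RIFLE", 88.4, [88.4, 140.0], False, 1),   # 1.58x -> Risk
            ("KDIGO", 88.4, [88.4, 140.0], False, 1),
            ("RIFLE", 88.4, [88.4, 180.0], False, 2),   # 2.04x -> Injury
            ("AKIN", 88.4, [88.4, 180.0], False, 2),
            ("RIFLE", 88.4, [88.4, 270.0], False, 3),   # 3.05x -> Failure
            ("KDIGO", 88.4, [88.4, 270.0], False, 3),
            # 354 umol/L tier: KDIGO needs only the level; AKIN needs a 26.5
            # rise; RIFLE needs a 44 rise
            ("KDIGO", 240.0, [335.0, 365.0], False, 3),  # 1.52x but peak >= 354
            ("AKIN", 240.0, [335.0, 365.0], False, 3),   # rise 30 >= 26.5
            ("RIFLE", 240.0, [335.0, 365.0], False, 1),  # rise 30 < 44
            ("RIFLE", 240.0, [240.0, 365.0], False, 3),  # rise 125 >= 44 and >= 354
            # RRT forces stage 3 under AKIN/KDIGO but not RIFLE
            ("AKIN", 88.4, [88.4, 145.0], True, 3),
            ("KDIGO", 88.4, [88.4, 145.0], True, 3),
            ("RIFLE", 88.4, [88.4, 145.0], True, 1),
        ],
    )
    def test_stage_assignment(self, criterion, baseline, values, rrt, expected):
        t = np.arange(len(values), dtype=float) * 24.0
        cls = stage_classification(
            criterion, t, np.array(values), baseline,
            detected=True, onset_hours=24.0, trigger="absolute_48h", rrt_started=rrt,
        )
        assert cls.stage == expected

    def test_not_detected_is_stage_zero(self):
        cls = stage_classification(
            "KDIGO", [0.0], [90.0], 90.0, detected=False, onset_hours=None, trigger=None
        )
        assert cls.stage == 0 and not cls.detected

    def test_detected_with_empty_series_is_integrity_error(self):
        with pytest.raises(IntegrityError):
            stage_classification(
                "KDIGO", [], [], 90.0, detected=True, onset_hours=24.0, trigger="relative_7d"
            )

    def test_stage_monotone_in_peak(self):
        stages = []
        for peak in np.linspace(135.0, 400.0, 40):
            cls = stage_classification(
                "KDIGO", [0.0, 24.0], [88.4, peak], 88.4,
                detected=True, onset_hours=24.0, trigger="relative_7d",
            )
            stages.append(cls.stage)
        assert all(b >= a for a, b in zip(stages, stages[1:]))


class TestClassifyCohort:
    def test_constructed_cohort_flags(self, three_patient_cohort):
        baselines = {
            p.patient_id: estimate_baseline(p) for p in three_patient_cohort
        }
        table = classify_cohort(three_patient_cohort, baselines)
        a, b, c = table.rows["A"], table.rows["B"], table.rows["C"]
        assert a.rifle.detected and a.akin.detected and a.kdigo.detected
        assert not b.rifle.detected and b.akin.detected and b.kdigo.detected
        assert not (c.rifle.detected or c.akin.detected or c.kdigo.detected)

    def test_missing_baseline_names_patient(self, three_patient_cohort):
        with pytest.raises(IntegrityError, match="B"):
            classify_cohort(
                three_patient_cohort,
                {"A": BaselineEstimate(90.0, "admission"), "C": BaselineEstimate(80.0, "admission")},
            )

    def test_empty_cohort_gives_empty_table(self):
        table = classify_cohort(Cohort(patients=[]), {})
        assert len(table) == 0

    def test_onset_invariants(self, three_patient_cohort):
        baselines = {p.patient_id: estimate_baseline(p) for p in three_patient_cohort}
        table = classify_cohort(three_patient_cohort, baselines)
        for row in table.rows.values():
            for cls in (row.rifle, row.akin, row.kdigo):
                if cls.detected:
                    assert cls.stage >= 1
                    assert 0 <= cls.onset_hours <= 168
                else:
                    assert cls.stage == 0 and cls.onset_hours is None

    def test_staging_peak_uses_whole_stay(self):
        # detection fires in week one; the peak in week two raises the stage
        p = make_patient(
            "L",
            scr=[(0.0, 90.0), (48.0, 140.0), (300.0, 290.0)],
            outcome_hours=400.0,
        )
        row = classify_patient(p, BaselineEstimate(90.0, "admission"))
        assert row.kdigo.detected
        assert row.kdigo.stage == 3  # 290/90 > 3 using the whole-stay peak

    def test_detection_restricted_to_first_week(self):
        p = make_patient(
            "M", scr=[(0.0, 90.0), (200.0, 200.0)], outcome_hours=400.0
        )
        row = classify_patient(p, BaselineEstimate(90.0, "admission"))
        assert not row.kdigo.detected
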