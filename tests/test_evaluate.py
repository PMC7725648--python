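"""Checklist grading: segmentation, colours, compliance, mode arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import build_session_events, make_synthetic_record, perfect_marks
from blskit.evaluate import (
    ManualMark,
    ModeError,
    SessionRecord,
    compliance_fraction,
    grade_step,
    marks_from_script,
    render_report,
    score_session,
    segment_cycles,
)
from blskit.protocol import ComplianceWindows, StepSpec, default_table

WINDOWS = ComplianceWindows()


class TestSegmentCycles:
    def test_perfect_session_blocks(self, perfect_pipeline):
        rec = perfect_pipeline["record"]
        shock = next(m.t_s for m in rec.marks if m.step_id == "aed_shock")
        a = segment_cycles(rec.compressions, rec.ventilations, shock_time_s=shock)
        assert [len(b) for b in a.cpr_blocks] == [30] * 5
        assert [len(p) for p in a.vent_pairs] == [2] * 5
        assert len(a.final_block) == 30

    def test_no_events_all_unmatched(self):
        a = segment_cycles([], [], shock_time_s=100.0)
        assert a.cpr_blocks == [[]] * 5 and a.vent_pairs == [[]] * 5 and a.final_block == []

    def test_four_blocks_leave_fifth_unmatched(self):
        comps, vents = build_session_events(
            [(30, 110.0, 55.0)] * 4 + [None], [(2, 500.0)] * 4 + [None]
        )
        a = segment_cycles(comps, vents, shock_time_s=252.0)
        assert [len(b) for b in a.cpr_blocks] == [30, 30, 30, 30, 0]
        assert [len(p) for p in a.vent_pairs] == [2, 2, 2, 2, 0]

    def test_extra_blocks_attach_to_last(self):
        # six pre-shock runs: the sixth merges into block five
        comps, vents = build_session_events(
            [(30, 110.0, 55.0)] * 5, [(2, 500.0)] * 4 + [None]
        )
        extra, _ = build_session_events([(10, 110.0, 55.0)], [None], first_block_start=225.0)
        a = segment_cycles(comps + extra, vents, shock_time_s=252.0)
        assert [len(b) for b in a.cpr_blocks] == [30, 30, 30, 30, 40]

    def test_gap_splits_blocks_without_ventilations(self):
        comps, _ = build_session_events(
            [(30, 110.0, 55.0), (30, 110.0, 55.0)], [None, None]
        )
        a = segment_cycles(comps, [], shock_time_s=None)
        assert [len(b) for b in a.cpr_blocks][:2] == [30, 30]
        assert a.final_block == []


class TestGradeStep:
    STEP = StepSpec("head_tilt", "Head Tilt", 5, 2, expected_time_s=25.0, timing_tolerance_s=10.0)

    def test_on_time_is_green(self):
        assert grade_step(self.STEP, 25.0, True) == "green"
        assert grade_step(self.STEP, 35.0, True) == "green"  # tolerance boundary

    def test_not_performed_is_red(self):
        assert grade_step(self.STEP, None, False) == "red"

    def test_late_is_orange(self):
        assert grade_step(self.STEP, 55.0, True) == "orange"

    def test_out_of_order_downgrades_to_orange(self):
        assert grade_step(self.STEP, 25.0, True, prev_time_s=30.0) == "orange"

    def test_performed_without_timestamp_is_orange(self):
        assert grade_step(self.STEP, None, True) == "orange"


class TestComplianceFraction:
    def test_perfect_block_fully_compliant(self):
        comps, _ = build_session_events([(30, 110.0, 55.0)], [None])
        assert compliance_fraction(comps, WINDOWS, "compression") == 1.0

    def test_shallow_block_fully_noncompliant(self):
        comps, _ = build_session_events([(30, 110.0, 40.0)], [None])
        assert compliance_fraction(comps, WINDOWS, "compression") == 0.0

    @pytest.mark.parametrize("rate,expected", [(100.0, 1.0), (120.0, 1.0), (99.0, 0.0), (121.0, 0.0)])
    def test_rate_window_boundaries_inclusive(self, rate, expected):
        comps, _ = build_session_events([(30, rate, 55.0)], [None])
        assert compliance_fraction(comps, WINDOWS, "compression") == expected

    def test_first_event_uses_following_interval(self):
        comps, _ = build_session_events([(2, 110.0, 55.0)], [None])
        assert comps[0].inst_rate_cpm is None
        assert compliance_fraction(comps, WINDOWS, "compression") == 1.0

    def test_single_compression_checked_on_depth_alone(self):
        comps, _ = build_session_events([(1, 110.0, 55.0)], [None])
        assert compliance_fraction(comps, WINDOWS, "compression") == 1.0
        shallow, _ = build_session_events([(1, 110.0, 30.0)], [None])
        assert compliance_fraction(shallow, WINDOWS, "compression") == 0.0

    def test_ventilation_volume_window(self):
        _, vents = build_session_events([(2, 110.0, 55.0)], [(2, 500.0)])
        assert compliance_fraction(vents, WINDOWS, "ventilation") == 1.0
        _, low = build_session_events([(2, 110.0, 55.0)], [(2, 300.0)])
        assert compliance_fraction(low, WINDOWS, "ventilation") == 0.0

    def test_empty_block_is_zero(self):
        assert compliance_fraction([], WINDOWS, "compression") == 0.0


class TestScoreSession:
    def test_perfect_simulated_session_scores_100_every_mode(self, table, perfect_pipeline):
        for mode in ("handson", "osce", "game"):
            card = score_session(perfect_pipeline["record"], table, mode=mode)
            assert card.total == 100.0
            assert card.passed
            assert all(r.status == "green" for r in card.step_results)

    def test_omitting_final_cpr_costs_15(self, table):
        rec = make_synthetic_record(table, final=None)
        card = score_session(rec, table, mode="handson")
        assert card.total == 85.0

    def test_shallow_compressions_penalised_only_in_handson(self, table):
        rec = make_synthetic_record(table, block=(30, 110.0, 40.0), final=(30, 110.0, 40.0))
        handson = score_session(rec, table, mode="handson")
        osce = score_session(rec, table, mode="osce")
        assert osce.total == 100.0
        # 5 CPR30 blocks (4 each) + final CPR (15) lose all sensor credit
        assert handson.total == pytest.approx(100.0 - (5 * 4 + 15))
        assert osce.total > handson.total

    def test_bls_training_mode_is_never_scored(self, table):
        rec = make_synthetic_record(table)
        rec.mode = "bls_training"
        with pytest.raises(ModeError, match="not recorded"):
            score_session(rec, table)

    def test_mark_for_sensor_step_rejected_outside_game_mode(self, table):
        rec = make_synthetic_record(table)
        rec.marks.append(ManualMark(step_id="cpr30_1", t_s=70.0))
        with pytest.raises(ValueError, match="visual-evidence"):
            score_session(rec, table, mode="handson")

    def test_game_mode_accepts_marks_as_virtual_evidence(self, table):
        marks = perfect_marks(table) + [
            ManualMark(step_id=s.step_id, t_s=s.expected_time_s)
            for s in table
            if s.evidence != "visual"
        ]
        rec = SessionRecord(learner_id="gamer", marks=marks)
        card = score_session(rec, table, mode="game")
        assert card.total == 100.0

    def test_empty_session_scores_zero(self, table):
        rec = SessionRecord(learner_id="absent")
        card = score_session(rec, table, mode="handson")
        assert card.total == 0.0
        assert all(r.status == "red" for r in card.step_results)
        assert not card.passed

    def test_late_visual_step_gets_half_credit(self, table):
        rec = make_synthetic_record(table)
        rec.marks = [
            m if m.step_id != "check_safety" else ManualMark("check_safety", 0.0, True)
            for m in rec.marks
        ]
        # moving check_safety to t=0 keeps it in order but 5 s early (within
        # tolerance) -> still green; push it far late instead
        rec.marks = [
            m if m.step_id != "check_rhythm" else ManualMark("check_rhythm", 350.0, True)
            for m in rec.marks
        ]
        card = score_session(rec, table, mode="osce")
        res = {r.step_id: r for r in card.step_results}
        assert res["check_rhythm"].status == "orange"
        assert "timing" in res["check_rhythm"].rationale

    def test_orange_credit_is_half_weight(self, table):
        rec = make_synthetic_record(table)
        rec.marks = [
            m if m.step_id != "check_breathing" else ManualMark("check_breathing", 80.0, True)
            for m in rec.marks
        ]
        card = score_session(rec, table, mode="osce")
        res = {r.step_id: r for r in card.step_results}
        # 80 s is 45 s past the expected 35 s -> orange -> half of 6 points;
        # the following step (call_for_help at 45 s) is now out of order
        # relative to it -> also orange, half of 5 points
        assert res["check_breathing"].status == "orange"
        assert res["check_breathing"].points == 3.0
        assert res["call_for_help"].status == "orange"
        assert card.total == 94.5

    def test_totals_conserved_and_bounded(self, table):
        rec = make_synthetic_record(table, block=(30, 90.0, 48.0), vent=(2, 350.0))
        card = score_session(rec, table, mode="handson")
        assert card.total == pytest.approx(sum(r.points for r in card.step_results))
        assert 0.0 <= card.total <= 100.0

    def test_deterministic(self, table, perfect_pipeline):
        a = score_session(perfect_pipeline["record"], table, mode="handson")
        b = score_session(perfect_pipeline["record"], table, mode="handson")
        assert a.to_dict() == b.to_dict()


class TestRenderReport:
    def test_perfect_card_all_green(self, table, perfect_pipeline):
        card = score_session(perfect_pipeline["record"], table, mode="handson")
        text = render_report(card, table)
        lines = [l for l in text.splitlines() if l.startswith("[")]
        assert len(lines) == 24
        assert all(l.startswith("[G]") for l in lines)
        assert "PASS" in text

    def test_empty_session_report_all_red(self, table):
        card = score_session(SessionRecord(learner_id="x"), table)
        text = render_report(card, table)
        assert text.count("[R]") == 24
        assert "Total: 0/100" in text
        assert "FAIL" in text

    def test_orange_line_carries_timing_rationale(self, table):
        rec = make_synthetic_record(table)
        rec.marks = [
            m if m.step_id != "head_tilt" else ManualMark("head_tilt", 60.0, True)
            for m in rec.marks
        ]
        card = score_session(rec, table, mode="osce")
        line = next(l for l in render_report(card, table).splitlines() if "Head Tilt" in l)
        assert line.startswith("[O]") and "timing" in line


class TestProperties:
    statuses = st.sampled_from(["ok", "late", "omit"])

    @given(st.lists(statuses, min_size=24, max_size=24))
    @settings(max_examples=60)
    def test_handson_never_exceeds_osce(self, table, perturbations):
        rec = _perturbed_record(table, perturbations)
        handson = score_session(rec, table, mode="handson").total
        osce = score_session(rec, table, mode="osce").total
        assert handson <= osce + 1e-9

    @given(st.lists(statuses, min_size=24, max_size=24))
    @settings(max_examples=60)
    def test_score_conservation(self, table, perturbations):
        rec = _perturbed_record(table, perturbations)
        for mode in ("handson", "osce"):
            card = score_session(rec, table, mode=mode)
            assert card.total == pytest.approx(sum(r.points for r in card.step_results))
            assert 0.0 <= card.total <= 100.0


def _perturbed_record(table, perturbations):
    """A synthetic record whose steps are individually on-time, late, or omitted."""
    flags = dict(zip((s.step_id for s in table), perturbations))
    blocks, vents = [], []
    for i in range(1, 6):
        b = flags[f"cpr30_{i}"]
        blocks.append(None if b == "omit" else (30, 110.0, 55.0 if b == "ok" else 40.0))
        v = flags[f"ventilation_{i}"]
        vents.append(None if v == "omit" else (2, 500.0 if v == "ok" else 250.0))
    f = flags["final_cpr"]
    final = None if f == "omit" else (30, 110.0, 55.0 if f == "ok" else 40.0)
    comps, vent_events = build_session_events(blocks, vents, final_spec=final)
    marks = []
    for s in table:
        if s.evidence != "visual":
            continue
        flag = flags[s.step_id]
        if flag == "omit":
            marks.append(ManualMark(s.step_id, None, performed=False))
        elif flag == "late":
            marks.append(ManualMark(s.step_id, s.expected_time_s + 60.0, performed=True))
        else:
            marks.append(ManualMark(s.step_id, s.expected_time_s, performed=True))
    return SessionRecord(
        learner_id="prop", compressions=comps, ventilations=vent_events, marks=marks
    )
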