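"""Checklist grading: map events and instructor marks onto the BLS protocol.

Each checklist step is graded with the three-colour scheme used across all
modalities: green (performed at the right time and in order), orange
(performed, but mistimed or out of order), red (not performed).  Points per
step are ``weight x status_multiplier x sensor_multiplier`` where the status
multiplier is 1 / 0.5 / 0 for green / orange / red, and — in hands-on mode
only — the sensor multiplier is the fraction of the step's sensor events that
meet the compliance windows (depth and rate for compressions, volume for
ventilations).  OSCE and game modes use a sensor multiplier of 1, which is
why a hands-on total can never exceed the OSCE total for the same session.

Compression events are assigned to checklist blocks (five pre-shock CPR30
blocks, the rescue-breath pair after each, and the post-shock Final CPR) by
:func:`segment_cycles`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .detect import CompressionEvent, VentilationEvent
from .protocol import (
    SENSOR_COMPRESSION,
    SENSOR_VENTILATION,
    VISUAL,
    ComplianceWindows,
    PassRule,
    ScoringTable,
    StepSpec,
    classify_success,
    default_table,
)

__all__ = [
    "ManualMark",
    "SessionRecord",
    "StepResult",
    "ReportCard",
    "CycleAssignment",
    "ModeError",
    "BLS_TRAINING",
    "FULL_TRAINING",
    "segment_cycles",
    "grade_step",
    "compliance_fraction",
    "score_session",
    "render_report",
    "marks_from_script",
]

BLS_TRAINING = "bls_training"
FULL_TRAINING = "full_training"
_MODES = ("handson", "osce", "game")
_STATUS_MULTIPLIER = {"green": 1.0, "orange": 0.5, "red": 0.0}
_TIME_EPS = 1e-9


class ModeError(ValueError):
    """Raised when a session cannot be scored in the requested mode."""


@dataclass(frozen=True)
class ManualMark:
    """An instructor's timestamped mark for a step the sensors cannot see."""

    step_id: str
    t_s: float | None
    performed: bool = True

    def to_dict(self) -> dict:
        return {"step_id": self.step_id, "t_s": self.t_s, "performed": self.performed}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ManualMark":
        t = d.get("t_s")
        return cls(step_id=d["step_id"], t_s=None if t is None else float(t),
                   performed=bool(d.get("performed", True)))


@dataclass
class SessionRecord:
    """One recorded training session (events + instructor marks).

    ``mode`` distinguishes the free-practice "BLS Training" mode (metronome
    assistance, never recorded or scored) from "Full Training", where the
    instructor marks visually observed steps and the session may be scored.
    """

    learner_id: str
    compressions: list[CompressionEvent] = field(default_factory=list)
    ventilations: list[VentilationEvent] = field(default_factory=list)
    marks: list[ManualMark] = field(default_factory=list)
    mode: str = FULL_TRAINING
    shock_time_s: float | None = None
    started_at: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in (BLS_TRAINING, FULL_TRAINING):
            raise ValueError(f"unknown session mode {self.mode!r}")


@dataclass(frozen=True)
class StepResult:
    step_id: str
    status: str  # green | orange | red
    points: float
    weight: int
    compliance_fraction: float | None = None  # sensor steps only
    rationale: str = ""
    observed_time_s: float | None = None

    def __post_init__(self) -> None:
        if self.status not in _STATUS_MULTIPLIER:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "red" and self.points != 0:
            raise ValueError("a red step awards no points")
        if self.points > self.weight + _TIME_EPS:
            raise ValueError("points cannot exceed the step weight")

    def to_dict(self) -> dict:
        return {
            "step_id": self.step_id,
            "status": self.status,
            "points": self.points,
            "weight": self.weight,
            "compliance_fraction": self.compliance_fraction,
            "rationale": self.rationale,
            "observed_time_s": self.observed_time_s,
        }


@dataclass
class ReportCard:
    """Scored session: one result per checklist step plus summary metrics."""

    learner_id: str
    mode_scored: str
    step_results: list[StepResult]
    total: float
    passed: bool
    summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "learner_id": self.learner_id,
            "mode_scored": self.mode_scored,
            "step_results": [r.to_dict() for r in self.step_results],
            "total": self.total,
            "passed": self.passed,
            "summary": self.summary,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReportCard":
        results = [
            StepResult(
                step_id=r["step_id"],
                status=r["status"],
                points=float(r["points"]),
                weight=int(r["weight"]),
                compliance_fraction=r.get("compliance_fraction"),
                rationale=r.get("rationale", ""),
                observed_time_s=r.get("observed_time_s"),
            )
            for r in d["step_results"]
        ]
        return cls(
            learner_id=d["learner_id"],
            mode_scored=d["mode_scored"],
            step_results=results,
            total=float(d["total"]),
            passed=bool(d["passed"]),
            summary=dict(d.get("summary", {})),
        )


@dataclass
class CycleAssignment:
    """Events mapped onto the 30:2 block structure of the checklist."""

    cpr_blocks: list[list[CompressionEvent]]  # pre-shock CPR30 blocks, in order
    vent_pairs: list[list[VentilationEvent]]  # breaths after block i (same length)
    final_block: list[CompressionEvent]  # compressions after the AED shock


def segment_cycles(
    compressions: Sequence[CompressionEvent],
    ventilations: Sequence[VentilationEvent],
    shock_time_s: float | None = None,
    gap_s: float = 2.0,
    n_cycles: int = 5,
) -> CycleAssignment:
    """Assign events to the five CPR30 blocks, their breath pairs, and Final CPR.

    Pre-shock compressions are split into maximal runs separated by a pause
    of at least ``gap_s`` between consecutive peaks or by an intervening
    ventilation.  The first ``n_cycles`` runs become the CPR30 blocks; any
    extra pre-shock runs are attached to the last block (the nearest expected
    boundary).  Ventilations between block *i* and block *i+1* (or the shock)
    form breath pair *i*.  Compressions after ``shock_time_s`` form the Final
    CPR block; with no shock time, all compressions are treated as pre-shock.
    Degenerate inputs yield empty assignments, never errors.
    """
    comps = sorted(compressions, key=lambda e: e.t_peak_s)
    vents = sorted(ventilations, key=lambda e: e.t_peak_s)
    if shock_time_s is None:
        pre, post = comps, []
    else:
        pre = [c for c in comps if c.t_peak_s <= shock_time_s]
        post = [c for c in comps if c.t_peak_s > shock_time_s]
    vent_peaks = np.array([v.t_peak_s for v in vents])

    runs: list[list[CompressionEvent]] = []
    for c in pre:
        if runs:
            prev = runs[-1][-1]
            gap = c.t_peak_s - prev.t_peak_s
            vent_between = bool(
                np.any((vent_peaks > prev.t_peak_s) & (vent_peaks < c.t_peak_s))
            )
            if gap < gap_s and not vent_between:
                runs[-1].append(c)
                continue
        runs.append([c])

    blocks = runs[:n_cycles]
    for extra in runs[n_cycles:]:
        blocks[-1].extend(extra)  # nearest expected boundary: the last block
    while len(blocks) < n_cycles:
        blocks.append([])

    # Breath pair i: ventilations after block i ends and before the next
    # boundary (next non-empty block start, else shock time, else forever).
    vent_pairs: list[list[VentilationEvent]] = []
    for i in range(n_cycles):
        if not blocks[i]:
            vent_pairs.append([])
            continue
        lo = blocks[i][-1].t_peak_s
        hi = np.inf
        for j in range(i + 1, n_cycles):
            if blocks[j]:
                hi = blocks[j][0].t_peak_s
                break
        else:
            if shock_time_s is not None:
                hi = shock_time_s
        vent_pairs.append([v for v in vents if lo < v.t_peak_s < hi])
    return CycleAssignment(cpr_blocks=blocks, vent_pairs=vent_pairs, final_block=post)


def grade_step(
    step: StepSpec,
    observed_time_s: float | None,
    performed: bool,
    prev_time_s: float | None = None,
) -> str:
    """Three-colour grade for one step.

    Red if the step was not performed at all.  Green if it was performed
    within ``timing_tolerance_s`` of its expected time and not out of order
    (not earlier than the previous credited step's observed time).  Orange
    otherwise — the step *was* applied, but mistimed or out of sequence; a
    performed step with no usable timestamp is also orange, since its timing
    cannot be verified.
    """
    if not performed:
        return "red"
    if observed_time_s is None:
        return "orange"
    on_time = abs(observed_time_s - step.expected_time_s) <= step.timing_tolerance_s + _TIME_EPS
    in_order = prev_time_s is None or observed_time_s >= prev_time_s - _TIME_EPS
    return "green" if (on_time and in_order) else "orange"


def compliance_fraction(
    events: Sequence[CompressionEvent] | Sequence[VentilationEvent],
    windows: ComplianceWindows,
    kind: str,
) -> float:
    """Fraction of a block's events meeting the sensor windows (closed intervals).

    Compressions must satisfy both the depth and the rate window; the first
    event's rate check uses the following interval (its own ``inst_rate_cpm``
    refers to the preceding event, which does not exist).  An event with no
    defined rate on either side — a single-compression block — is checked on
    depth alone.  Ventilations are checked on volume.  An empty block has
    fraction 0 by convention.
    """
    if kind not in ("compression", "ventilation"):
        raise ValueError(f"unknown kind {kind!r}")
    events = list(events)
    if not events:
        return 0.0
    ok = 0
    for i, ev in enumerate(events):
        if kind == "compression":
            if i == 0:
                rate = events[1].inst_rate_cpm if len(events) > 1 else None
            else:
                rate = ev.inst_rate_cpm
            rate_ok = True if rate is None else windows.rate_ok(rate)
            if windows.depth_ok(ev.depth_mm) and rate_ok:
                ok += 1
        else:
            if windows.volume_ok(ev.volume_ml):
                ok += 1
    return ok / len(events)


def _sensor_step_mapping(table: ScoringTable) -> tuple[list[str], list[str], list[str]]:
    """Split sensor steps into pre-shock CPR blocks, breath pairs, post-shock CPR.

    The AED-shock step (id ``aed_shock`` in the default table, else the last
    visual step before a trailing compression step) divides compression steps
    into the numbered CPR30 blocks and the Final CPR.
    """
    shock_order = None
    for s in table:
        if s.step_id == "aed_shock":
            shock_order = s.order_index
    comp_steps = [s for s in table if s.evidence == SENSOR_COMPRESSION]
    vent_steps = [s.step_id for s in table if s.evidence == SENSOR_VENTILATION]
    if shock_order is None:
        pre = [s.step_id for s in comp_steps]
        post = []
    else:
        pre = [s.step_id for s in comp_steps if s.order_index < shock_order]
        post = [s.step_id for s in comp_steps if s.order_index > shock_order]
    return pre, vent_steps, post


def score_session(
    record: SessionRecord,
    table: ScoringTable | None = None,
    windows: ComplianceWindows | None = None,
    mode: str = "handson",
    orange_credit: float = 0.5,
    pass_rule: PassRule | None = None,
    gap_s: float = 2.0,
) -> ReportCard:
    """Grade a recorded session against the checklist and emit a report card.

    ``mode`` selects how evidence is credited: ``handson`` applies the sensor
    compliance multiplier to compression/ventilation steps; ``osce`` and
    ``game`` grade the same step structure on performance and timing alone.
    Only "Full Training" sessions can be scored — practice sessions are never
    recorded.
    """
    if mode not in _MODES:
        raise ModeError(f"unknown scoring mode {mode!r}")
    if record.mode == BLS_TRAINING:
        raise ModeError("BLS Training sessions are not recorded and cannot be scored")
    if table is None:
        table = default_table()
    if windows is None:
        windows = ComplianceWindows()
    if pass_rule is None:
        pass_rule = PassRule()

    marks = {m.step_id: m for m in record.marks}
    for m in record.marks:
        if m.step_id not in table:
            raise ValueError(f"mark references unknown step {m.step_id!r}")
        if mode != "game" and table.step(m.step_id).evidence != VISUAL:
            raise ValueError(
                f"mark for {m.step_id!r}: marks are only accepted for visual-evidence steps"
            )

    shock_time = record.shock_time_s
    if shock_time is None and "aed_shock" in marks and marks["aed_shock"].performed:
        shock_time = marks["aed_shock"].t_s
    assignment = segment_cycles(
        record.compressions, record.ventilations, shock_time_s=shock_time, gap_s=gap_s
    )
    pre_ids, vent_ids, post_ids = _sensor_step_mapping(table)
    block_for = {sid: assignment.cpr_blocks[i] if i < len(assignment.cpr_blocks) else []
                 for i, sid in enumerate(pre_ids)}
    for sid in post_ids:
        block_for[sid] = assignment.final_block
    pair_for = {sid: assignment.vent_pairs[i] if i < len(assignment.vent_pairs) else []
                for i, sid in enumerate(vent_ids)}

    results: list[StepResult] = []
    prev_time: float | None = None
    for step in table:
        frac: float | None = None
        if step.evidence == SENSOR_COMPRESSION:
            block = block_for.get(step.step_id, [])
            performed = bool(block)
            observed = block[0].t_peak_s if block else None
            frac = compliance_fraction(block, windows, "compression")
        elif step.evidence == SENSOR_VENTILATION:
            pair = pair_for.get(step.step_id, [])
            performed = bool(pair)
            observed = pair[0].t_peak_s if pair else None
            frac = compliance_fraction(pair, windows, "ventilation")
        else:
            mark = marks.get(step.step_id)
            performed = mark is not None and mark.performed
            observed = mark.t_s if (mark is not None and mark.performed) else None

        # In game mode the "sensor" steps are virtual actions; if no telemetry
        # exists, a mark for the step stands in as evidence.
        if mode == "game" and not performed and step.step_id in marks:
            mark = marks[step.step_id]
            performed = mark.performed
            observed = mark.t_s if mark.performed else None

        status = grade_step(step, observed, performed, prev_time)
        status_mult = {"green": 1.0, "orange": orange_credit, "red": 0.0}[status]
        sensor_mult = 1.0
        if mode == "handson" and frac is not None:
            sensor_mult = frac
        points = step.weight * status_mult * sensor_mult
        results.append(
            StepResult(
                step_id=step.step_id,
                status=status,
                points=points,
                weight=step.weight,
                compliance_fraction=frac,
                rationale=_rationale(step, status, observed, prev_time, frac, mode),
                observed_time_s=observed,
            )
        )
        if status in ("green", "orange") and observed is not None:
            prev_time = observed

    total = float(sum(r.points for r in results))
    total = min(max(total, 0.0), 100.0)
    card = ReportCard(
        learner_id=record.learner_id,
        mode_scored=mode,
        step_results=results,
        total=total,
        passed=classify_success(total, pass_rule),
        summary=_summary_metrics(record, results, windows),
    )
    return card


def _rationale(step, status, observed, prev_time, frac, mode) -> str:
    if status == "red":
        return "not performed"
    bits = []
    if status == "orange":
        if observed is None:
            bits.append("timing unverifiable")
        elif abs(observed - step.expected_time_s) > step.timing_tolerance_s:
            bits.append(
                f"timing off by {observed - step.expected_time_s:+.1f} s"
                f" (tolerance ±{step.timing_tolerance_s:.0f} s)"
            )
        else:
            bits.append("out of order")
    else:
        bits.append("on time")
    if frac is not None and mode == "handson":
        bits.append(f"sensor compliance {frac:.0%}")
    return "; ".join(bits)


def _summary_metrics(record, results, windows) -> dict:
    depths = [c.depth_mm for c in record.compressions]
    # Instantaneous rate is only meaningful within a block: exclude intervals
    # spanning a block boundary (>= 2 s pause, i.e. rate < 30/min).
    rates = [
        c.inst_rate_cpm
        for c in record.compressions
        if c.inst_rate_cpm is not None and c.inst_rate_cpm >= 30.0
    ]
    volumes = [v.volume_ml for v in record.ventilations]
    sensor = [r for r in results if r.compliance_fraction is not None]
    return {
        "mean_depth_mm": float(np.mean(depths)) if depths else None,
        "mean_rate_cpm": float(np.mean(rates)) if rates else None,
        "mean_volume_ml": float(np.mean(volumes)) if volumes else None,
        "overall_compliance": (
            float(np.mean([r.compliance_fraction for r in sensor])) if sensor else None
        ),
        "n_compressions": len(record.compressions),
        "n_ventilations": len(record.ventilations),
    }


_COLOR_DOT = {"green": "[G]", "orange": "[O]", "red": "[R]"}


def render_report(card: ReportCard, table: ScoringTable | None = None) -> str:
    """Human-readable report: one line per step plus summary, deterministic."""
    lines = [
        f"Learner {card.learner_id} — mode: {card.mode_scored}",
        f"Total: {card.total:g}/100  ({'PASS' if card.passed else 'FAIL'})",
        "-" * 64,
    ]
    labels = {}
    if table is not None:
        labels = {s.step_id: s.label for s in table}
    for r in card.step_results:
        name = labels.get(r.step_id, r.step_id)
        timing = f"t={r.observed_time_s:7.1f}s" if r.observed_time_s is not None else "t=   --  "
        lines.append(
            f"{_COLOR_DOT[r.status]} {name:<22} {r.points:5.1f}/{r.weight:<2d} {timing}  {r.rationale}"
        )
    s = card.summary
    lines.append("-" * 64)
    if s.get("mean_depth_mm") is not None:
        lines.append(f"mean depth {s['mean_depth_mm']:.1f} mm")
    if s.get("mean_rate_cpm") is not None:
        lines.append(f"mean rate {s['mean_rate_cpm']:.1f} /min")
    if s.get("mean_volume_ml") is not None:
        lines.append(f"mean volume {s['mean_volume_ml']:.0f} mL")
    if s.get("overall_compliance") is not None:
        lines.append(f"overall sensor compliance {s['overall_compliance']:.0%}")
    return "\n".join(lines)


def marks_from_script(script: Iterable, table: ScoringTable) -> list[ManualMark]:
    """Instructor marks for the visual steps of a scripted session.

    Takes the simulator's scripted actions (anything with ``step_id``,
    ``start_s`` and ``performed`` attributes) and produces the marks an
    instructor following the script would have entered.
    """
    marks = []
    for action in script:
        if action.step_id in table and table.step(action.step_id).evidence == VISUAL:
            marks.append(
                ManualMark(step_id=action.step_id, t_s=action.start_s, performed=action.performed)
            )
    return marks


def write_card_json(card: ReportCard, path: str | Path) -> None:
    Path(path).write_text(json.dumps(card.to_dict(), indent=1))


def read_card_json(path: str | Path) -> ReportCard:
    return ReportCard.from_dict(json.loads(Path(path).read_text()))
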