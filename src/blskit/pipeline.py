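"""End-to-end convenience wrappers: script -> telemetry -> events -> report card.

These functions chain the simulator, the event detector and the scorer the
way the platform chains manikin, manikin service and app — one call from a
session description to a scored report card.  All building blocks remain
individually accessible in their own modules.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .detect import (
    DetectorConfig,
    augment_events,
    detect_compressions,
    detect_ventilations,
    filter_misdetections,
)
from .evaluate import (
    FULL_TRAINING,
    ReportCard,
    SessionRecord,
    marks_from_script,
    score_session,
)
from .protocol import ComplianceWindows, ScoringTable, default_table
from .simulate import SensorStream, SimulatorConfig, render_stream, script_session

__all__ = ["detect_all", "record_from_stream", "simulate_session", "simulate_and_score"]


def detect_all(
    stream: SensorStream, det_cfg: DetectorConfig | None = None, augment: bool = False
):
    """Full detection pipeline on both channels: detect, filter, optionally augment."""
    if det_cfg is None:
        det_cfg = DetectorConfig()
    comps = filter_misdetections(detect_compressions(stream, det_cfg), det_cfg)
    vents = filter_misdetections(detect_ventilations(stream, det_cfg), det_cfg)
    if augment:
        comps = augment_events(comps, stream, det_cfg)
        vents = augment_events(vents, stream, det_cfg)
    return comps, vents


def record_from_stream(
    stream: SensorStream,
    script: Sequence,
    table: ScoringTable,
    learner_id: str = "learner",
    det_cfg: DetectorConfig | None = None,
) -> SessionRecord:
    """Build a scoreable Full Training record from telemetry plus its script's marks."""
    comps, vents = detect_all(stream, det_cfg)
    return SessionRecord(
        learner_id=learner_id,
        compressions=comps,
        ventilations=vents,
        marks=marks_from_script(script, table),
        mode=FULL_TRAINING,
    )


def simulate_session(
    table: ScoringTable | None = None,
    sim_cfg: SimulatorConfig | None = None,
    det_cfg: DetectorConfig | None = None,
    learner_id: str = "learner",
    omit: Sequence[str] = (),
    delay: Mapping[str, float] | None = None,
    degrade: Mapping | None = None,
):
    """Script, render and detect one session; returns (record, stream, truth, script)."""
    if table is None:
        table = default_table()
    script = script_session(table, omit=omit, delay=delay, degrade=degrade)
    stream, truth = render_stream(script, sim_cfg)
    record = record_from_stream(stream, script, table, learner_id=learner_id, det_cfg=det_cfg)
    return record, stream, truth, script


def simulate_and_score(
    mode: str = "handson",
    table: ScoringTable | None = None,
    windows: ComplianceWindows | None = None,
    sim_cfg: SimulatorConfig | None = None,
    det_cfg: DetectorConfig | None = None,
    learner_id: str = "learner",
    omit: Sequence[str] = (),
    delay: Mapping[str, float] | None = None,
    degrade: Mapping | None = None,
) -> ReportCard:
    """One call from session description to report card."""
    if table is None:
        table = default_table()
    record, _stream, _truth, _script = simulate_session(
        table=table, sim_cfg=sim_cfg, det_cfg=det_cfg, learner_id=learner_id,
        omit=omit, delay=delay, degrade=degrade,
    )
    return score_session(record, table=table, windows=windows, mode=mode)
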