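"""ERC-2015 adult basic life support checklist: step weights, compliance windows, pass rule.

The checklist is the shared scoring frame for all three assessment modalities
(serious game, hands-on app, OSCE): 24 ordered steps, each worth a fixed
number of points, totalling 100.  Three steps (the two carotid-pulse checks
and the final rhythm check) carry zero weight: they are tracked and reported
but never change the total.

Sensor-compliance windows gate the chest-compression and ventilation steps in
hands-on mode: compression depth in mm, compression rate in compressions per
minute, and ventilation volume in mL must fall inside closed intervals.  Only
the rate window (100-120/min) is part of the published protocol description;
the depth and volume windows default to the ERC-2015 adult guideline ranges
(50-60 mm, 400-600 mL) and are configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "VISUAL",
    "SENSOR_COMPRESSION",
    "SENSOR_VENTILATION",
    "StepSpec",
    "ScoringTable",
    "ComplianceWindows",
    "PassRule",
    "ValidationError",
    "load_scoring_table",
    "classify_success",
    "default_table",
]

VISUAL = "visual"
SENSOR_COMPRESSION = "sensor-compression"
SENSOR_VENTILATION = "sensor-ventilation"
_EVIDENCE_KINDS = (VISUAL, SENSOR_COMPRESSION, SENSOR_VENTILATION)

# Relative slack for closed-interval membership so that values sitting exactly
# on a boundary (e.g. a 120/min compression train) are not rejected by
# floating-point round-off.
_BOUNDARY_RTOL = 1e-9


class ValidationError(ValueError):
    """A config document or domain object violates a checklist invariant."""


@dataclass(frozen=True)
class StepSpec:
    """One row of the BLS checklist.

    Parameters
    ----------
    step_id:
        Short token, unique within a table (e.g. ``"check_safety"``).
    label:
        Human-readable display name.
    weight:
        Points awarded for a fully correct, on-time performance.
    order_index:
        0-based position in the expected sequence.
    evidence:
        How performance of this step is established: ``"visual"`` (instructor
        mark), ``"sensor-compression"`` or ``"sensor-ventilation"`` (manikin
        telemetry).
    expected_time_s:
        Nominal offset of the step from session start, seconds.
    timing_tolerance_s:
        Half-width of the on-time window around ``expected_time_s``.
    """

    step_id: str
    label: str
    weight: int
    order_index: int
    evidence: str = VISUAL
    expected_time_s: float = 0.0
    timing_tolerance_s: float = 10.0

    def __post_init__(self) -> None:
        if not self.step_id:
            raise ValidationError("step_id must be non-empty")
        if not isinstance(self.weight, int) or self.weight < 0:
            raise ValidationError(
                f"step {self.step_id!r}: weight must be a non-negative integer, got {self.weight!r}"
            )
        if self.order_index < 0:
            raise ValidationError(f"step {self.step_id!r}: order_index must be >= 0")
        if self.evidence not in _EVIDENCE_KINDS:
            raise ValidationError(
                f"step {self.step_id!r}: evidence must be one of {_EVIDENCE_KINDS}, got {self.evidence!r}"
            )
        if self.timing_tolerance_s < 0:
            raise ValidationError(f"step {self.step_id!r}: timing_tolerance_s must be >= 0")

    def to_dict(self) -> dict:
        return {
            "step_id": self.step_id,
            "label": self.label,
            "weight": self.weight,
            "order_index": self.order_index,
            "evidence": self.evidence,
            "expected_time_s": self.expected_time_s,
            "timing_tolerance_s": self.timing_tolerance_s,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StepSpec":
        try:
            return cls(**{k: d[k] for k in ("step_id", "label", "weight", "order_index")},
                       evidence=d.get("evidence", VISUAL),
                       expected_time_s=float(d.get("expected_time_s", 0.0)),
                       timing_tolerance_s=float(d.get("timing_tolerance_s", 10.0)))
        except KeyError as exc:
            raise ValidationError(f"step definition missing required field {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class ScoringTable:
    """Ordered BLS checklist with per-step weights."""

    steps: tuple[StepSpec, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", tuple(self.steps))
        ids = [s.step_id for s in self.steps]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate step_id(s): {dup}")
        order = [s.order_index for s in self.steps]
        if any(b <= a for a, b in zip(order, order[1:])):
            raise ValidationError("order_index must be strictly increasing")

    @property
    def total_weight(self) -> int:
        return sum(s.weight for s in self.steps)

    def step(self, step_id: str) -> StepSpec:
        for s in self.steps:
            if s.step_id == step_id:
                return s
        raise KeyError(f"unknown step_id {step_id!r} in table {self.name!r}")

    def __contains__(self, step_id: str) -> bool:
        return any(s.step_id == step_id for s in self.steps)

    def __len__(self) -> int:
        return len(self.steps)

    def __iter__(self):
        return iter(self.steps)

    def without(self, *step_ids: str) -> "ScoringTable":
        """A copy of the table with the named steps removed."""
        for sid in step_ids:
            self.step(sid)  # raise KeyError on unknown ids
        return ScoringTable(
            steps=tuple(s for s in self.steps if s.step_id not in step_ids),
            name=f"{self.name}-reduced",
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "total": self.total_weight,
            "steps": [s.to_dict() for s in self.steps],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoringTable":
        if "steps" not in d:
            raise ValidationError("scoring-table document missing 'steps'")
        steps = tuple(StepSpec.from_dict(row) for row in d["steps"])
        table = cls(steps=steps, name=d.get("name", "custom"))
        declared = d.get("total")
        if declared is not None and table.total_weight != declared:
            raise ValidationError(
                f"weights sum to {table.total_weight} but document declares total {declared}"
            )
        return table


# The published checklist: (step_id, label, weight, evidence).  Weights sum
# to 100; zero-weight rows are tracked but award nothing.
_DEFAULT_ROWS: tuple[tuple[str, str, int, str], ...] = (
    ("check_safety", "Check Safety", 5, VISUAL),
    ("check_consciousness", "Check Consciousness", 9, VISUAL),
    ("head_tilt", "Head Tilt", 5, VISUAL),
    ("check_breathing", "Check Breathing", 6, VISUAL),
    ("call_for_help", "Call for Help", 5, VISUAL),
    ("get_aed", "Get AED", 5, VISUAL),
    ("check_carotid_pulse", "Check Carotid Pulse", 0, VISUAL),
    ("cpr30_1", "1st CPR30", 4, SENSOR_COMPRESSION),
    ("ventilation_1", "1st Ventilation", 2, SENSOR_VENTILATION),
    ("cpr30_2", "2nd CPR30", 4, SENSOR_COMPRESSION),
    ("ventilation_2", "2nd Ventilation", 2, SENSOR_VENTILATION),
    ("cpr30_3", "3rd CPR30", 4, SENSOR_COMPRESSION),
    ("ventilation_3", "3rd Ventilation", 2, SENSOR_VENTILATION),
    ("cpr30_4", "4th CPR30", 4, SENSOR_COMPRESSION),
    ("ventilation_4", "4th Ventilation", 2, SENSOR_VENTILATION),
    ("cpr30_5", "5th CPR30", 4, SENSOR_COMPRESSION),
    ("ventilation_5", "5th Ventilation", 2, SENSOR_VENTILATION),
    ("carotid_pulse_2", "2nd Carotid Pulse", 0, VISUAL),
    ("aed_use_pad", "AED Use Pad", 5, VISUAL),
    ("aed_on_off", "AED On Off", 5, VISUAL),
    ("stand_clear", "Stand Clear", 5, VISUAL),
    ("aed_shock", "AED Shock", 5, VISUAL),
    ("final_cpr", "Final CPR", 15, SENSOR_COMPRESSION),
    ("check_rhythm", "Check Rhythm", 0, VISUAL),
)

# Nominal timeline of a correct session (seconds from start).  Each CPR30
# block lasts ~16.4 s at 110/min; a 30-second slot per compression cycle
# leaves room for the two rescue breaths.  These expected times anchor the
# green/orange timing check; the ±10 s default tolerance is generous enough
# that any fluent performance stays green.
_DEFAULT_TIMES: dict[str, float] = {
    "check_safety": 5.0,
    "check_consciousness": 15.0,
    "head_tilt": 25.0,
    "check_breathing": 35.0,
    "call_for_help": 45.0,
    "get_aed": 55.0,
    "check_carotid_pulse": 65.0,
    "cpr30_1": 70.0,
    "ventilation_1": 88.0,
    "cpr30_2": 100.0,
    "ventilation_2": 118.0,
    "cpr30_3": 130.0,
    "ventilation_3": 148.0,
    "cpr30_4": 160.0,
    "ventilation_4": 178.0,
    "cpr30_5": 190.0,
    "ventilation_5": 208.0,
    "carotid_pulse_2": 222.0,
    "aed_use_pad": 230.0,
    "aed_on_off": 238.0,
    "stand_clear": 246.0,
    "aed_shock": 252.0,
    "final_cpr": 258.0,
    "check_rhythm": 278.0,
}


def default_table() -> ScoringTable:
    """The ERC-2015 BLS checklist with the published weights (total 100)."""
    steps = tuple(
        StepSpec(
            step_id=sid,
            label=label,
            weight=w,
            order_index=i,
            evidence=evidence,
            expected_time_s=_DEFAULT_TIMES[sid],
        )
        for i, (sid, label, w, evidence) in enumerate(_DEFAULT_ROWS)
    )
    return ScoringTable(steps=steps, name="erc2015-bls")


def load_scoring_table(source: str | Path | Mapping = "default") -> ScoringTable:
    """Load and validate a scoring table.

    ``source`` may be the literal ``"default"`` (the built-in ERC-2015
    checklist), a mapping already in the document schema, or a path to a YAML
    or JSON document.  A document that declares a ``total`` whose step
    weights do not sum to it is rejected.
    """
    if isinstance(source, str) and source == "default":
        return default_table()
    if isinstance(source, Mapping):
        return ScoringTable.from_dict(source)
    path = Path(source)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    if not isinstance(doc, Mapping):
        raise ValidationError(f"{path}: scoring-table document must be a mapping")
    return ScoringTable.from_dict(doc)


def _interval(pair: Sequence[float], name: str) -> tuple[float, float]:
    lo, hi = float(pair[0]), float(pair[1])
    if lo > hi:
        raise ValidationError(f"{name}: interval low {lo} > high {hi}")
    return (lo, hi)


@dataclass(frozen=True)
class ComplianceWindows:
    """Closed intervals a compliant sensor event must fall into.

    ``rate_cpm`` (100-120 compressions/min) is the published protocol window;
    ``depth_mm`` and ``volume_ml`` default to the ERC-2015 adult guideline
    ranges.  Boundary values are compliant (closed intervals).
    """

    depth_mm: tuple[float, float] = (50.0, 60.0)
    rate_cpm: tuple[float, float] = (100.0, 120.0)
    volume_ml: tuple[float, float] = (400.0, 600.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "depth_mm", _interval(self.depth_mm, "depth_mm"))
        object.__setattr__(self, "rate_cpm", _interval(self.rate_cpm, "rate_cpm"))
        object.__setattr__(self, "volume_ml", _interval(self.volume_ml, "volume_ml"))

    @staticmethod
    def _contains(x: float, lo: float, hi: float) -> bool:
        tol = _BOUNDARY_RTOL * max(1.0, abs(lo), abs(hi))
        return (lo - tol) <= x <= (hi + tol)

    def depth_ok(self, depth_mm: float) -> bool:
        return self._contains(depth_mm, *self.depth_mm)

    def rate_ok(self, rate_cpm: float) -> bool:
        return self._contains(rate_cpm, *self.rate_cpm)

    def volume_ok(self, volume_ml: float) -> bool:
        return self._contains(volume_ml, *self.volume_ml)

    def to_dict(self) -> dict:
        return {
            "depth_mm": list(self.depth_mm),
            "rate_cpm": list(self.rate_cpm),
            "volume_ml": list(self.volume_ml),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ComplianceWindows":
        kwargs = {}
        for key in ("depth_mm", "rate_cpm", "volume_ml"):
            if key in d:
                kwargs[key] = tuple(d[key])
        return cls(**kwargs)


@dataclass(frozen=True)
class PassRule:
    """Success rule: a session passes iff its total score reaches the threshold."""

    threshold: float = 80.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.threshold <= 100.0):
            raise ValidationError(f"pass threshold must be in [0, 100], got {self.threshold}")


def classify_success(total: float, rule: PassRule | None = None) -> bool:
    """True iff ``total`` meets the pass threshold (inclusive: 80/100 passes).

    Raises ``ValueError`` if ``total`` is outside [0, 100].
    """
    if rule is None:
        rule = PassRule()
    if not (0.0 <= total <= 100.0 + _BOUNDARY_RTOL):
        raise ValueError(f"total score must be in [0, 100], got {total}")
    return total >= rule.threshold
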