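"""xAPI-style learning records: statement emission, append-only store, histories.

Every scored session yields one statement per checklist step (verb
``performed`` or ``omitted``, with the step's colour in the result) plus a
session summary statement (verb ``completed``) carrying the total score and
the pass flag.  Statements follow the actor/verb/object(/result) structure of
the Experience API, so exporting them to a real learning record store is a
transport concern only; here they are persisted to a JSON-Lines file, one
statement per line, append-only.

The minimal verb vocabulary: ``performed`` (step done), ``omitted`` (step not
done within the session), ``completed`` (session finished and scored).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .evaluate import ReportCard

__all__ = [
    "XapiStatement",
    "StatementStore",
    "StoreError",
    "VERB_PERFORMED",
    "VERB_OMITTED",
    "VERB_COMPLETED",
    "emit_statements",
    "history_report",
]

VERB_PERFORMED = "performed"
VERB_OMITTED = "omitted"
VERB_COMPLETED = "completed"

_EPOCH = datetime(2020, 1, 1, tzinfo=timezone.utc)


class StoreError(RuntimeError):
    """The statement store is unreadable or corrupt."""


@dataclass(frozen=True)
class XapiStatement:
    """One actor/verb/object(/result) learning record."""

    actor: str
    verb: str
    object: str
    result: Mapping | None = None
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not (self.actor and self.verb and self.object):
            raise ValueError("actor, verb and object must be non-empty")
        if self.result is not None and "score" in self.result:
            score = self.result["score"]
            if not (0.0 <= score <= 100.0):
                raise ValueError(f"result.score must be in [0, 100], got {score}")

    def to_dict(self) -> dict:
        d = {"actor": self.actor, "verb": self.verb, "object": self.object,
             "timestamp": self.timestamp}
        if self.result is not None:
            d["result"] = dict(self.result)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "XapiStatement":
        return cls(
            actor=d["actor"],
            verb=d["verb"],
            object=d["object"],
            result=d.get("result"),
            timestamp=d.get("timestamp", ""),
        )


def _iso(base: datetime, offset_s: float | None) -> str:
    if offset_s is None:
        offset_s = 0.0
    return (base + timedelta(seconds=offset_s)).isoformat().replace("+00:00", "Z")


def emit_statements(
    card: ReportCard,
    session_id: str | None = None,
    started_at: datetime | str | None = None,
) -> list[XapiStatement]:
    """Statements for a scored session: one per step plus one summary.

    Step statements use verb ``performed`` (green/orange, the colour in
    ``result.status``) or ``omitted`` (red — the step was not performed
    within the session).  Timestamps are the session start plus each step's
    observed offset.
    """
    if started_at is None:
        base = _EPOCH
    elif isinstance(started_at, str):
        base = datetime.fromisoformat(started_at.replace("Z", "+00:00"))
    else:
        base = started_at
    if session_id is None:
        session_id = f"{card.learner_id}-{card.mode_scored}"

    statements = []
    last_t = 0.0
    for r in card.step_results:
        verb = VERB_OMITTED if r.status == "red" else VERB_PERFORMED
        if r.observed_time_s is not None:
            last_t = max(last_t, r.observed_time_s)
        statements.append(
            XapiStatement(
                actor=card.learner_id,
                verb=verb,
                object=f"step/{r.step_id}",
                result={"status": r.status, "score": r.points},
                timestamp=_iso(base, r.observed_time_s),
            )
        )
    statements.append(
        XapiStatement(
            actor=card.learner_id,
            verb=VERB_COMPLETED,
            object=f"session/{session_id}",
            result={
                "score": card.total,
                "success": card.passed,
                "modality": card.mode_scored,
            },
            timestamp=_iso(base, last_t),
        )
    )
    return statements


class StatementStore:
    """Append-only JSON-Lines statement store (one statement per line)."""

    def __init__(self, path: str | Path):
        self.path = Path(path)

    def append(self, statements: Iterable[XapiStatement]) -> None:
        """Durably append statements; existing content is never touched."""
        with open(self.path, "a") as fh:
            for st in statements:
                fh.write(json.dumps(st.to_dict()) + "\n")
            fh.flush()

    def __iter__(self):
        if not self.path.exists():
            return iter(())
        return iter(self._read_all())

    def _read_all(self) -> list[XapiStatement]:
        out = []
        with open(self.path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    out.append(XapiStatement.from_dict(json.loads(line)))
                except (json.JSONDecodeError, KeyError, ValueError) as exc:
                    raise StoreError(f"{self.path}: corrupt statement at line {lineno}: {exc}") from exc
        return out

    def query(
        self,
        actor: str | None = None,
        since: str | None = None,
        until: str | None = None,
        verb: str | None = None,
    ) -> list[XapiStatement]:
        """Statements in insertion order, optionally filtered by actor/time/verb."""
        out = []
        for st in self:
            if actor is not None and st.actor != actor:
                continue
            if verb is not None and st.verb != verb:
                continue
            if since is not None and st.timestamp < since:
                continue
            if until is not None and st.timestamp > until:
                continue
            out.append(st)
        return out


def history_report(store: StatementStore, actor: str, pass_threshold: float = 80.0) -> dict:
    """Per-learner training history across modalities.

    ``trials_to_pass`` is the 1-based index of the first session whose
    summary score meets the pass threshold (inclusive), ``None`` if the
    learner never passed.  Appending sessions after the first pass does not
    change it.
    """
    sessions = []
    for st in store.query(actor=actor, verb=VERB_COMPLETED):
        res = dict(st.result or {})
        sessions.append(
            {
                "session": st.object,
                "modality": res.get("modality"),
                "score": res.get("score"),
                "success": res.get("success"),
                "timestamp": st.timestamp,
            }
        )
    scores = [s["score"] for s in sessions if s["score"] is not None]
    trials_to_pass = None
    for i, s in enumerate(sessions, start=1):
        if s["score"] is not None and s["score"] >= pass_threshold:
            trials_to_pass = i
            break
    by_modality: dict[str, list[float]] = {}
    for s in sessions:
        if s["modality"] is not None and s["score"] is not None:
            by_modality.setdefault(s["modality"], []).append(s["score"])
    return {
        "actor": actor,
        "sessions": sessions,
        "scores_by_modality": by_modality,
        "best_score": max(scores) if scores else None,
        "trials_to_pass": trials_to_pass,
    }
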