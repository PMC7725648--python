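"""Track a learner's progress through an xAPI-style statement store.

Scores two sessions of increasing quality, appends their statements to a
JSON-Lines store, and reads back the learner's history: trials to first
pass (score >= 80) and best score.
"""

import tempfile
from pathlib import Path

from blskit import StatementStore, default_table, emit_statements, history_report, score_session
from blskit.pipeline import simulate_session

table = default_table()
store = StatementStore(Path(tempfile.mkdtemp()) / "lrs.jsonl")

# Session 1: misses the final CPR block, an AED step and the consciousness
# check -> 71/100, below the 80-point pass mark.
rec1, *_ = simulate_session(
    table, learner_id="ayse", omit=["final_cpr", "stand_clear", "check_consciousness"]
)
card1 = score_session(rec1, table=table, mode="handson")
store.append(emit_statements(card1, session_id="handson-1"))

# Session 2: textbook performance -> passes.
rec2, *_ = simulate_session(table, learner_id="ayse")
card2 = score_session(rec2, table=table, mode="handson")
store.append(emit_statements(card2, session_id="handson-2"))

print(f"session 1: {card1.total:g}/100, session 2: {card2.total:g}/100")
h = history_report(store, "ayse")
print(f"trials to pass: {h['trials_to_pass']}  (first session reaching 80)")
print(f"best score: {h['best_score']:g}")
print(f"statements stored: {len(store.query(actor='ayse'))}  (25 per session: 24 steps + summary)")
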