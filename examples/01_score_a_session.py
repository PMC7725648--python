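"""Score a simulated BLS session in all three assessment modes.

Renders a textbook session (every checklist step on time, 30:2 compression
pattern at 110/min and 55 mm, 500 mL breaths), detects the events back out
of the telemetry, and grades them against the 100-point checklist.
"""

from blskit import default_table, render_report, score_session
from blskit.pipeline import simulate_session

table = default_table()
record, stream, truth, script = simulate_session(table)

for mode in ("handson", "osce", "game"):
    card = score_session(record, table=table, mode=mode)
    print(f"{mode:>8}: {card.total:g}/100  ({'PASS' if card.passed else 'FAIL'})")

# A degraded performance: shallow compressions (40 mm).  OSCE — which only
# sees that compressions happened — still awards full credit; hands-on mode
# strips the sensor-gated points (5 CPR blocks x 4 + Final CPR 15 = 35).
from blskit.pipeline import simulate_and_score

shallow_handson = simulate_and_score(mode="handson", degrade={"depth_mm": 40.0})
shallow_osce = simulate_and_score(mode="osce", degrade={"depth_mm": 40.0})
print(f"\nshallow compressions: handson {shallow_handson.total:g}, osce {shallow_osce.total:g}")

print("\nFull report card (hands-on):")
print(render_report(score_session(record, table=table, mode="handson"), table))
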