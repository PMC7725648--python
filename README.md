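# blskit

Desk-scale tooling for **basic life support (BLS) training assessment**. It
re-creates, in software, a blended training platform in which the same
100-point ERC-2015 BLS checklist is scored three ways: from a serious-game
play-through, from an instructor's visual OSCE checks, and from a hands-on
manikin session where the visual checks are combined with the manikin's
internal sensors (chest-compression depth and rate, ventilation volume).

The package is aimed at simulation-centre engineers and education
researchers who want to study how sensor-gated scoring differs from purely
observational OSCE scoring — without hardware: a built-in simulator
generates manikin telemetry with known ground truth.

## What's inside

| module | what it does |
| --- | --- |
| `blskit.protocol` | the 24-step checklist with its published weights (total 100), compliance windows, 80-point pass rule |
| `blskit.simulate` | synthetic manikin telemetry (50 Hz displacement + volume channels) from scripted sessions; cohort generator |
| `blskit.detect` | streaming hysteresis edge detection, misdetection filtering, windowed-average augmentation |
| `blskit.evaluate` | green/orange/red step grading, 30:2 cycle segmentation, sensor-compliance gating, report cards |
| `blskit.records` | xAPI-style statements (actor/verb/object/result), append-only JSON-Lines store, learner histories |
| `blskit.stats` | cohort descriptives, Mann–Whitney U, Spearman rho, Shapiro–Wilk |

## The scoring model

Each checklist step *i* has weight *w&#8537;* (the three zero-weight steps are
tracked but never change the total). A step is graded **green** (performed,
on time, in order), **orange** (performed but mistimed or out of order) or
**red** (not performed), and awards

&nbsp;&nbsp;&nbsp;&nbsp;points&#8537; = *w&#8537;* · *s&#8537;* · *c&#8537;*,

where *s&#8537;* ∈ {1, 0.5, 0} is the status multiplier and, in hands-on mode
only, *c&#8537;* ∈ [0, 1] is the fraction of the step's sensor events inside the
compliance windows — depth ∈ [50, 60] mm **and** instantaneous rate
∈ [100, 120] /min for compressions, volume ∈ [400, 600] mL for ventilations
(closed intervals). OSCE and game modes use *c&#8537;* = 1, so for any session
the hands-on total never exceeds the OSCE total. A session passes at
total ≥ 80/100.

## Worked example

```python
from blskit import default_table, score_session
from blskit.pipeline import simulate_session, simulate_and_score

table = default_table()
record, stream, truth, script = simulate_session(table)   # textbook session
for mode in ("handson", "osce", "game"):
    print(mode, score_session(record, table=table, mode=mode).total)
# handson 100.0
# osce 100.0
# game 100.0

# shallow compressions (40 mm): OSCE can't see depth, the sensors can
print(simulate_and_score(mode="osce",    degrade={"depth_mm": 40.0}).total)  # 100.0
print(simulate_and_score(mode="handson", degrade={"depth_mm": 40.0}).total)  # 65.0
```

The 35-point gap is exactly the sensor-gated weight (five CPR30 blocks × 4
plus Final CPR 15): the session *looks* complete to an observer, but every
compression fails the depth window. This is the mechanism by which
observational and sensor-based scores of the same performance diverge.

The `examples/` directory has four narrative scripts (scoring, event
detection, learning records, cohort statistics); each prints the numbers it
computes with a line on what they mean. A thin CLI mirrors the library:

```sh
blskit simulate --style perfect --seed 1 --out stream.csv --marks marks.json
blskit detect --stream stream.csv --out events.json
blskit score --events events.json --marks marks.json --mode handson --out card.json
blskit report card.json
```

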