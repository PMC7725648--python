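# Methods

## The assessment model

`blskit` scores a BLS performance against an ordered 24-step ERC-2015
checklist whose weights total 100 points. The same checklist is scored in
three modes:

- **game** — virtual play-through; step evidence comes from timestamped
  action marks; no sensor data exists.
- **osce** — observational scoring of a hands-on session; step evidence is
  the instructor's visual marks plus the mere occurrence of compressions
  and ventilations.
- **handson** — as OSCE, plus the manikin's sensors gate the
  compression/ventilation steps by measured quality.

Step status follows the three-colour scheme: **red** = not performed (0
points), **orange** = performed but outside the timing window or out of
sequence (half credit), **green** = performed, on time and in order (full
credit). The half-credit multiplier for orange is a design choice — the
colour scheme distinguishes "applied with wrong timing" from full credit
but no partial-credit arithmetic is standard, so the multiplier is an
argument of `score_session` (`orange_credit`, default 0.5).

Sensor gating is proportional: a sensor step's points are multiplied by the
fraction of its events inside the compliance windows. A proportional
multiplier degrades smoothly (10% shallow compressions cost 10% of the
block's credit, not all of it) and makes the hands-on ≤ OSCE ordering hold
identically, since the multiplier is ≤ 1. A hard-cutoff rule can be
recovered by thresholding the fraction downstream; we deliberately did not
make it the default.

An **ordering violation downgrades to orange, not red**: the step *was*
applied; red is reserved for steps not applied at all. One consequence
worth knowing: a badly mistimed step also knocks the immediately following
step out of order (its observed time now precedes the mistimed step's), so
a single gross timing error can cost 1.5× the naive expectation. This is
faithful to a sequential checklist read left to right.

## Parameters and defaults

| parameter | default | units | why |
| --- | --- | --- | --- |
| compression depth window | [50, 60] | mm | ERC-2015 adult guideline range |
| compression rate window | [100, 120] | /min | the protocol's stated metronome band |
| ventilation volume window | [400, 600] | mL | ERC-2015 adult guideline range |
| pass threshold | 80 (inclusive) | points | the platform's success rule |
| timing tolerance | ±10 | s | generous half-width; any fluent performance stays green |
| orange credit | 0.5 | — | see above |
| cycle-splitting gap | 2 | s | a pause ≥ 2 s at 100–120/min is > 3 missed compressions — clearly a block boundary |

All windows are closed intervals. Membership is evaluated with a 1e-9
relative tolerance so a value sitting exactly on a boundary (a 120/min
train) is never rejected by floating-point round-off.

## The simulator

The generator emulates a sensored manikin's two channels at 50 Hz (>10× the
~2 Hz compression frequency): each compression is a half-sine displacement
pulse of amplitude = depth and period = 60/rate (positive = chest
depressed); each ventilation a half-sine volume pulse of peak = delivered
volume (1.2 s duration, 2 s spacing within a pair). The textbook script
performs every step at its nominal time with 30-compression blocks at
110/min and 55 mm and 500 mL breath pairs — the 30:2 pattern with five
cycles plus a post-shock Final CPR block. Optional Gaussian noise is added
per channel, and spurious "artifact" bumps (default 16–19 mm, 0.3 s) land
in quiet parts of the displacement channel to exercise misdetection
filtering.

What the simulator does **not** emulate: thorax mechanics (leaning,
incomplete recoil, depth-rate coupling), baseline drift, sensor dropout,
Bluetooth transport, or correlated noise. Passing tests therefore show the
*pipeline* is correct under clean-to-moderately-noisy conditions with known
ground truth; they do not certify detector thresholds against real manikin
data, whose native sampling rate and noise spectrum are hardware-specific.

The cohort generator draws per-learner modality scores from clamped normal
distributions whose defaults (game 88.3 ± 5.1, hands-on 70.7 ± 17.3, OSCE
84.4 ± 12.9, 44% male, pass-on-trial probabilities 0.68/0.24/0.08) mirror a
published 25-participant pilot cohort's summaries. The three modality
scores are drawn independently — the generator reproduces marginal shapes,
not the (unpublished) per-learner joint distribution, so cohort-level
correlations hover near zero by construction.

## Event detection

Dual-threshold (hysteresis) edge detection per channel: an event opens at
the on-threshold (15 mm / 100 mL) and closes at the off-threshold (10 mm /
50 mL); the gap between the thresholds prevents chatter near a single
threshold. Defaults are engineering choices — only "rising and falling
edges" is inherent to the approach — and all sit in `DetectorConfig`.

The peak inside each event is refined by a three-point parabolic fit around
the maximum sample. This matters: peak-to-peak intervals define the
instantaneous rate, and at 50 Hz the raw argmax quantises intervals to
20 ms, i.e. up to ±4/min of rate error at 120/min — enough to misjudge the
window boundaries. With the parabolic refinement, noise-free trains are
recovered to better than 0.01/min. The refined peak time is clamped into
the event's [start, end] span (under noise the fit can otherwise stray one
sample outside).

Filtering removes events below the depth/volume floor (20 mm / 150 mL),
with implausible durations (outside [0.05, 3] s), or starting within 0.2 s
of the previously kept event's start (keep-first debounce — deterministic
and causal). Rates are recomputed over the survivors, which makes the
filter idempotent. Windowed augmentation attaches the arithmetic mean of
both channels over ±0.5 s around each peak, truncated at stream
boundaries rather than dropped, so first/last events are still augmented.

The detector is a single-pass state machine; its output is invariant to how
the sample stream is chunked (verified by property test). An event still
open at end-of-stream has no falling edge and is dropped.

## Cycle segmentation

Pre-shock compressions split into maximal runs separated by a ≥ 2 s
peak-to-peak pause or an intervening ventilation; the first five runs are
the CPR30 blocks, extra runs merge into the fifth (the nearest expected
boundary — deterministic), and missing runs leave later blocks red.
Ventilations between consecutive blocks (or between the last block and the
shock) form the numbered breath pairs. The AED-shock time comes from the
instructor's mark unless given explicitly; everything after it is Final
CPR.

`compliance_fraction` checks the first event of a block against the
*following* interval (its own rate refers to a predecessor outside the
block); a single-compression block has no interval at all and is checked on
depth alone. An empty block is red with fraction 0.

## Degenerate inputs and tie-breaks

- Empty streams, empty blocks, sessions with no events: scored all-red,
  total 0; never an error.
- A performed step with no usable timestamp grades orange (timing
  unverifiable), not green.
- "BLS Training" practice sessions are refused by the scorer — that mode is
  never recorded.
- Statement stores are strictly append-only; a corrupt line fails loudly
  with its line number.

## A note on deletion monotonicity

"Removing evidence never raises a score" holds from a fully compliant
session (removing a compliant event can only lower a block's compliance
fraction and worsen a neighbour's rate), and omitting a whole step always
costs its points. It is **not** a theorem of the general model: with a
per-event compliance fraction, deleting a *non-compliant* event raises the
fraction, and removing a mistimed step can restore a later step's ordering.
The property tests assert the regime where the property genuinely holds;
the general arithmetic follows the fraction definition, which the
rate-window behaviour depends on.

## Statistics

Descriptives are mean/SD (ddof = 1)/median/range. Group comparisons use the
two-sided Mann–Whitney U (scipy: exact p for small tie-free samples, else
normal approximation with tie correction); correlations use Spearman's rho
with average ranks for ties; normality screening uses Shapiro–Wilk
(3 ≤ n ≤ 5000; constant samples rejected). α = .05, two-sided, no
multiple-testing correction — matching the analysis layer this reproduces.
The test suite cross-checks U, rho and the exact p against brute-force
enumeration on small inputs.

## Problem sizes

The test suite and the acceptance script work at desk scale: full sessions
are ~285 s of 50 Hz telemetry (~14,000 samples, 190 true events), rate
sweeps use 61 thirty-compression trains, detector-recovery checks run 20
seeds clean + 20 noisy, and the property suite runs 100 randomized cases
per invariant on synthetic event lists. The whole suite runs in a few
seconds on one core.
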