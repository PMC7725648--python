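"""Synthetic manikin telemetry with known ground truth.

Stands in for the Bluetooth CPR manikin: it renders scripted learner sessions
into a two-channel sensor stream (chest displacement in mm, positive =
chest depressed; lung volume in mL) sampled uniformly, plus a ground-truth
event log.  Compressions are half-sine displacement pulses whose amplitude is
the compression depth and whose period is the inter-compression interval
(60/rate); ventilations are half-sine volume pulses whose peak is the
delivered volume.  Gaussian sensor noise and sub-threshold artifact bumps
(to exercise misdetection filtering) are optional.

Also provides the cohort generator that feeds the statistics layer with
per-learner modality scores shaped like the study table (game / hands-on /
OSCE score, sex, trials-to-pass).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .protocol import (
    SENSOR_COMPRESSION,
    SENSOR_VENTILATION,
    VISUAL,
    ScoringTable,
)

__all__ = [
    "ScriptedAction",
    "SimulatorConfig",
    "SensorStream",
    "GroundTruth",
    "ScriptError",
    "script_session",
    "render_stream",
    "compression_train",
    "generate_cohort",
    "write_stream_csv",
    "read_stream_csv",
]


class ScriptError(ValueError):
    """A session script is internally inconsistent (overlap, unknown step...)."""


# Default action parameters of a textbook performance: 30 compressions per
# CPR block at 110/min and 55 mm depth, rescue breaths of 500 mL.
PERFECT_PARAMS: dict = {
    "n_compressions": 30,
    "rate_cpm": 110.0,
    "depth_mm": 55.0,
    "depth_sd_mm": 0.0,
    "n_ventilations": 2,
    "volume_ml": 500.0,
    "volume_sd_ml": 0.0,
    "ventilation_duration_s": 1.2,
    "ventilation_spacing_s": 2.0,
}


@dataclass(frozen=True)
class ScriptedAction:
    """One checklist action in a scripted session.

    ``params`` carries waveform parameters for sensor-tracked actions
    (``n_compressions``/``rate_cpm``/``depth_mm`` for compression blocks,
    ``n_ventilations``/``volume_ml`` for rescue breaths); visual actions have
    empty params and produce no telemetry.
    """

    step_id: str
    start_s: float
    performed: bool = True
    params: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise ScriptError(f"action {self.step_id!r}: start_s must be >= 0")
        n = self.params.get("n_compressions", 0)
        if n < 0:
            raise ScriptError(f"action {self.step_id!r}: n_compressions must be >= 0")

    def merged_params(self) -> dict:
        out = dict(PERFECT_PARAMS)
        out.update(self.params)
        return out

    def to_dict(self) -> dict:
        return {
            "step_id": self.step_id,
            "start_s": self.start_s,
            "performed": self.performed,
            "params": dict(self.params),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScriptedAction":
        return cls(
            step_id=d["step_id"],
            start_s=float(d["start_s"]),
            performed=bool(d.get("performed", True)),
            params=dict(d.get("params", {})),
        )


@dataclass(frozen=True)
class SimulatorConfig:
    """Rendering knobs for the synthetic manikin.

    50 Hz sampling is well above the ~2 Hz compression frequency.  Artifact
    bumps default to amplitudes between the detector's on-threshold and its
    minimum-depth floor, so they are detected as edges but removed by the
    misdetection filter.
    """

    sampling_rate_hz: float = 50.0
    noise_sd_mm: float = 0.0
    noise_sd_ml: float = 0.0
    artifact_rate_per_min: float = 0.0
    artifact_amp_mm: tuple[float, float] = (16.0, 19.0)
    artifact_duration_s: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if self.noise_sd_mm < 0 or self.noise_sd_ml < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.artifact_rate_per_min < 0:
            raise ValueError("artifact_rate_per_min must be >= 0")


@dataclass
class SensorStream:
    """Uniformly sampled two-channel telemetry."""

    t: np.ndarray
    displacement_mm: np.ndarray
    volume_ml: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        self.volume_ml = np.asarray(self.volume_ml, dtype=float)
        n = self.t.size
        if self.displacement_mm.size != n or self.volume_ml.size != n:
            raise ValueError("channel lengths must match the time axis")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if np.any(np.abs(dt - dt[0]) > 1e-9):
                raise ValueError("sampling must be uniform (within 1e-9 s)")
        if not (np.all(np.isfinite(self.displacement_mm)) and np.all(np.isfinite(self.volume_ml))):
            raise ValueError("channel values must be finite")

    def __len__(self) -> int:
        return int(self.t.size)


@dataclass
class GroundTruth:
    """What the simulator actually rendered, for oracle comparisons.

    ``compressions``/``ventilations`` list every true event as
    ``{"t_peak_s", "depth_mm"|"volume_ml", "step_id"}``; ``artifacts`` lists
    spurious bumps that a correct pipeline must reject.
    """

    compressions: list[dict] = field(default_factory=list)
    ventilations: list[dict] = field(default_factory=list)
    artifacts: list[dict] = field(default_factory=list)
    actions: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "compressions": self.compressions,
            "ventilations": self.ventilations,
            "artifacts": self.artifacts,
            "actions": self.actions,
        }


def script_session(
    table: ScoringTable,
    omit: Sequence[str] = (),
    delay: Mapping[str, float] | None = None,
    degrade: Mapping[str, float] | Mapping[str, Mapping] | None = None,
) -> list[ScriptedAction]:
    """Build a scripted session covering every step of ``table``.

    With no perturbations the script is a textbook performance: every step at
    its expected time, CPR blocks of 30 compressions at 110/min and 55 mm,
    rescue-breath pairs of 500 mL (the 30:2 pattern).

    ``omit`` marks the named steps as not performed; ``delay`` shifts the
    named steps' start times by the given seconds; ``degrade`` overrides
    waveform parameters — either globally (``{"rate_cpm": 90}`` applies to
    every sensor action that uses the parameter) or per step
    (``{"cpr30_1": {"depth_mm": 40}}``).
    """
    delay = dict(delay or {})
    degrade = dict(degrade or {})
    for sid in list(omit) + list(delay):
        table.step(sid)  # KeyError for unknown ids
    per_step_degrade = {k: dict(v) for k, v in degrade.items() if isinstance(v, Mapping)}
    global_degrade = {k: v for k, v in degrade.items() if not isinstance(v, Mapping)}
    for sid in per_step_degrade:
        table.step(sid)

    actions: list[ScriptedAction] = []
    for step in table:
        start = step.expected_time_s + delay.get(step.step_id, 0.0)
        if step.evidence == SENSOR_COMPRESSION:
            params = {
                "n_compressions": PERFECT_PARAMS["n_compressions"],
                "rate_cpm": PERFECT_PARAMS["rate_cpm"],
                "depth_mm": PERFECT_PARAMS["depth_mm"],
                "depth_sd_mm": PERFECT_PARAMS["depth_sd_mm"],
            }
        elif step.evidence == SENSOR_VENTILATION:
            params = {
                "n_ventilations": PERFECT_PARAMS["n_ventilations"],
                "volume_ml": PERFECT_PARAMS["volume_ml"],
                "volume_sd_ml": PERFECT_PARAMS["volume_sd_ml"],
            }
        else:
            params = {}
        for key, value in global_degrade.items():
            if key in params:
                params[key] = value
        for key, value in per_step_degrade.get(step.step_id, {}).items():
            params[key] = value
        actions.append(
            ScriptedAction(
                step_id=step.step_id,
                start_s=start,
                performed=step.step_id not in omit,
                params=params,
            )
        )
    return actions


def _add_half_sine(channel: np.ndarray, t: np.ndarray, t0: float, duration: float, peak: float) -> None:
    """Add ``peak * sin(pi (t-t0)/duration)`` on [t0, t0+duration)."""
    i0 = int(np.searchsorted(t, t0, side="left"))
    i1 = int(np.searchsorted(t, t0 + duration, side="left"))
    if i1 <= i0:
        return
    phase = (t[i0:i1] - t0) / duration
    channel[i0:i1] += peak * np.sin(np.pi * np.clip(phase, 0.0, 1.0))


def render_stream(
    script: Iterable[ScriptedAction],
    cfg: SimulatorConfig | None = None,
) -> tuple[SensorStream, GroundTruth]:
    """Render a scripted session into telemetry plus its ground-truth log.

    Deterministic for a fixed config (identical seed → identical stream).
    Raises :class:`ScriptError` if two actions overlap on one channel.
    """
    if cfg is None:
        cfg = SimulatorConfig()
    rng = np.random.default_rng(cfg.seed)
    script = list(script)

    # Pre-compute the occupied interval of every performed sensor action.
    spans: list[tuple[float, float, str, ScriptedAction]] = []  # (t0, t1, channel, action)
    for action in script:
        if not action.performed:
            continue
        p = action.merged_params()
        if _is_compression(action):
            period = 60.0 / float(p["rate_cpm"])
            dur = p["n_compressions"] * period
            spans.append((action.start_s, action.start_s + dur, "displacement", action))
        elif _is_ventilation(action):
            n = int(p["n_ventilations"])
            dur = (n - 1) * p["ventilation_spacing_s"] + p["ventilation_duration_s"] if n else 0.0
            spans.append((action.start_s, action.start_s + dur, "volume", action))

    for chan in ("displacement", "volume"):
        chan_spans = sorted((s for s in spans if s[2] == chan), key=lambda s: s[0])
        for (a0, a1, _, aa), (b0, b1, _, ab) in zip(chan_spans, chan_spans[1:]):
            if b0 < a1 - 1e-12:
                raise ScriptError(
                    f"actions {aa.step_id!r} and {ab.step_id!r} overlap on the {chan} channel"
                )

    t_end = max((s[1] for s in spans), default=0.0) + 5.0
    for action in script:
        t_end = max(t_end, action.start_s + 5.0)
    dt = 1.0 / cfg.sampling_rate_hz
    n_samples = int(np.ceil(t_end / dt)) + 1
    t = np.arange(n_samples) * dt
    disp = np.zeros(n_samples)
    vol = np.zeros(n_samples)

    truth = GroundTruth(actions=[a.to_dict() for a in script])
    for t0, _t1, chan, action in sorted(spans, key=lambda s: s[0]):
        p = action.merged_params()
        if chan == "displacement":
            period = 60.0 / float(p["rate_cpm"])
            for k in range(int(p["n_compressions"])):
                depth = float(p["depth_mm"])
                if p["depth_sd_mm"] > 0:
                    depth = max(0.0, rng.normal(depth, p["depth_sd_mm"]))
                start = t0 + k * period
                _add_half_sine(disp, t, start, period, depth)
                truth.compressions.append(
                    {"t_peak_s": start + period / 2.0, "depth_mm": depth, "step_id": action.step_id}
                )
        else:
            for k in range(int(p["n_ventilations"])):
                volume = float(p["volume_ml"])
                if p["volume_sd_ml"] > 0:
                    volume = max(0.0, rng.normal(volume, p["volume_sd_ml"]))
                start = t0 + k * p["ventilation_spacing_s"]
                dur = p["ventilation_duration_s"]
                _add_half_sine(vol, t, start, dur, volume)
                truth.ventilations.append(
                    {"t_peak_s": start + dur / 2.0, "volume_ml": volume, "step_id": action.step_id}
                )

    if cfg.artifact_rate_per_min > 0:
        _add_artifacts(disp, t, spans, cfg, rng, truth)

    if cfg.noise_sd_mm > 0:
        disp += rng.normal(0.0, cfg.noise_sd_mm, size=n_samples)
    if cfg.noise_sd_ml > 0:
        vol += rng.normal(0.0, cfg.noise_sd_ml, size=n_samples)

    stream = SensorStream(t=t, displacement_mm=disp, volume_ml=vol, sampling_rate_hz=cfg.sampling_rate_hz)
    return stream, truth


def _is_compression(action: ScriptedAction) -> bool:
    p = action.merged_params()
    return ("n_compressions" in action.params or "depth_mm" in action.params or "rate_cpm" in action.params) and int(p["n_compressions"]) > 0


def _is_ventilation(action: ScriptedAction) -> bool:
    p = action.merged_params()
    return ("n_ventilations" in action.params or "volume_ml" in action.params) and int(p["n_ventilations"]) > 0


def _add_artifacts(disp, t, spans, cfg, rng, truth) -> None:
    """Drop sub-threshold bumps into quiet parts of the displacement channel."""
    duration_min = t[-1] / 60.0
    n_art = rng.poisson(cfg.artifact_rate_per_min * duration_min)
    busy = [(t0 - 1.0, t1 + 1.0) for t0, t1, chan, _ in spans if chan == "displacement"]
    placed: list[float] = []
    attempts = 0
    while len(placed) < n_art and attempts < 50 * max(1, n_art):
        attempts += 1
        start = rng.uniform(0.0, max(t[-1] - cfg.artifact_duration_s, 0.0))
        end = start + cfg.artifact_duration_s
        if any(start < b1 and end > b0 for b0, b1 in busy):
            continue
        if any(abs(start - p) < 2.0 * cfg.artifact_duration_s for p in placed):
            continue
        amp = rng.uniform(*cfg.artifact_amp_mm)
        _add_half_sine(disp, t, start, cfg.artifact_duration_s, amp)
        truth.artifacts.append({"t_peak_s": start + cfg.artifact_duration_s / 2.0, "depth_mm": amp})
        placed.append(start)


def compression_train(
    rate_cpm: float,
    n: int = 30,
    depth_mm: float = 55.0,
    cfg: SimulatorConfig | None = None,
    start_s: float = 1.0,
) -> tuple[SensorStream, GroundTruth]:
    """A single uniform compression train — the workhorse for rate sweeps."""
    action = ScriptedAction(
        step_id="cpr",
        start_s=start_s,
        params={"n_compressions": n, "rate_cpm": rate_cpm, "depth_mm": depth_mm, "depth_sd_mm": 0.0},
    )
    return render_stream([action], cfg)


# ---------------------------------------------------------------------------
# Stream CSV I/O

_CSV_HEADER = "t_s,displacement_mm,volume_ml"
_CSV_FMT = "%.6f"


def write_stream_csv(stream: SensorStream, path: str | Path) -> None:
    """Write a stream as CSV (header ``t_s,displacement_mm,volume_ml``).

    Fixed 6-decimal formatting keeps output bit-identical across runs for a
    fixed seed.
    """
    data = np.column_stack([stream.t, stream.displacement_mm, stream.volume_ml])
    np.savetxt(path, data, fmt=_CSV_FMT, delimiter=",", header=_CSV_HEADER, comments="")


def read_stream_csv(path: str | Path, sampling_rate_hz: float | None = None) -> SensorStream:
    df = pd.read_csv(path)
    expected = _CSV_HEADER.split(",")
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    t = df["t_s"].to_numpy()
    if sampling_rate_hz is None:
        if len(t) < 2:
            raise ValueError(f"{path}: cannot infer sampling rate from {len(t)} sample(s)")
        sampling_rate_hz = 1.0 / float(np.median(np.diff(t)))
    # Rebuild a numerically uniform time axis (CSV text has finite precision).
    dt = 1.0 / sampling_rate_hz
    t_uniform = np.round(t / dt).astype(int) * dt
    return SensorStream(
        t=t_uniform,
        displacement_mm=df["displacement_mm"].to_numpy(),
        volume_ml=df["volume_ml"].to_numpy(),
        sampling_rate_hz=sampling_rate_hz,
    )


# ---------------------------------------------------------------------------
# Cohort generation

# Defaults mirror the study cohort's reported summaries: modality score
# means/SDs, 44% male participants, and the pass-on-trial-k distribution
# (68% / 24% / 8% on trials 1 / 2 / 3).
DEFAULT_SCORE_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "game_score": (88.3, 5.1),
    "handson_score": (70.7, 17.3),
    "osce_score": (84.4, 12.9),
}
DEFAULT_TRIALS_PMF: tuple[float, ...] = (0.68, 0.24, 0.08)
DEFAULT_MALE_FRACTION = 0.44


def generate_cohort(
    n: int,
    distributions: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    male_fraction: float = DEFAULT_MALE_FRACTION,
    trials_pmf: Sequence[float] = DEFAULT_TRIALS_PMF,
) -> pd.DataFrame:
    """Draw a synthetic cohort of per-learner modality scores.

    Scores are normal draws clamped to [0, 100]; ``trials_to_pass`` is drawn
    from ``trials_pmf`` (probability of first passing on trial 1, 2, ...).
    Reproducible given ``seed``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    dists = dict(DEFAULT_SCORE_DISTRIBUTIONS)
    if distributions:
        dists.update(distributions)
    for name, (mu, sd) in dists.items():
        if sd < 0:
            raise ValueError(f"{name}: standard deviation must be >= 0")
    pmf = np.asarray(trials_pmf, dtype=float)
    if pmf.ndim != 1 or pmf.size == 0 or np.any(pmf < 0) or not np.isclose(pmf.sum(), 1.0):
        raise ValueError("trials_pmf must be a probability vector summing to 1")
    if not (0.0 <= male_fraction <= 1.0):
        raise ValueError("male_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    rows: dict[str, object] = {"learner_id": [f"learner{i + 1:04d}" for i in range(n)]}
    rows["sex"] = np.where(rng.random(n) < male_fraction, "male", "female")
    for name, (mu, sd) in dists.items():
        rows[name] = np.clip(rng.normal(mu, sd, size=n), 0.0, 100.0)
    rows["trials_to_pass"] = rng.choice(np.arange(1, pmf.size + 1), size=n, p=pmf)
    return pd.DataFrame(rows)
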