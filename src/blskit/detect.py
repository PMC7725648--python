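"""Edge-detection event extraction from manikin telemetry.

The software twin of the manikin-service pipeline: sensor samples are tracked
linearly (a single streaming pass) to detect rising and falling edges, which
are turned into compression and ventilation events; the event list is then
filtered for misdetections and augmented with windowed channel averages.

Detection uses a dual-threshold (hysteresis) scheme per channel: an event
opens when the signal rises to the on-threshold and closes when it falls to
the off-threshold, which prevents chatter from noise near a single
threshold.  The peak inside each event is refined to sub-sample precision by
fitting a parabola through the three samples around the maximum, so that
peak-to-peak intervals — and the instantaneous compression rate derived from
them — do not inherit the sampling grid's quantisation.

The streaming contract: processing a stream in arbitrary chunks yields
exactly the same events as processing it in one shot
(:class:`StreamingEdgeDetector` keeps all cross-chunk state).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .simulate import SensorStream

__all__ = [
    "DetectorConfig",
    "CompressionEvent",
    "VentilationEvent",
    "StreamingEdgeDetector",
    "detect_compressions",
    "detect_ventilations",
    "filter_misdetections",
    "augment_events",
    "write_events_json",
    "read_events_json",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds and filters of the event pipeline.

    The hysteresis pairs (``on`` must exceed ``off``) are in channel units:
    mm of chest displacement, mL of lung volume.  ``min_depth_mm`` /
    ``min_volume_ml`` are the misdetection floors — events whose peak stays
    below them are discarded as spurious bumps.  ``min_event_gap_s``
    debounces events whose starts are implausibly close (the earlier event is
    kept).  ``augment_window_s`` is the half-width of the averaging window
    around each event peak.
    """

    on_threshold_mm: float = 15.0
    off_threshold_mm: float = 10.0
    on_threshold_ml: float = 100.0
    off_threshold_ml: float = 50.0
    min_depth_mm: float = 20.0
    min_volume_ml: float = 150.0
    min_event_gap_s: float = 0.2
    min_duration_s: float = 0.05
    max_duration_s: float = 3.0
    augment_window_s: float = 0.5

    def __post_init__(self) -> None:
        for on, off, unit in (
            (self.on_threshold_mm, self.off_threshold_mm, "mm"),
            (self.on_threshold_ml, self.off_threshold_ml, "ml"),
        ):
            if off <= 0 or on <= 0:
                raise ValueError(f"hysteresis thresholds ({unit}) must be positive")
            if on <= off:
                raise ValueError(
                    f"on-threshold must exceed off-threshold ({unit}): on={on}, off={off}"
                )
        if self.min_event_gap_s < 0 or self.min_duration_s < 0:
            raise ValueError("durations and gaps must be >= 0")
        if self.max_duration_s <= self.min_duration_s:
            raise ValueError("max_duration_s must exceed min_duration_s")


@dataclass(frozen=True)
class CompressionEvent:
    """One detected chest compression."""

    t_start_s: float
    t_peak_s: float
    t_end_s: float
    depth_mm: float
    inst_rate_cpm: float | None = None  # 60 / interval to previous peak; None for the first event
    augmented: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not (self.t_start_s <= self.t_peak_s <= self.t_end_s):
            raise ValueError("event times must satisfy t_start <= t_peak <= t_end")

    def to_dict(self) -> dict:
        return {
            "t_start_s": self.t_start_s,
            "t_peak_s": self.t_peak_s,
            "t_end_s": self.t_end_s,
            "depth_mm": self.depth_mm,
            "inst_rate_cpm": self.inst_rate_cpm,
            "augmented": dict(self.augmented) if self.augmented is not None else None,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CompressionEvent":
        return cls(
            t_start_s=float(d["t_start_s"]),
            t_peak_s=float(d["t_peak_s"]),
            t_end_s=float(d["t_end_s"]),
            depth_mm=float(d["depth_mm"]),
            inst_rate_cpm=None if d.get("inst_rate_cpm") is None else float(d["inst_rate_cpm"]),
            augmented=d.get("augmented"),
        )


@dataclass(frozen=True)
class VentilationEvent:
    """One detected rescue breath."""

    t_start_s: float
    t_peak_s: float
    t_end_s: float
    volume_ml: float
    augmented: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not (self.t_start_s <= self.t_peak_s <= self.t_end_s):
            raise ValueError("event times must satisfy t_start <= t_peak <= t_end")
        if self.t_start_s >= self.t_end_s:
            raise ValueError("t_start must precede t_end")

    def to_dict(self) -> dict:
        return {
            "t_start_s": self.t_start_s,
            "t_peak_s": self.t_peak_s,
            "t_end_s": self.t_end_s,
            "volume_ml": self.volume_ml,
            "augmented": dict(self.augmented) if self.augmented is not None else None,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "VentilationEvent":
        return cls(
            t_start_s=float(d["t_start_s"]),
            t_peak_s=float(d["t_peak_s"]),
            t_end_s=float(d["t_end_s"]),
            volume_ml=float(d["volume_ml"]),
            augmented=d.get("augmented"),
        )


@dataclass
class _RawEvent:
    t_start_s: float
    t_peak_s: float
    t_end_s: float
    peak: float


class StreamingEdgeDetector:
    """Single-pass hysteresis edge detector over one channel.

    Feed samples with :meth:`process` (any chunking); completed events are
    returned as they close.  State carries across chunks, so the result is
    identical however the stream is split.
    """

    def __init__(self, on_threshold: float, off_threshold: float):
        if on_threshold <= off_threshold:
            raise ValueError("on_threshold must exceed off_threshold")
        self.on = float(on_threshold)
        self.off = float(off_threshold)
        self._in_event = False
        self._t_start = 0.0
        self._t_max = 0.0
        self._y_max = -np.inf
        self._y_before = None  # sample just before the running max
        self._y_after = None  # sample just after the running max
        self._t_prev: float | None = None
        self._y_prev: float | None = None
        self._dt: float | None = None

    def process(self, t: Sequence[float], x: Sequence[float]) -> list[_RawEvent]:
        t = np.asarray(t, dtype=float)
        x = np.asarray(x, dtype=float)
        if t.shape != x.shape:
            raise ValueError("t and x must have the same length")
        out: list[_RawEvent] = []
        for ti, xi in zip(t, x):
            if self._t_prev is not None:
                if ti <= self._t_prev:
                    raise ValueError("timestamps must be strictly increasing across samples")
                self._dt = ti - self._t_prev
            if not self._in_event:
                if xi >= self.on:
                    self._in_event = True
                    self._t_start = ti
                    self._t_max = ti
                    self._y_max = xi
                    self._y_before = self._y_prev
                    self._y_after = None
            else:
                if xi > self._y_max:
                    self._y_before = self._y_prev
                    self._y_max = xi
                    self._t_max = ti
                    self._y_after = None
                elif self._y_after is None:
                    self._y_after = xi
                if xi <= self.off:
                    out.append(self._close(ti))
            self._t_prev = ti
            self._y_prev = xi
        return out

    def finish(self) -> list[_RawEvent]:
        """End of stream.  An event still open has no falling edge and is dropped."""
        self._in_event = False
        return []

    def _close(self, t_end: float) -> _RawEvent:
        t_peak, peak = self._t_max, self._y_max
        if (
            self._y_before is not None
            and self._y_after is not None
            and self._dt is not None
        ):
            # Parabolic (three-point) sub-sample peak refinement.
            denom = self._y_before - 2.0 * self._y_max + self._y_after
            if denom < -1e-12:
                offset = 0.5 * (self._y_before - self._y_after) / denom
                offset = float(np.clip(offset, -0.5, 0.5))
                t_peak = self._t_max + offset * self._dt
                peak = self._y_max - 0.25 * (self._y_before - self._y_after) * offset
                # the refined peak must stay inside the event
                t_peak = min(max(t_peak, self._t_start), t_end)
        self._in_event = False
        self._y_max = -np.inf
        self._y_before = None
        self._y_after = None
        return _RawEvent(t_start_s=self._t_start, t_peak_s=t_peak, t_end_s=t_end, peak=peak)


def _assign_rates(events: list[CompressionEvent]) -> list[CompressionEvent]:
    """Recompute instantaneous rates from consecutive peak intervals."""
    out: list[CompressionEvent] = []
    for i, ev in enumerate(events):
        if i == 0:
            rate = None
        else:
            interval = ev.t_peak_s - events[i - 1].t_peak_s
            rate = 60.0 / interval if interval > 0 else None
        out.append(replace(ev, inst_rate_cpm=rate))
    return out


def detect_compressions(
    stream: SensorStream, cfg: DetectorConfig | None = None
) -> list[CompressionEvent]:
    """Detect chest compressions on the displacement channel.

    One event per excursion that crosses the on-threshold upward and later
    the off-threshold downward; depth is the (sub-sample refined) peak
    displacement between the edges.  Events are time-ordered and carry
    instantaneous rates from peak-to-peak intervals.  No misdetection
    filtering is applied here — see :func:`filter_misdetections`.
    """
    if cfg is None:
        cfg = DetectorConfig()
    det = StreamingEdgeDetector(cfg.on_threshold_mm, cfg.off_threshold_mm)
    raw = det.process(stream.t, stream.displacement_mm)
    raw += det.finish()
    events = [
        CompressionEvent(
            t_start_s=r.t_start_s, t_peak_s=r.t_peak_s, t_end_s=r.t_end_s, depth_mm=r.peak
        )
        for r in raw
    ]
    return _assign_rates(events)


def detect_ventilations(
    stream: SensorStream, cfg: DetectorConfig | None = None
) -> list[VentilationEvent]:
    """Detect rescue breaths on the volume channel (peak volume between edges)."""
    if cfg is None:
        cfg = DetectorConfig()
    det = StreamingEdgeDetector(cfg.on_threshold_ml, cfg.off_threshold_ml)
    raw = det.process(stream.t, stream.volume_ml)
    raw += det.finish()
    return [
        VentilationEvent(
            t_start_s=r.t_start_s, t_peak_s=r.t_peak_s, t_end_s=r.t_end_s, volume_ml=r.peak
        )
        for r in raw
    ]


def filter_misdetections(
    events: Sequence[CompressionEvent] | Sequence[VentilationEvent],
    cfg: DetectorConfig | None = None,
) -> list:
    """Drop implausible events; keep order; output is a subset of input.

    Removes events whose peak is below the misdetection floor
    (``min_depth_mm`` for compressions, ``min_volume_ml`` for ventilations),
    whose duration falls outside ``[min_duration_s, max_duration_s]``, or
    whose start lies within ``min_event_gap_s`` of the previously kept
    event's start (keep-first debounce).  Instantaneous compression rates are
    recomputed over the surviving events, so the operation is idempotent.
    """
    if cfg is None:
        cfg = DetectorConfig()
    kept: list = []
    last_start: float | None = None
    for ev in events:
        peak = ev.depth_mm if isinstance(ev, CompressionEvent) else ev.volume_ml
        floor = cfg.min_depth_mm if isinstance(ev, CompressionEvent) else cfg.min_volume_ml
        duration = ev.t_end_s - ev.t_start_s
        if peak < floor:
            continue
        if not (cfg.min_duration_s <= duration <= cfg.max_duration_s):
            continue
        if last_start is not None and (ev.t_start_s - last_start) < cfg.min_event_gap_s:
            continue
        kept.append(ev)
        last_start = ev.t_start_s
    if kept and isinstance(kept[0], CompressionEvent):
        kept = _assign_rates(kept)
    return kept


def augment_events(
    events: Sequence[CompressionEvent] | Sequence[VentilationEvent],
    stream: SensorStream,
    cfg: DetectorConfig | None = None,
) -> list:
    """Attach windowed channel averages to each event.

    Each event gains the arithmetic mean of both channels over
    ``[t_peak - w, t_peak + w]`` (``w = cfg.augment_window_s``), truncated at
    the stream boundaries.  An event whose window contains no samples is left
    unaugmented and a warning is logged.
    """
    if cfg is None:
        cfg = DetectorConfig()
    w = cfg.augment_window_s
    out: list = []
    for ev in events:
        lo = int(np.searchsorted(stream.t, ev.t_peak_s - w, side="left"))
        hi = int(np.searchsorted(stream.t, ev.t_peak_s + w, side="right"))
        if hi <= lo:
            logger.warning("event at t=%.3f s: empty averaging window, left unaugmented", ev.t_peak_s)
            out.append(ev)
            continue
        aug = {
            "displacement_mm": float(np.mean(stream.displacement_mm[lo:hi])),
            "volume_ml": float(np.mean(stream.volume_ml[lo:hi])),
        }
        out.append(replace(ev, augmented=aug))
    return out


# ---------------------------------------------------------------------------
# Event JSON I/O (times in seconds, depths in mm, volumes in mL)


def write_events_json(
    compressions: Sequence[CompressionEvent],
    ventilations: Sequence[VentilationEvent],
    path: str | Path,
) -> None:
    doc = {
        "compressions": [e.to_dict() for e in compressions],
        "ventilations": [e.to_dict() for e in ventilations],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_events_json(path: str | Path) -> tuple[list[CompressionEvent], list[VentilationEvent]]:
    doc = json.loads(Path(path).read_text())
    comps = [CompressionEvent.from_dict(d) for d in doc.get("compressions", [])]
    vents = [VentilationEvent.from_dict(d) for d in doc.get("ventilations", [])]
    return comps, vents
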