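import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from blskit.detect import CompressionEvent, VentilationEvent
from blskit.evaluate import ManualMark, SessionRecord, marks_from_script
from blskit.pipeline import record_from_stream
from blskit.protocol import VISUAL, default_table
from blskit.simulate import SimulatorConfig, render_stream, script_session

settings.register_profile(
    "fixed",
    max_examples=100,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.filter_too_much],
)
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def perfect_pipeline(table):
    """Noise-free textbook session, rendered and detected once per run."""
    script = script_session(table)
    stream, truth = render_stream(script, SimulatorConfig(seed=0))
    record = record_from_stream(stream, script, table)
    return {"script": script, "stream": stream, "truth": truth, "record": record}


def build_session_events(
    block_specs,
    vent_specs,
    final_spec=None,
    first_block_start=70.0,
    cycle_spacing=30.0,
    final_start=258.0,
):
    """Construct compression/ventilation events directly (no waveform rendering).

    ``block_specs``: per CPR block, None (absent) or (n, rate_cpm, depth_mm).
    ``vent_specs``: per breath pair, None or (n, volume_ml).
    Returns (compressions, ventilations) with instantaneous rates assigned
    within blocks, shaped like the detector's filtered output.
    """
    comps, vents = [], []
    for i, spec in enumerate(block_specs):
        if spec is None:
            continue
        n, rate, depth = spec
        start = first_block_start + i * cycle_spacing
        _append_block(comps, start, n, rate, depth)
        if i < len(vent_specs) and vent_specs[i] is not None:
            nv, vol = vent_specs[i]
            vstart = start + n * 60.0 / rate + 1.5
            for k in range(nv):
                t0 = vstart + 2.0 * k
                vents.append(
                    VentilationEvent(t_start_s=t0, t_peak_s=t0 + 0.6, t_end_s=t0 + 1.1, volume_ml=vol)
                )
    if final_spec is not None:
        n, rate, depth = final_spec
        _append_block(comps, final_start, n, rate, depth)
    return comps, vents


def _append_block(comps, start, n, rate, depth):
    period = 60.0 / rate
    prev_peak = None
    for k in range(n):
        peak = start + (k + 0.5) * period
        comps.append(
            CompressionEvent(
                t_start_s=start + k * period,
                t_peak_s=peak,
                t_end_s=start + (k + 1) * period,
                depth_mm=depth,
                inst_rate_cpm=None if prev_peak is None else 60.0 / (peak - prev_peak),
            )
        )
        prev_peak = peak


def perfect_marks(table):
    return [
        ManualMark(step_id=s.step_id, t_s=s.expected_time_s, performed=True)
        for s in table
        if s.evidence == VISUAL
    ]


def make_synthetic_record(
    table,
    block=(30, 110.0, 55.0),
    vent=(2, 500.0),
    final=(30, 110.0, 55.0),
    learner_id="synthetic",
):
    """A fully compliant Full Training record built from synthetic events."""
    comps, vents = build_session_events([block] * 5, [vent] * 5, final_spec=final)
    return SessionRecord(
        learner_id=learner_id,
        compressions=comps,
        ventilations=vents,
        marks=perfect_marks(table),
    )
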