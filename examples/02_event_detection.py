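"""Extract compression and ventilation events from noisy telemetry.

Simulates a compression train plus rescue breaths with sensor noise and
spurious sub-threshold artifact bumps, then runs the hysteresis edge
detector and the misdetection filter, and compares against ground truth.
"""

from blskit import DetectorConfig, detect_compressions, detect_ventilations, filter_misdetections
from blskit.simulate import ScriptedAction, SimulatorConfig, render_stream

script = [
    ScriptedAction("cpr", 1.0, params={"n_compressions": 30, "rate_cpm": 112.0, "depth_mm": 53.0}),
    ScriptedAction("breaths", 19.0, params={"n_ventilations": 2, "volume_ml": 480.0}),
]
cfg = SimulatorConfig(noise_sd_mm=2.0, noise_sd_ml=5.0, artifact_rate_per_min=6.0, seed=42)
stream, truth = render_stream(script, cfg)

det = DetectorConfig()
raw = detect_compressions(stream, det)
comps = filter_misdetections(raw, det)
vents = filter_misdetections(detect_ventilations(stream, det), det)

print(f"true compressions: {len(truth.compressions)}, artifacts injected: {len(truth.artifacts)}")
print(f"raw detections: {len(raw)}  -> after misdetection filter: {len(comps)}")
print(f"ventilations detected: {len(vents)} / {len(truth.ventilations)}")

rates = [e.inst_rate_cpm for e in comps if e.inst_rate_cpm is not None and e.inst_rate_cpm > 30]
depths = [e.depth_mm for e in comps]
print(f"mean depth {sum(depths)/len(depths):.1f} mm (scripted 53.0)")
print(f"mean within-block rate {sum(rates)/len(rates):.1f} /min (scripted 112.0)")
# The artifact bumps are 16-19 mm, below the filter's 20 mm depth floor, so
# they are removed — except when the 2 mm sensor noise happens to push a
# borderline bump's detected peak over the floor: threshold filtering is
# only as sharp as the noise allows.  Noise-free streams are recovered
# event-for-event.
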