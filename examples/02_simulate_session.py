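"""Generate a synthetic seven-block rivalry session with ground truth.

Writes pupil traces (1000 Hz, with blinks and artifacts) and button-report
timelines for the full session design - static bookends, phase-shifted
luminance-modulation blocks, the in-phase control, attention-instruction
blocks - plus a manifest holding the lag-free ground-truth percept
timeline of every block.
"""

import tempfile
from pathlib import Path

from pupiltag import RunConfig, SimulationParams, StimulusSchedule, make_fixture_session

cfg = RunConfig(seed=7)
cfg.schedule = StimulusSchedule(block_duration_s=60.0)  # short demo blocks
cfg.simulation = SimulationParams(seed=7)

outdir = Path(tempfile.mkdtemp()) / "session"
manifest = make_fixture_session(cfg, outdir)

print(f"wrote {len(manifest['blocks'])} blocks to {outdir}\n")
for blk in manifest["blocks"]:
    n_truth = len(blk["truth_intervals"])
    n_blinks = len(blk["artifact_gaps"])
    print(f"{blk['name']:24s} phase diff {blk['phase_diff_deg']:5.1f} deg, "
          f"{blk['eye_assignment']:10s} {n_truth:3d} percept intervals, "
          f"{n_blinks:2d} blinks")

print()
print("Each *_trace.tsv holds the raw pupil samples (gaps empty, blink")
print("flag set); *_events.tsv holds the reported percept intervals,")
print("which lag the manifest's ground truth by the 400 ms button latency.")
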