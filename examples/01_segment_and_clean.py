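"""Segment a noisy insole recording into unit steps.

Simulates one walking recording with swing-phase sensor artifacts,
cleans them, and checks the recovered step boundaries against the
generator's ground truth.
"""

import numpy as np

import insolegait as ig
from insolegait.preprocess import detect_phase_boundaries, reduce_swing_noise

config = ig.SimulatorConfig()  # default artifact probability 0.05
recording, truth = ig.simulate_recording(config, ig.GaitType.WALKING, n_steps=12, seed=7)

annotation = detect_phase_boundaries(recording.pressure)
_, corrections = reduce_swing_noise(recording.pressure, annotation)
steps = ig.segment_unit_steps(recording)

print(f"recording: {recording.n_frames} frames, label = {recording.label.label}")
print(f"swing artifacts cleaned: {corrections}")
print(f"unit steps recovered: {len(steps)} (simulated: {len(truth.step_intervals)})")
exact = [(s.start, s.end) for s in steps] == truth.step_intervals
print(f"boundaries match ground truth exactly: {exact}")
lengths = [s.L for s in steps]
print(f"step lengths (frames): min {min(lengths)}, mean {np.mean(lengths):.1f}, max {max(lengths)}")
# Each step runs from a left-foot swing start (all 8 pressure sensors zero)
# to the end of the following stance; exact recovery despite the injected
# artifacts shows the sum-1 cleaning rule repairing split swings.
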