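"""Turn segmented steps into fixed-size classifier samples.

Normalizes steps of varying duration to t = 63 frames, flattens one step
to the standard vector lengths, and stacks k = 2 consecutive steps into
classifier inputs.
"""

import insolegait as ig
from insolegait.preprocess import flatten_step

config = ig.SimulatorConfig()
recording, _ = ig.simulate_recording(config, ig.GaitType.RUNNING, n_steps=10, seed=3)

steps = ig.segment_unit_steps(recording)
normalized = [ig.normalize_step(s, t=63) for s in steps]
print(f"raw step lengths: {[s.L for s in steps]}")
print(f"after normalization: every step is {normalized[0].pressure.shape[0]} frames")

flat = flatten_step(normalized[0])
print(
    "flattened vector lengths: pressure "
    f"{len(flat.pressure_vec)}, accel {len(flat.accel_vec)}, gyro {len(flat.gyro_vec)}"
)

samples = ig.assemble_samples(normalized, k=2)
shape = samples[0].arrays["pressure"].shape
print(f"k=2 assembly: {len(samples)} samples, pressure array {shape[0]}x{shape[1]}")
# 63*16 = 1008 and 63*6 = 378 are the fixed per-step vector lengths; a
# k-step sample stacks k normalized steps into a (63*k) x W network input.
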