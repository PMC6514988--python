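"""Synthetic insole-recording generator with ground-truth step boundaries.

The generator emulates the structure the preprocessing and classification
stages assume, without claiming biomechanical fidelity:

* **Left-foot pressure** alternates swing (all 8 channels 0) and stance.
  During stance the 8 sensors activate heel-to-toe: heel sensors switch on
  at heel strike, forefoot sensors later, toe sensors last, each ramping
  1 -> 2 -> 1 within its active window.  At least two sensors are active at
  the first stance frame, so the heel-strike detection rule always fires.
* **Right-foot pressure** is the left pattern shifted by half a step, the
  out-of-phase alternation of normal gait.
* **Accel/gyro channels** are sums of harmonics locked to the step phase,
  with per-class amplitude and harmonic-weight signatures plus white
  Gaussian sensor noise.  Classes therefore differ in waveform shape and
  amplitude the way gaits differ in impact and limb dynamics.
* **Swing artifacts**: with probability ``p`` per eligible frame a single
  pressure channel reads 1 during swing, the sensor fault the sum-1
  cleaning rule removes.  Injection skips the first frame of each swing:
  an artifact on the zero-crossing itself shifts the measurable swing
  onset and no post-hoc rule could recover the true boundary.

Each recording ends with a short all-zero tail so the final stance
demonstrably ends, making ground-truth step intervals exactly recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .records import GaitType, SensorRecording, validate_recording
from .preprocess import PhaseAnnotation

__all__ = [
    "ClassParams",
    "SimulatorConfig",
    "GroundTruth",
    "simulate_recording",
    "inject_swing_noise",
    "simulate_dataset",
    "truth_annotation",
]


@dataclass
class ClassParams:
    """Per-gait-type generator parameters.

    Durations are in frames at 100 Hz; amplitudes are in arbitrary sensor
    units (the classifier standardizes per feature, so only relative
    structure matters).
    """

    step_frames_mean: float
    step_frames_sd: float
    stance_fraction: float
    accel_amp: float
    gyro_amp: float
    accel_harmonics: tuple = (1.0, 0.4, 0.15)
    gyro_harmonics: tuple = (1.0, 0.3, 0.1)


def _default_class_params() -> dict:
    # step durations ~ gait norms (walking ~1 s/step, running ~0.6 s);
    # running has a short stance (aerial phase), climbing a long one.
    return {
        GaitType.WALKING: ClassParams(100, 8, 0.62, 1.0, 1.0, (1.0, 0.40, 0.15), (1.0, 0.30, 0.10)),
        GaitType.FAST_WALKING: ClassParams(80, 7, 0.58, 1.4, 1.3, (1.0, 0.55, 0.20), (1.0, 0.45, 0.15)),
        GaitType.RUNNING: ClassParams(60, 6, 0.40, 2.2, 1.8, (1.0, 0.75, 0.35), (1.0, 0.60, 0.30)),
        GaitType.STAIR_CLIMBING: ClassParams(110, 9, 0.66, 0.8, 1.2, (1.0, 0.25, 0.40), (0.8, 0.60, 0.20)),
        GaitType.STAIR_DESCENDING: ClassParams(90, 8, 0.60, 1.2, 1.5, (0.7, 0.60, 0.25), (1.0, 0.25, 0.40)),
        GaitType.HILL_CLIMBING: ClassParams(105, 8, 0.64, 0.9, 0.8, (1.0, 0.15, 0.05), (1.2, 0.20, 0.05)),
        GaitType.HILL_DESCENDING: ClassParams(95, 8, 0.61, 1.1, 1.1, (0.6, 0.30, 0.50), (0.9, 0.50, 0.35)),
    }


#: per-sensor (onset, offset, peak) fractions within stance, heel to toe
DEFAULT_PRESSURE_TEMPLATE = (
    (0.00, 0.60, 2),  # heel medial
    (0.00, 0.55, 2),  # heel lateral
    (0.20, 0.75, 1),  # midfoot medial
    (0.20, 0.70, 1),  # midfoot lateral
    (0.30, 0.90, 2),  # forefoot medial
    (0.30, 0.85, 2),  # forefoot lateral
    (0.50, 1.00, 2),  # hallux
    (0.50, 1.00, 1),  # lesser toes
)


@dataclass
class SimulatorConfig:
    """Full description of the synthetic gait-data generating process."""

    class_params: dict = field(default_factory=_default_class_params)
    pressure_template: tuple = DEFAULT_PRESSURE_TEMPLATE
    sensor_noise_sd: float = 0.15  # accel/gyro white noise, sensor units
    artifact_prob: float = 0.05  # per swing-interior frame
    artifact_channel: int = 2  # "third sensor" of the left foot
    tail_frames: int = 5  # zero tail closing the final stance
    sample_rate_hz: float = 100.0

    def validate(self) -> None:
        for label, cp in self.class_params.items():
            if cp.step_frames_mean < 4:
                raise ValueError(f"{label}: step duration must be >= 4 frames")
            if not 0.0 < cp.stance_fraction < 1.0:
                raise ValueError(f"{label}: stance fraction must be in (0, 1)")
        if not 0.0 <= self.artifact_prob <= 1.0:
            raise ValueError("artifact probability must be in [0, 1]")
        if not 0 <= self.artifact_channel < 8:
            raise ValueError("artifact channel must index a left-foot sensor (0-7)")

    @classmethod
    def uninformative(cls) -> "SimulatorConfig":
        """All classes share one parameter set: labels carry no signal."""
        base = ClassParams(90, 8, 0.60, 1.0, 1.0)
        return cls(class_params={g: replace(base) for g in GaitType})


@dataclass
class GroundTruth:
    """Exact step boundaries of a simulated recording."""

    swing_starts: list[int]
    stance_starts: list[int]
    step_intervals: list[tuple]  # [(start, end)) per step
    labels: list[GaitType]


def truth_annotation(truth: GroundTruth) -> PhaseAnnotation:
    """View ground truth as a phase annotation (for the cleaning rule)."""
    return PhaseAnnotation(
        swing_starts=list(truth.swing_starts),
        stance_starts=list(truth.stance_starts),
    )


def _stance_profile(stance_len: int, template) -> np.ndarray:
    """(stance_len, 8) heel-to-toe activation pattern, levels in {0,1,2}."""
    frac = (np.arange(stance_len) + 0.5) / stance_len
    out = np.zeros((stance_len, 8), dtype=np.int64)
    for ch, (onset, offset, peak) in enumerate(template):
        active = (frac >= onset) & (frac < offset)
        out[active, ch] = 1
        if peak >= 2:
            width = offset - onset
            core = (frac >= onset + 0.2 * width) & (frac < offset - 0.2 * width)
            out[core, ch] = 2
    return out


def simulate_recording(
    config: SimulatorConfig,
    label: GaitType,
    n_steps: int,
    seed: int,
) -> tuple[SensorRecording, GroundTruth]:
    """Generate one labeled recording of ``n_steps`` left-foot steps.

    Deterministic given ``(config, label, n_steps, seed)``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    config.validate()
    label = GaitType(label)
    cp = config.class_params[label]
    rng = np.random.default_rng(seed)

    durations = np.clip(
        np.rint(rng.normal(cp.step_frames_mean, cp.step_frames_sd, n_steps)), 4, None
    ).astype(int)
    swing_lens = np.clip(np.rint(durations * (1.0 - cp.stance_fraction)), 2, durations - 2).astype(int)
    stance_lens = durations - swing_lens

    swing_starts, stance_starts, intervals = [], [], []
    left_blocks = []
    pos = 0
    for sw, st in zip(swing_lens, stance_lens):
        swing_starts.append(pos)
        stance_starts.append(pos + sw)
        intervals.append((pos, pos + sw + st))
        left_blocks.append(np.zeros((sw, 8), dtype=np.int64))
        left_blocks.append(_stance_profile(st, config.pressure_template))
        pos += sw + st
    left_blocks.append(np.zeros((config.tail_frames, 8), dtype=np.int64))
    left = np.vstack(left_blocks)
    n_frames = left.shape[0]

    # right foot: same pattern shifted by half the mean step (out of phase)
    right = np.roll(left, int(round(durations.mean() / 2)), axis=0)

    # step-locked phase ramps 0 -> 2*pi over each step, frozen in the tail
    phase = np.zeros(n_frames)
    for (a, b) in intervals:
        phase[a:b] = np.linspace(0.0, 2 * np.pi, b - a, endpoint=False)
    phase[intervals[-1][1] :] = 0.0

    def modality(amp, weights, chan_offsets):
        sig = np.zeros((n_frames, 6))
        for c, off in enumerate(chan_offsets):
            wave = sum(
                w * np.sin((h + 1) * phase + off) for h, w in enumerate(weights)
            )
            sig[:, c] = amp * wave
        sig += rng.normal(0.0, config.sensor_noise_sd, sig.shape)
        return sig

    # left xyz then right xyz; right foot is half a cycle out of phase
    offsets = [0.0, np.pi / 3, 2 * np.pi / 3, np.pi, np.pi + np.pi / 3, np.pi + 2 * np.pi / 3]
    accel = modality(cp.accel_amp, cp.accel_harmonics, offsets)
    gyro = modality(cp.gyro_amp, cp.gyro_harmonics, offsets)

    recording = SensorRecording(
        pressure=np.hstack([left, right]),
        accel=accel,
        gyro=gyro,
        label=label,
        subject_id="sim",
        sample_rate_hz=config.sample_rate_hz,
    )
    truth = GroundTruth(
        swing_starts=swing_starts,
        stance_starts=stance_starts,
        step_intervals=intervals,
        labels=[label] * n_steps,
    )
    if config.artifact_prob > 0:
        recording, _ = inject_swing_noise(
            recording,
            truth,
            p=config.artifact_prob,
            channel=config.artifact_channel,
            seed=int(rng.integers(2**31)),
        )
    return recording, truth


def inject_swing_noise(
    recording: SensorRecording,
    truth: GroundTruth,
    p: float,
    channel: int,
    seed: int,
) -> tuple[SensorRecording, int]:
    """Set one left-foot channel to 1 on random swing-interior frames.

    Each frame strictly inside a ``(swing_start, stance_start)`` interval is
    hit independently with probability ``p``.  Stance frames and the swing
    onset itself are never modified (see module docstring).  Returns the
    modified recording (a copy) and the number of injected frames.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pressure = recording.pressure.copy()
    injected = 0
    for ss, st in zip(truth.swing_starts, truth.stance_starts):
        for i in range(ss + 1, st):
            if rng.random() < p:
                pressure[i, channel] = 1
                injected += 1
    out = SensorRecording(
        pressure=pressure,
        accel=recording.accel.copy(),
        gyro=recording.gyro.copy(),
        label=recording.label,
        subject_id=recording.subject_id,
        sample_rate_hz=recording.sample_rate_hz,
    )
    return out, injected


def simulate_dataset(
    config: SimulatorConfig,
    n_per_class: int,
    steps_per_recording: int,
    seed: int,
) -> tuple[list[SensorRecording], list[GroundTruth]]:
    """Generate a balanced dataset: ``n_per_class`` recordings per gait type.

    Per-recording seeds are derived deterministically from the master seed,
    so the full dataset is reproducible from one integer.
    """
    if n_per_class < 1 or steps_per_recording < 1:
        raise ValueError("counts must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(7 * n_per_class) % (2**31)
    recordings, truths = [], []
    i = 0
    for label in GaitType:
        for r in range(n_per_class):
            rec, truth = simulate_recording(
                config, label, steps_per_recording, seed=int(seeds[i])
            )
            rec.subject_id = f"sim-{label.label}-{r:03d}"
            recordings.append(rec)
            truths.append(truth)
            i += 1
    return recordings, truths


def simulate_samples(
    config: SimulatorConfig,
    n_per_class: int,
    steps_per_recording: int,
    k: int = 1,
    t: int = 63,
    seed: int = 0,
):
    """Simulate a dataset and run it through the preprocessing pipeline.

    Convenience wrapper: generate recordings, segment unit steps, normalize
    to ``t`` frames, and assemble ``k``-step samples.  Returns the flat list
    of :class:`~insolegait.preprocess.GaitSample` (unstandardized; the
    evaluation protocols standardize inside each split).
    """
    from .preprocess import assemble_samples, normalize_step, segment_unit_steps

    recordings, _ = simulate_dataset(config, n_per_class, steps_per_recording, seed)
    samples = []
    for rec in recordings:
        steps = [normalize_step(s, t) for s in segment_unit_steps(rec)]
        samples.extend(assemble_samples(steps, k, recording_id=rec.subject_id))
    return samples
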