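"""Gait-cycle preprocessing: phase detection, denoising, segmentation,
length normalization and sample assembly.

The pipeline turns a continuous recording into fixed-size classifier inputs:

1. **Phase detection** — scan the summed left-foot pressure channels.  A
   *swing start* is the first frame of each maximal zero-sum run (the foot
   has left the ground); the following *stance start* is the first frame at
   which two or more left-foot sensors are non-zero (heel strike).
2. **Swing-phase noise reduction** — between a swing start and the next
   stance start the left-foot sum must be 0; a frame whose sum is exactly 1
   is a sensor artifact and the offending channel is zeroed.  A single
   spurious reading would otherwise split one swing into two and double-count
   a step boundary.
3. **Unit-step segmentation** — one step spans a left-foot swing start to
   the end of the following stance phase, which (phases being contiguous) is
   the next swing start.  A trailing step truncated mid-stance is dropped.
4. **Length normalization** — each step is resampled to ``t`` frames per
   channel (``t = 63`` by default, the shortest step in the reference data),
   removing walking-speed variation.  Pressure is re-quantized to {0, 1, 2}.
5. **Assembly** — ``k`` consecutive normalized steps are stacked into one
   ``(t*k, W)`` sample per modality; samples are standardized per feature
   with statistics fitted on the training portion only.

Frame indices are 0-based; all intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .records import (
    LEFT_PRESSURE,
    MODALITIES,
    GaitType,
    SensorRecording,
)

__all__ = [
    "PhaseAnnotation",
    "UnitStep",
    "NormalizedStep",
    "FlattenedStep",
    "GaitSample",
    "Standardizer",
    "detect_phase_boundaries",
    "reduce_swing_noise",
    "segment_unit_steps",
    "normalize_step",
    "flatten_step",
    "unflatten_step",
    "assemble_samples",
    "stack_samples",
    "standardize",
    "DEFAULT_T",
]

#: default normalized step length in frames
DEFAULT_T = 63


@dataclass
class PhaseAnnotation:
    """Swing-start and stance-start frame indices for the left foot.

    On artifact-free pressure the two lists strictly alternate starting
    with a swing start; on noisy input consecutive swing starts may share
    one stance start (the double-swing error the cleaning rule repairs).
    """

    swing_starts: list[int]
    stance_starts: list[int]
    foot: str = "left"

    def is_alternating(self) -> bool:
        events = sorted(
            [(i, 0) for i in self.swing_starts] + [(i, 1) for i in self.stance_starts]
        )
        return all(kind == j % 2 for j, (_, kind) in enumerate(events))


@dataclass
class UnitStep:
    """One segmented step: swing start through the end of the stance phase."""

    pressure: np.ndarray  # (L, 16)
    accel: np.ndarray  # (L, 6)
    gyro: np.ndarray  # (L, 6)
    label: GaitType
    start: int = 0  # frame interval [start, end) in the source recording
    end: int = 0

    @property
    def L(self) -> int:
        return self.pressure.shape[0]


@dataclass
class NormalizedStep:
    """A unit step resampled to exactly ``t`` frames per channel."""

    pressure: np.ndarray  # (t, 16), values in {0, 1, 2}
    accel: np.ndarray  # (t, 6)
    gyro: np.ndarray  # (t, 6)
    label: GaitType
    t: int = DEFAULT_T


@dataclass
class FlattenedStep:
    """Row-major (time-major) vectorization of a normalized step.

    For t=63 the lengths are 1008 (pressure), 378 (accel) and 378 (gyro).
    """

    pressure_vec: np.ndarray
    accel_vec: np.ndarray
    gyro_vec: np.ndarray


@dataclass
class GaitSample:
    """``k`` consecutive normalized steps stacked into (t*k, W) per modality."""

    arrays: dict  # modality name -> (t*k, W) array
    label: GaitType
    k: int
    t: int
    recording_id: str = ""


def _left_sums(pressure: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    left = np.asarray(pressure)[:, LEFT_PRESSURE]
    return left.sum(axis=1), (left != 0).sum(axis=1)


def detect_phase_boundaries(pressure: np.ndarray) -> PhaseAnnotation:
    """Scan left-foot pressure for swing and stance starts.

    A swing start is frame 0 if the sum is zero there, or any frame where the
    sum reaches 0 after being non-zero.  The paired stance start is the first
    subsequent frame with >= 2 non-zero left-foot channels.  A trailing swing
    with no stance start is kept in the annotation (segmentation drops it).
    """
    pressure = np.asarray(pressure)
    if pressure.ndim != 2 or pressure.shape[0] < 1:
        raise ValueError("pressure must be a non-empty (frames, channels) array")
    sums, n_active = _left_sums(pressure)
    swing_starts: list[int] = []
    stance_starts: list[int] = []
    awaiting_stance = False
    for i in range(len(sums)):
        if sums[i] == 0 and (i == 0 or sums[i - 1] != 0):
            swing_starts.append(i)
            awaiting_stance = True
        elif awaiting_stance and n_active[i] >= 2:
            stance_starts.append(i)
            awaiting_stance = False
    return PhaseAnnotation(swing_starts=swing_starts, stance_starts=stance_starts)


def reduce_swing_noise(
    pressure: np.ndarray, annotation: PhaseAnnotation
) -> tuple[np.ndarray, int]:
    """Zero out single-sensor artifacts inside swing intervals.

    For every frame in a ``[swing_start, stance_start)`` interval whose
    left-foot sum is exactly 1, the one offending channel is set to 0.  A sum
    of 2 is left untouched: two sensors at 1 would instead have triggered a
    stance start, and a single sensor at level 2 is outside the stated rule.

    Returns the cleaned array and the number of frames altered.
    """
    pressure = np.asarray(pressure)
    cleaned = pressure.copy()
    sums, _ = _left_sums(pressure)
    stance = np.asarray(annotation.stance_starts)
    fix = np.zeros(len(sums), dtype=bool)
    for ss in annotation.swing_starts:
        j = np.searchsorted(stance, ss)
        if j >= len(stance):
            continue  # trailing swing with no heel strike: leave untouched
        seg = slice(ss, int(stance[j]))
        fix[seg] |= sums[seg] == 1
    corrections = int(fix.sum())
    if corrections:
        left = cleaned[:, LEFT_PRESSURE]
        left[fix] = 0
        cleaned[:, LEFT_PRESSURE] = left
    return cleaned, corrections


def segment_unit_steps(recording: SensorRecording) -> list[UnitStep]:
    """Split a recording into unit steps on cleaned left-foot pressure.

    Boundaries are detected, the swing-noise rule applied, and boundaries
    re-detected on the cleaned pressure.  Each step spans one swing start to
    the next (the frame at which the left-foot sum leaves the stance phase);
    a recording that truncates mid-stance loses its final step.  All three
    modality arrays are sliced with identical intervals.
    """
    annotation = detect_phase_boundaries(recording.pressure)
    cleaned, _ = reduce_swing_noise(recording.pressure, annotation)
    annotation = detect_phase_boundaries(cleaned)
    swings = annotation.swing_starts
    stances = np.asarray(annotation.stance_starts)
    steps: list[UnitStep] = []
    for i in range(len(swings) - 1):
        start, end = swings[i], swings[i + 1]
        # require a heel strike inside the interval, else no step occurred
        j = np.searchsorted(stances, start)
        if j >= len(stances) or stances[j] >= end:
            continue
        steps.append(
            UnitStep(
                pressure=cleaned[start:end],
                accel=recording.accel[start:end],
                gyro=recording.gyro[start:end],
                label=recording.label,
                start=int(start),
                end=int(end),
            )
        )
    return steps


def _resample_channel(values: np.ndarray, t: int) -> np.ndarray:
    L = len(values)
    src = np.linspace(0.0, 1.0, L)
    dst = np.linspace(0.0, 1.0, t)
    return np.interp(dst, src, values)


def normalize_step(step: UnitStep, t: int = DEFAULT_T) -> NormalizedStep:
    """Resample every channel of a step from L frames to ``t`` frames.

    Linear interpolation on a uniform grid; pressure is rounded to the
    nearest level and clipped back into {0, 1, 2} so the value domain is
    preserved.  Degenerate steps (L < 2) cannot be resampled.
    """
    if t < 1:
        raise ValueError(f"t must be >= 1, got {t}")
    if step.L < 2:
        raise ValueError(f"degenerate step of length {step.L}; need L >= 2")
    pressure = np.stack(
        [_resample_channel(step.pressure[:, c].astype(float), t) for c in range(step.pressure.shape[1])],
        axis=1,
    )
    pressure = np.clip(np.rint(pressure), 0, 2).astype(step.pressure.dtype)
    accel = np.stack(
        [_resample_channel(step.accel[:, c], t) for c in range(step.accel.shape[1])], axis=1
    )
    gyro = np.stack(
        [_resample_channel(step.gyro[:, c], t) for c in range(step.gyro.shape[1])], axis=1
    )
    return NormalizedStep(pressure=pressure, accel=accel, gyro=gyro, label=step.label, t=t)


def flatten_step(step: NormalizedStep) -> FlattenedStep:
    """Unroll each (t, W) array row-major into a length t*W vector."""
    return FlattenedStep(
        pressure_vec=step.pressure.reshape(-1),
        accel_vec=step.accel.reshape(-1),
        gyro_vec=step.gyro.reshape(-1),
    )


def unflatten_step(flat: FlattenedStep, t: int, label: GaitType = GaitType.WALKING) -> NormalizedStep:
    """Invert :func:`flatten_step` given the normalization length ``t``."""
    return NormalizedStep(
        pressure=flat.pressure_vec.reshape(t, -1),
        accel=flat.accel_vec.reshape(t, -1),
        gyro=flat.gyro_vec.reshape(t, -1),
        label=label,
        t=t,
    )


def assemble_samples(
    steps: list[NormalizedStep], k: int, recording_id: str = ""
) -> list[GaitSample]:
    """Stack consecutive non-overlapping windows of ``k`` steps into samples.

    Steps must come from one recording in chronological order and share
    ``t``; a leftover tail of fewer than ``k`` steps is discarded.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    samples: list[GaitSample] = []
    for i in range(0, len(steps) - k + 1, k):
        window = steps[i : i + k]
        ts = {s.t for s in window}
        if len(ts) != 1:
            raise ValueError(f"steps in one sample must share t, got {sorted(ts)}")
        labels = {s.label for s in window}
        if len(labels) != 1:
            raise ValueError("steps in one sample must share a label")
        samples.append(
            GaitSample(
                arrays={
                    "pressure": np.vstack([s.pressure for s in window]).astype(float),
                    "accel": np.vstack([s.accel for s in window]),
                    "gyro": np.vstack([s.gyro for s in window]),
                },
                label=window[0].label,
                k=k,
                t=window[0].t,
                recording_id=recording_id,
            )
        )
    return samples


def stack_samples(samples: list[GaitSample]) -> tuple[dict, np.ndarray]:
    """Stack a sample list into ``{modality: (N, t*k, W)}`` plus labels."""
    if not samples:
        raise ValueError("empty sample list")
    X = {m: np.stack([s.arrays[m] for s in samples]) for m in MODALITIES}
    y = np.array([int(s.label) for s in samples], dtype=np.int64)
    return X, y


@dataclass
class Standardizer:
    """Per-feature affine transform (zero mean, unit variance) fitted on train.

    Each (time, channel) cell of each modality is one feature.  Zero-variance
    features map to 0 so constant channels carry no signal.
    """

    mean: dict = field(default_factory=dict)
    var: dict = field(default_factory=dict)

    def fit(self, X: dict) -> "Standardizer":
        for m, arr in X.items():
            self.mean[m] = arr.mean(axis=0)
            self.var[m] = arr.var(axis=0)
        return self

    def transform(self, X: dict) -> dict:
        out = {}
        for m, arr in X.items():
            var = self.var[m]
            scale = np.sqrt(np.where(var == 0, 1.0, var))
            out[m] = np.where(var == 0, 0.0, (arr - self.mean[m]) / scale)
        return out


def standardize(
    train: list[GaitSample], test: list[GaitSample]
) -> tuple[list[GaitSample], list[GaitSample], Standardizer]:
    """Standardize samples per feature using training statistics only.

    The identical transform (train means and variances) is applied to the
    test samples, mirroring a deployment where test data arrive later.
    """
    if not train:
        raise ValueError("training set must be non-empty")
    Xtr, _ = stack_samples(train)
    scaler = Standardizer().fit(Xtr)
    Ztr = scaler.transform(Xtr)

    def rebuild(samples, Z):
        return [
            replace(s, arrays={m: Z[m][i] for m in MODALITIES})
            for i, s in enumerate(samples)
        ]

    out_test: list[GaitSample] = []
    if test:
        Xte, _ = stack_samples(test)
        out_test = rebuild(test, scaler.transform(Xte))
    return rebuild(train, Ztr), out_test, scaler


def write_samples(samples: list[GaitSample], path) -> None:
    """Write assembled samples to one text container file.

    Same CSV dialect as recordings: per sample a ``#``-header block
    (index, label, k, t, source recording) followed by t*k rows of
    16 + 6 + 6 columns.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for i, s in enumerate(samples):
            fh.write(f"# sample: {i}\n")
            fh.write(f"# label: {s.label.label}\n")
            fh.write(f"# k: {s.k}\n")
            fh.write(f"# t: {s.t}\n")
            fh.write(f"# recording: {s.recording_id}\n")
            block = np.hstack([s.arrays["pressure"], s.arrays["accel"], s.arrays["gyro"]])
            for row in block:
                fh.write(",".join(repr(float(v)) for v in row) + "\n")


def read_samples(path) -> list[GaitSample]:
    """Read a sample container written by :func:`write_samples`."""
    samples: list[GaitSample] = []
    header: dict[str, str] = {}
    rows: list[list[float]] = []

    def flush():
        if not header:
            return
        block = np.array(rows, dtype=float)
        samples.append(
            GaitSample(
                arrays={
                    "pressure": block[:, :16],
                    "accel": block[:, 16:22],
                    "gyro": block[:, 22:28],
                },
                label=GaitType.from_label(header["label"]),
                k=int(header["k"]),
                t=int(header["t"]),
                recording_id=header.get("recording", ""),
            )
        )

    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("# sample:"):
                flush()
                header, rows = {"sample": line.split(":", 1)[1].strip()}, []
            elif line.startswith("#"):
                key, _, value = line[1:].partition(":")
                header[key.strip()] = value.strip()
            else:
                rows.append([float(v) for v in line.split(",")])
    flush()
    return samples
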