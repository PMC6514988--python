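"""Domain types and file I/O for smart-insole gait recordings.

A recording is a synchronized set of three sensor arrays sampled at 100 Hz
from a pair of instrumented insoles:

* ``pressure`` — 16 channels (8 per foot), quantized to {0, 1, 2}: 0 means
  the foot is off the ground at that sensor, 1 and 2 encode increasing
  plantar pressure during stance;
* ``accel`` — 6 channels (x, y, z per foot), real-valued;
* ``gyro`` — 6 channels (x, y, z per foot), real-valued.

Channel convention: left-foot channels first, then right-foot channels.
Left-foot pressure occupies columns 0–7; segmentation consults only these.

The on-disk format is a single UTF-8, comma-delimited text file per
recording: ``#``-prefixed ``key: value`` header lines (``subject_id``,
``label``, ``sample_rate_hz``) followed by one row per frame with 28 data
columns (16 pressure, 6 accel, 6 gyro, in that order).  A single flat file
keeps the three arrays synchronized by construction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GaitType",
    "SensorRecording",
    "ParseError",
    "RecordingValidationError",
    "read_recording",
    "write_recording",
    "validate_recording",
    "N_PRESSURE",
    "N_ACCEL",
    "N_GYRO",
    "LEFT_PRESSURE",
    "RIGHT_PRESSURE",
    "MODALITIES",
    "MODALITY_WIDTHS",
]

N_PRESSURE = 16
N_ACCEL = 6
N_GYRO = 6
N_COLUMNS = N_PRESSURE + N_ACCEL + N_GYRO

#: column slices into the pressure array
LEFT_PRESSURE = slice(0, 8)
RIGHT_PRESSURE = slice(8, 16)

MODALITIES = ("pressure", "accel", "gyro")
MODALITY_WIDTHS = {"pressure": N_PRESSURE, "accel": N_ACCEL, "gyro": N_GYRO}

DEFAULT_SAMPLE_RATE_HZ = 100.0


class GaitType(enum.IntEnum):
    """The seven gait types, with a fixed integer coding 0–6."""

    WALKING = 0
    FAST_WALKING = 1
    RUNNING = 2
    STAIR_CLIMBING = 3
    STAIR_DESCENDING = 4
    HILL_CLIMBING = 5
    HILL_DESCENDING = 6

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "GaitType":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise ValueError(
                f"unknown gait type {label!r}; expected one of "
                f"{[g.label for g in cls]}"
            ) from None


class ParseError(ValueError):
    """Raised when a recording file is malformed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class RecordingValidationError(ValueError):
    """Raised when recording contents violate a domain invariant."""


@dataclass
class SensorRecording:
    """One gait session: synchronized pressure/accel/gyro arrays + label."""

    pressure: np.ndarray  # (frames, 16) integer, values in {0, 1, 2}
    accel: np.ndarray  # (frames, 6) float
    gyro: np.ndarray  # (frames, 6) float
    label: GaitType
    subject_id: str = ""
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ

    def __post_init__(self):
        self.pressure = np.asarray(self.pressure)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.label = GaitType(self.label)

    @property
    def n_frames(self) -> int:
        return self.pressure.shape[0]

    @property
    def left_pressure(self) -> np.ndarray:
        return self.pressure[:, LEFT_PRESSURE]

    def equals(self, other: "SensorRecording", rtol: float = 0.0, atol: float = 0.0) -> bool:
        """Field-for-field equality (exact by default)."""
        return (
            self.label == other.label
            and self.subject_id == other.subject_id
            and float(self.sample_rate_hz) == float(other.sample_rate_hz)
            and np.array_equal(self.pressure, other.pressure)
            and np.allclose(self.accel, other.accel, rtol=rtol, atol=atol)
            and np.allclose(self.gyro, other.gyro, rtol=rtol, atol=atol)
        )


def validate_recording(recording: SensorRecording) -> list[str]:
    """Check domain invariants; return a list of violation descriptions.

    Pure and total: never raises, an empty list means the recording conforms.
    """
    violations: list[str] = []
    p, a, g = recording.pressure, recording.accel, recording.gyro
    if p.ndim != 2 or p.shape[1] != N_PRESSURE:
        violations.append(f"pressure must be (frames, {N_PRESSURE}), got {p.shape}")
    if a.ndim != 2 or a.shape[1] != N_ACCEL:
        violations.append(f"accel must be (frames, {N_ACCEL}), got {a.shape}")
    if g.ndim != 2 or g.shape[1] != N_GYRO:
        violations.append(f"gyro must be (frames, {N_GYRO}), got {g.shape}")
    if violations:
        return violations

    if not (p.shape[0] == a.shape[0] == g.shape[0]):
        violations.append(
            "frame-count mismatch across arrays: "
            f"pressure={p.shape[0]}, accel={a.shape[0]}, gyro={g.shape[0]}"
        )
    bad = (p != 0) & (p != 1) & (p != 2)
    if bad.any():
        frame, channel = np.argwhere(bad)[0]
        violations.append(
            f"pressure value {p[frame, channel]} outside {{0,1,2}} at "
            f"frame {frame}, channel {channel}"
        )
    if not np.isfinite(a).all():
        violations.append("accel contains non-finite values")
    if not np.isfinite(g).all():
        violations.append("gyro contains non-finite values")
    if recording.sample_rate_hz <= 0:
        violations.append(f"sample_rate_hz must be positive, got {recording.sample_rate_hz}")
    return violations


def write_recording(recording: SensorRecording, path) -> None:
    """Write a recording to ``path`` in the flat CSV dialect.

    Integers round-trip losslessly; reals are written with ``repr`` precision.
    """
    violations = validate_recording(recording)
    if violations:
        raise RecordingValidationError("; ".join(violations))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# subject_id: {recording.subject_id}\n")
        fh.write(f"# label: {recording.label.label}\n")
        fh.write(f"# sample_rate_hz: {recording.sample_rate_hz!r}\n")
        for i in range(recording.n_frames):
            row = (
                [str(int(v)) for v in recording.pressure[i]]
                + [repr(float(v)) for v in recording.accel[i]]
                + [repr(float(v)) for v in recording.gyro[i]]
            )
            fh.write(",".join(row) + "\n")


def read_recording(path) -> SensorRecording:
    """Read a recording file; inverse of :func:`write_recording`.

    Raises :class:`ParseError` (naming the 1-based line number) on malformed
    rows and :class:`RecordingValidationError` on domain violations such as a
    pressure value outside {0, 1, 2}.
    """
    header: dict[str, str] = {}
    pressure_rows: list[list[int]] = []
    accel_rows: list[list[float]] = []
    gyro_rows: list[list[float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, sep, value = line[1:].partition(":")
                if sep:
                    header[key.strip()] = value.strip()
                continue
            parts = line.split(",")
            if len(parts) != N_COLUMNS:
                raise ParseError(
                    f"expected {N_COLUMNS} columns, found {len(parts)}", line=lineno
                )
            try:
                pvals = [int(v) for v in parts[:N_PRESSURE]]
                avals = [float(v) for v in parts[N_PRESSURE : N_PRESSURE + N_ACCEL]]
                gvals = [float(v) for v in parts[N_PRESSURE + N_ACCEL :]]
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from None
            for ch, v in enumerate(pvals):
                if v not in (0, 1, 2):
                    raise RecordingValidationError(
                        f"line {lineno}: pressure value {v} outside {{0,1,2}} "
                        f"(channel {ch})"
                    )
            pressure_rows.append(pvals)
            accel_rows.append(avals)
            gyro_rows.append(gvals)

    if "label" not in header:
        raise ParseError("missing 'label' header line")
    n = len(pressure_rows)
    recording = SensorRecording(
        pressure=np.array(pressure_rows, dtype=np.int64).reshape(n, N_PRESSURE),
        accel=np.array(accel_rows, dtype=float).reshape(n, N_ACCEL),
        gyro=np.array(gyro_rows, dtype=float).reshape(n, N_GYRO),
        label=GaitType.from_label(header["label"]),
        subject_id=header.get("subject_id", ""),
        sample_rate_hz=float(header.get("sample_rate_hz", DEFAULT_SAMPLE_RATE_HZ)),
    )
    violations = validate_recording(recording)
    if violations:
        raise RecordingValidationError("; ".join(violations))
    return recording
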