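"""Core data types for IMU trials, frame-level annotations, and episode segments.

A trial is a fixed-rate multichannel inertial recording from five body-worn
sensors (pelvis, both tibiae, both tali), each contributing a triaxial
accelerometer and a triaxial gyroscope.  Freezing-of-gait (FOG) annotations
live on a parallel per-sample label tier with four classes:

===  =====================================================
  0  non-FOG (normal locomotion, transitions, background)
  1  FOG (trembling, shuffling, or akinetic freezing)
  2  FOG-related (non-paroxysmal shuffling / festination)
  3  stop (volitional or imposed cessation of walking)
===  =====================================================

For model training and evaluation the tier is collapsed to a binary view in
which only class 1 is positive; FOG-related movement and stops are negatives,
but the full tier is preserved for error attribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Task",
    "Medication",
    "StopCondition",
    "TrialMetadata",
    "IMUTrial",
    "FrameLabels",
    "Segment",
    "SENSOR_SITES",
    "CHANNEL_AXES",
    "signal_columns",
    "LABEL_NONFOG",
    "LABEL_FOG",
    "LABEL_FOG_RELATED",
    "LABEL_STOP",
    "labels_to_segments",
    "segments_to_labels",
    "resample_labels",
]

LABEL_NONFOG = 0
LABEL_FOG = 1
LABEL_FOG_RELATED = 2
LABEL_STOP = 3

#: canonical sensor order; column layout is site-major, accelerometer first
SENSOR_SITES = ("pelvis", "tibia_left", "tibia_right", "talus_left", "talus_right")
CHANNEL_AXES = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")


class Task(str, Enum):
    TUG = "TUG"
    TURN360 = "TURN360"


class Medication(str, Enum):
    ON = "ON"
    OFF = "OFF"


class StopCondition(str, Enum):
    NONE = "NONE"
    SELF_GENERATED = "SELF_GENERATED"
    IMPOSED = "IMPOSED"


def signal_columns(sensors: Sequence[str] = SENSOR_SITES) -> list[str]:
    """Column names in the fixed site-major order, e.g. ``pelvis_acc_x``."""
    return [f"{site}_{axis}" for site in sensors for axis in CHANNEL_AXES]


@dataclass(frozen=True)
class TrialMetadata:
    """Condition factors of one recorded trial.

    ``stop_condition`` is :attr:`StopCondition.NONE` for "clinical" trials;
    trials with a self-generated or researcher-imposed stop form the stopping
    arm of the protocol.
    """

    subject_id: str
    trial_id: str
    task: Task
    medication: Medication
    dual_task: bool = False
    stop_condition: StopCondition = StopCondition.NONE

    def __post_init__(self) -> None:
        object.__setattr__(self, "task", Task(self.task))
        object.__setattr__(self, "medication", Medication(self.medication))
        object.__setattr__(self, "stop_condition", StopCondition(self.stop_condition))

    @property
    def is_stopping(self) -> bool:
        return self.stop_condition is not StopCondition.NONE


@dataclass
class IMUTrial:
    """One trial's multichannel inertial recording.

    ``signal`` has shape (T, 6 * n_sensors): per site acc x,y,z in m/s**2
    followed by gyro x,y,z in deg/s, sites in the order of ``sensors``.
    """

    signal: np.ndarray
    metadata: TrialMetadata
    sample_rate_hz: float = 64.0
    sensors: tuple[str, ...] = SENSOR_SITES

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D (T, channels) array")
        if self.signal.shape[0] < 1:
            raise ValueError("trial must contain at least one sample")
        expected = 6 * len(self.sensors)
        if self.signal.shape[1] != expected:
            raise ValueError(
                f"signal has {self.signal.shape[1]} columns, expected {expected} "
                f"for sensors {self.sensors}"
            )
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def columns(self) -> list[str]:
        return signal_columns(self.sensors)


@dataclass
class FrameLabels:
    """Per-sample annotation tier over {0 non-FOG, 1 FOG, 2 FOG-related, 3 stop}."""

    labels: np.ndarray
    sample_rate_hz: float = 64.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        if self.labels.size == 0:
            raise ValueError("label vector must be non-empty")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        bad = (self.labels < 0) | (self.labels > 3)
        if bad.any():
            raise ValueError(f"labels outside {{0,1,2,3}} at index {int(np.argmax(bad))}")

    def __len__(self) -> int:
        return int(self.labels.size)

    def binary(self) -> np.ndarray:
        """Binary training/evaluation view: class 1 positive, {0,2,3} negative."""
        return (self.labels == LABEL_FOG).astype(np.int64)

    def binary_labels(self) -> "FrameLabels":
        return FrameLabels(self.binary(), self.sample_rate_hz)


@dataclass(frozen=True, order=True)
class Segment:
    """Half-open labeled sample interval [start, end) with 0-based indices."""

    start: int
    end: int
    label: int = LABEL_FOG

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid segment [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def duration_s(self, sample_rate_hz: float) -> float:
        return self.length / sample_rate_hz


def _label_array(labels: "FrameLabels | np.ndarray | Sequence[int]") -> np.ndarray:
    if isinstance(labels, FrameLabels):
        return labels.labels
    arr = np.asarray(labels, dtype=np.int64)
    if arr.ndim != 1:
        raise ValueError("labels must be 1-D")
    return arr


def labels_to_segments(
    labels: "FrameLabels | np.ndarray | Sequence[int]",
    target_class: int = LABEL_FOG,
) -> list[Segment]:
    """Extract maximal runs of ``target_class`` as sorted half-open segments."""
    arr = _label_array(labels)
    if arr.size == 0:
        raise ValueError("cannot extract segments from an empty label vector")
    mask = np.concatenate(([0], (arr == target_class).astype(np.int8), [0]))
    diff = np.diff(mask)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [Segment(int(s), int(e), target_class) for s, e in zip(starts, ends)]


def segments_to_labels(
    segments: Iterable[Segment],
    length: int,
    background: int = LABEL_NONFOG,
) -> FrameLabels:
    """Paint segments onto a background vector; inverse of :func:`labels_to_segments`."""
    if length < 1:
        raise ValueError("length must be >= 1")
    out = np.full(length, background, dtype=np.int64)
    covered = np.zeros(length, dtype=bool)
    for seg in sorted(segments):
        if seg.end > length:
            raise ValueError(f"segment [{seg.start}, {seg.end}) exceeds length {length}")
        if covered[seg.start : seg.end].any():
            raise ValueError(f"overlapping segment [{seg.start}, {seg.end})")
        covered[seg.start : seg.end] = True
        out[seg.start : seg.end] = seg.label
    return FrameLabels(out)


def resample_labels(
    labels: "FrameLabels | np.ndarray | Sequence[int]",
    source_rate: float,
    target_rate: float,
) -> FrameLabels:
    """Re-express categorical labels at a new sampling rate.

    Each output sample at time ``i / target_rate`` takes the label of the
    temporally nearest source frame (exact ties break toward the earlier
    frame).  Used to carry 30 fps video annotations onto 64 Hz IMU samples.
    """
    if source_rate <= 0 or target_rate <= 0:
        raise ValueError("sampling rates must be positive")
    arr = _label_array(labels)
    if arr.size == 0:
        raise ValueError("cannot resample an empty label vector")
    n_out = int(round(arr.size * target_rate / source_rate))
    if n_out < 1:
        raise ValueError("resampled vector would be empty")
    i = np.arange(n_out, dtype=np.float64)
    # nearest source index with ties toward the earlier frame: ceil(x - 1/2)
    src = np.ceil(i * (source_rate / target_rate) - 0.5).astype(np.int64)
    src = np.clip(src, 0, arr.size - 1)
    return FrameLabels(arr[src], sample_rate_hz=float(target_rate))
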