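"""In-memory containers for raw sensor recordings.

One trial of the protocol produces three single-channel surface-EMG
recordings (gluteus medius, gluteus maximus, rectus femoris) and one
three-axis knee accelerometer recording, all nominally 90 s long.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: canonical muscle order used everywhere downstream
MUSCLES = ("gluteus_medius", "gluteus_maximus", "rectus_femoris")

#: short column suffixes for feature-table columns
MUSCLE_SHORT = {
    "gluteus_medius": "gmd",
    "gluteus_maximus": "gmx",
    "rectus_femoris": "rf",
}

#: the five static exercises of the protocol
ACTIVITIES = (
    "single_leg_squat",
    "wall_sit",
    "side_leg_raise",
    "hip_extension",
    "knee_raise",
)


def _check_finite_1d(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D array")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite samples")
    return x


@dataclass
class EmgRecording:
    """A single sEMG channel: samples in volts at a fixed sampling rate."""

    samples: np.ndarray
    fs: float
    muscle: str

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.muscle not in MUSCLES:
            raise ValueError(f"unknown muscle {self.muscle!r}; expected one of {MUSCLES}")
        self.samples = _check_finite_1d(self.samples, "samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class AccelRecording:
    """Three-axis translational acceleration in m/s² at a fixed sampling rate."""

    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        self.ax = _check_finite_1d(self.ax, "ax")
        self.ay = _check_finite_1d(self.ay, "ay")
        self.az = _check_finite_1d(self.az, "az")
        if not (self.ax.size == self.ay.size == self.az.size):
            raise ValueError("axes must have equal length")

    @property
    def n_samples(self) -> int:
        return self.ax.size

    @property
    def duration_s(self) -> float:
        return self.ax.size / self.fs


@dataclass
class Trial:
    """One subject performing one static exercise, with all four sensor streams.

    ``truth`` carries synthetic ground-truth parameters (programmed relative
    MNF slopes, tremor growth, responder flags) when the trial was simulated;
    it is ``None`` for measured data.
    """

    trial_id: str
    subject: str
    activity: str
    emg: dict[str, EmgRecording]
    accel: AccelRecording
    limb: str = "right"
    truth: Optional[dict] = field(default=None)

    def __post_init__(self) -> None:
        missing = [m for m in MUSCLES if m not in self.emg]
        if missing:
            raise ValueError(f"trial {self.trial_id}: missing EMG channels {missing}")
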