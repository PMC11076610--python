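"""Synthetic trial generator with known ground truth.

The study's raw recordings are not publicly deposited, so the pipeline is
exercised on simulated trials that reproduce the two phenomena the analysis
is built to detect:

* **sEMG spectral compression under fatigue** — a band-limited stochastic
  signal whose mean frequency (MNF) drifts downward linearly in time while
  the amplitude envelope does not decrease (the JASA signature of fatigue
  rather than reduced effort).
* **growing knee wobble** — a gravity baseline plus a low-frequency tremor
  whose amplitude grows linearly over the trial.

The sEMG model is unit-RMS low-pass Gaussian noise (cutoff ``bandwidth/2``)
amplitude-modulated by a linear envelope and mixed up to a chirp carrier with
instantaneous frequency ``center_freq0 * (1 + rel_mnf_slope * t)``.  The
resulting power spectrum is symmetric about the carrier, so the programmed
MNF *is* the carrier frequency — which makes parameter-recovery tests exact
in expectation rather than approximate.

The tremor is circular in the x–y plane (quadrature sinusoids), so with zero
noise and a flat envelope the resultant acceleration is exactly constant.

All randomness flows from explicit integer seeds; a cohort derives per-trial,
per-channel seeds by counter from its master seed, never from the clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import signal

from .recordings import ACTIVITIES, MUSCLES, AccelRecording, EmgRecording, Trial

__all__ = [
    "SemgSynthParams",
    "AccelSynthParams",
    "CohortSpec",
    "generate_semg",
    "generate_accel",
    "cohort_truth",
    "iter_cohort",
    "generate_cohort",
]


@dataclass(frozen=True)
class SemgSynthParams:
    """Parameters of one synthetic sEMG channel.

    ``rel_mnf_slope`` is the relative drift of the spectral center per second:
    −0.003/s means the MNF falls by 0.3 % of its initial value every second,
    i.e. a −0.3 %/s fatigue slope.
    """

    duration_s: float = 90.0
    fs_emg: float = 4370.0
    center_freq0: float = 110.0     # Hz, inside the 20-400 Hz analysis band
    rel_mnf_slope: float = -0.003   # fraction/s; negative = fatigue
    bandwidth: float = 60.0         # Hz, full spectral width of the noise band
    amp0: float = 1e-4              # V, initial RMS (typical surface EMG ~0.1 mV)
    rel_amp_slope: float = 0.002    # fraction/s, >= 0 (effort does not decrease)
    noise_floor: float = 2e-6       # V, broadband measurement noise SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        if self.bandwidth <= 0:
            raise ValueError(f"bandwidth must be > 0, got {self.bandwidth}")
        nyq_need = 2.0 * (self.center_freq0 + self.bandwidth / 2.0)
        if self.fs_emg <= nyq_need:
            raise ValueError(
                f"fs_emg={self.fs_emg} Hz violates the Nyquist bound: must exceed "
                f"2*(center_freq0 + bandwidth/2) = {nyq_need} Hz"
            )
        if not 20.0 < self.center_freq0 < 400.0:
            raise ValueError(
                f"center_freq0 must lie in (20, 400) Hz so the drifting center stays "
                f"inside the analysis band, got {self.center_freq0}"
            )
        if self.rel_amp_slope < 0:
            raise ValueError(f"rel_amp_slope must be >= 0, got {self.rel_amp_slope}")


@dataclass(frozen=True)
class AccelSynthParams:
    """Parameters of one synthetic 3-axis knee accelerometer stream."""

    duration_s: float = 90.0
    fs_imu: float = 370.0
    gravity: float = 9.81           # m/s², static baseline on the z axis
    tremor_freq: float = 4.0        # Hz; < 10 Hz so it survives the IMU lowpass
    tremor_amp0: float = 0.8        # m/s², initial tremor amplitude
    rel_tremor_slope: float = 0.01  # fraction/s; positive = growing wobble
    noise_sd: float = 0.05          # m/s², per-axis white noise SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        if self.tremor_freq >= self.fs_imu / 2.0:
            raise ValueError(
                f"tremor_freq={self.tremor_freq} Hz must be below the Nyquist "
                f"frequency fs_imu/2 = {self.fs_imu / 2.0} Hz"
            )
        if self.tremor_amp0 < 0:
            raise ValueError(f"tremor_amp0 must be >= 0, got {self.tremor_amp0}")


def generate_semg(params: SemgSynthParams, muscle: str = "gluteus_medius") -> EmgRecording:
    """Generate one synthetic sEMG channel.

    The signal is zero-mean, band-limited around a center frequency drifting
    linearly from ``center_freq0`` at relative rate ``rel_mnf_slope``, with RMS
    envelope ``amp0 * (1 + rel_amp_slope * t)`` plus white measurement noise.
    Identical params (including seed) give bit-identical output.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration_s * p.fs_emg))
    t = np.arange(n) / p.fs_emg

    # unit-RMS baseband noise of half-bandwidth bandwidth/2
    white = rng.standard_normal(n)
    sos = signal.butter(4, p.bandwidth / 2.0, btype="low", fs=p.fs_emg, output="sos")
    base = signal.sosfilt(sos, white)
    rms = np.sqrt(np.mean(base**2))
    base = base / rms if rms > 0 else base

    # chirp carrier: instantaneous frequency f0*(1 + s*t)  ->  phase integral
    phase = 2.0 * np.pi * p.center_freq0 * (t + 0.5 * p.rel_mnf_slope * t**2)
    envelope = p.amp0 * (1.0 + p.rel_amp_slope * t)
    samples = np.sqrt(2.0) * envelope * base * np.cos(phase)
    if p.noise_floor > 0:
        samples = samples + p.noise_floor * rng.standard_normal(n)
    return EmgRecording(samples=samples, fs=p.fs_emg, muscle=muscle)


def generate_accel(params: AccelSynthParams) -> AccelRecording:
    """Generate one synthetic 3-axis accelerometer stream.

    Gravity sits on the z axis; the tremor is a quadrature (circular) x-y
    oscillation at ``tremor_freq`` whose amplitude grows linearly at
    ``rel_tremor_slope``, plus independent white noise per axis.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration_s * p.fs_imu))
    t = np.arange(n) / p.fs_imu

    amp = p.tremor_amp0 * (1.0 + p.rel_tremor_slope * t)
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    w = 2.0 * np.pi * p.tremor_freq * t + phi0
    ax = amp * np.cos(w)
    ay = amp * np.sin(w)
    az = np.full(n, p.gravity)
    if p.noise_sd > 0:
        ax = ax + p.noise_sd * rng.standard_normal(n)
        ay = ay + p.noise_sd * rng.standard_normal(n)
        az = az + p.noise_sd * rng.standard_normal(n)
    return AccelRecording(ax=ax, ay=ay, az=az, fs=p.fs_imu)


@dataclass(frozen=True)
class CohortSpec:
    """Shape and parameter distributions of a synthetic cohort.

    Mirrors the study design: ``n_subjects`` subjects each perform every
    activity once (24 x 5 = 120 trials by default).  Each muscle of each trial
    is independently drawn as a fatigue responder with probability
    ``responder_fraction``; responders get a relative MNF slope drawn uniformly
    from ``fatigue_slope_range`` (defaults spanning the −0.5 to −0.15 %/s band
    typical of static-exercise fatigue), non-responders get slope 0.

    Knee-wobble growth is coupled to fatigue: the per-trial tremor growth rate
    is ``accel.rel_tremor_slope * (wobble_floor + wobble_coupling * n_fatigued/3)``,
    so trials with more fatigued muscles wobble more.
    """

    n_subjects: int = 24
    activities: tuple[str, ...] = ACTIVITIES
    responder_fraction: float = 0.5
    master_seed: int = 0
    semg: SemgSynthParams = field(default_factory=SemgSynthParams)
    accel: AccelSynthParams = field(default_factory=AccelSynthParams)
    fatigue_slope_range: tuple[float, float] = (-0.005, -0.0015)  # fraction/s
    wobble_floor: float = 0.2
    wobble_coupling: float = 1.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.activities:
            raise ValueError("activities must be non-empty")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError(
                f"responder_fraction must be in [0, 1], got {self.responder_fraction}"
            )
        lo, hi = self.fatigue_slope_range
        if lo > hi:
            raise ValueError("fatigue_slope_range must be (low, high) with low <= high")

    @property
    def n_trials(self) -> int:
        return self.n_subjects * len(self.activities)


def _child_seed(master_seed: int, *key: int) -> int:
    """Counter-derived child seed, stable across runs, < 2**31."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def cohort_truth(spec: CohortSpec) -> pd.DataFrame:
    """Draw the cohort's ground-truth plan without generating any signals.

    One row per trial: identifiers, per-muscle responder flags and programmed
    relative MNF slopes, the coupled tremor growth rate, and the per-channel
    seeds.  Deterministic under ``master_seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.master_seed))
    lo, hi = spec.fatigue_slope_range
    rows = []
    idx = 0
    for s in range(spec.n_subjects):
        subject = f"S{s + 1:02d}"
        for activity in spec.activities:
            u = rng.random(len(MUSCLES))
            drawn = rng.uniform(lo, hi, len(MUSCLES))
            responders = u < spec.responder_fraction
            slopes = np.where(responders, drawn, 0.0)
            n_fat = int(responders.sum())
            tremor_slope = spec.accel.rel_tremor_slope * (
                spec.wobble_floor + spec.wobble_coupling * n_fat / len(MUSCLES)
            )
            row = {
                "trial_id": f"{subject}_{activity}",
                "subject": subject,
                "activity": activity,
                "n_fatigued": n_fat,
                "rel_tremor_slope": tremor_slope,
                "accel_seed": _child_seed(spec.master_seed, idx, len(MUSCLES)),
            }
            for k, m in enumerate(MUSCLES):
                row[f"fatigue_{m}"] = bool(responders[k])
                row[f"rel_mnf_slope_{m}"] = float(slopes[k])
                row[f"emg_seed_{m}"] = _child_seed(spec.master_seed, idx, k)
            rows.append(row)
            idx += 1
    return pd.DataFrame(rows)


def realize_trial(spec: CohortSpec, row: pd.Series | dict) -> Trial:
    """Generate the four sensor streams for one row of the ground-truth plan."""
    emg = {}
    for m in MUSCLES:
        params = replace(
            spec.semg,
            rel_mnf_slope=float(row[f"rel_mnf_slope_{m}"]),
            seed=int(row[f"emg_seed_{m}"]),
        )
        emg[m] = generate_semg(params, muscle=m)
    accel_params = replace(
        spec.accel,
        rel_tremor_slope=float(row["rel_tremor_slope"]),
        seed=int(row["accel_seed"]),
    )
    truth = {k: row[k] for k in row.keys() if k not in ("trial_id", "subject", "activity")}
    return Trial(
        trial_id=str(row["trial_id"]),
        subject=str(row["subject"]),
        activity=str(row["activity"]),
        emg=emg,
        accel=generate_accel(accel_params),
        truth=truth,
    )


def iter_cohort(spec: CohortSpec, truth: pd.DataFrame | None = None) -> Iterator[Trial]:
    """Yield the cohort's trials one at a time (memory-friendly)."""
    if truth is None:
        truth = cohort_truth(spec)
    for _, row in truth.iterrows():
        yield realize_trial(spec, row)


def generate_cohort(spec: CohortSpec) -> tuple[list[Trial], pd.DataFrame]:
    """Generate the full cohort eagerly; returns (trials, ground-truth table)."""
    truth = cohort_truth(spec)
    return list(iter_cohort(spec, truth)), truth
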