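"""Plain-CSV readers and writers for trials and cohort manifests.

Each trial is stored as four CSVs in its own directory: one per sEMG channel
(columns ``time_s, value``) and one for the IMU (``time_s, ax, ay, az``),
plus a cohort-level ``manifest.csv`` carrying identifiers and, for synthetic
cohorts, the ground-truth parameters.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .recordings import MUSCLES, AccelRecording, EmgRecording, Trial

__all__ = [
    "write_trial_csvs",
    "write_manifest",
    "read_emg_csv",
    "read_accel_csv",
    "read_trial",
]

EMG_COLUMNS = ["time_s", "value"]
IMU_COLUMNS = ["time_s", "ax", "ay", "az"]


def write_trial_csvs(trial: Trial, out_dir: str | Path) -> Path:
    """Write one trial's four sensor streams under ``out_dir/<trial_id>/``."""
    trial_dir = Path(out_dir) / trial.trial_id
    trial_dir.mkdir(parents=True, exist_ok=True)
    for muscle, rec in trial.emg.items():
        t = np.arange(rec.samples.size) / rec.fs
        pd.DataFrame({"time_s": t, "value": rec.samples}).to_csv(
            trial_dir / f"emg_{muscle}.csv", index=False
        )
    acc = trial.accel
    t = np.arange(acc.n_samples) / acc.fs
    pd.DataFrame({"time_s": t, "ax": acc.ax, "ay": acc.ay, "az": acc.az}).to_csv(
        trial_dir / "imu.csv", index=False
    )
    return trial_dir


def write_manifest(truth: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    truth.to_csv(path, index=False)
    return path


def _read_timeseries(path: str | Path, expected_columns: list[str]) -> tuple[pd.DataFrame, float]:
    df = pd.read_csv(path)
    missing = [c for c in expected_columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time_s must be strictly increasing")
    fs = (t.size - 1) / (t[-1] - t[0])
    return df, float(fs)


def read_emg_csv(path: str | Path, muscle: str) -> EmgRecording:
    df, fs = _read_timeseries(path, EMG_COLUMNS)
    return EmgRecording(samples=df["value"].to_numpy(dtype=float), fs=fs, muscle=muscle)


def read_accel_csv(path: str | Path) -> AccelRecording:
    df, fs = _read_timeseries(path, IMU_COLUMNS)
    return AccelRecording(
        ax=df["ax"].to_numpy(dtype=float),
        ay=df["ay"].to_numpy(dtype=float),
        az=df["az"].to_numpy(dtype=float),
        fs=fs,
    )


def read_trial(trial_dir: str | Path, subject: str | None = None, activity: str | None = None) -> Trial:
    """Load one trial from the CSV layout written by :func:`write_trial_csvs`."""
    trial_dir = Path(trial_dir)
    emg = {m: read_emg_csv(trial_dir / f"emg_{m}.csv", m) for m in MUSCLES}
    accel = read_accel_csv(trial_dir / "imu.csv")
    trial_id = trial_dir.name
    if subject is None or activity is None:
        parts = trial_id.split("_", 1)
        subject = subject or parts[0]
        activity = activity or (parts[1] if len(parts) > 1 else "unknown")
    return Trial(trial_id=trial_id, subject=subject, activity=activity, emg=emg, accel=accel)
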