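"""Filtering, trimming and segmentation of raw recordings.

sEMG channels get an 8th-order Butterworth bandpass (20-400 Hz); the
accelerometer axes get a 4th-order Butterworth lowpass (10 Hz).  Both are
applied zero-phase (forward-backward) so interval boundaries are not smeared
by group delay; the stated filter order refers to the single-pass design, and
the -3 dB contract is defined on that single-pass magnitude.

The first and last 2 s of each 90 s exercise are discarded and the remaining
86 s is split into ten equal intervals (37,582 samples each at 4370 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.optimize import brentq

from .recordings import AccelRecording, EmgRecording

__all__ = [
    "design_bandpass",
    "design_lowpass",
    "bandpass_emg",
    "lowpass_accel",
    "trim",
    "resultant",
    "SegmentedSeries",
    "segment",
    "magnitude_db",
    "band_edges_3db",
]


def design_bandpass(low: float, high: float, fs: float, order: int = 8) -> np.ndarray:
    """Butterworth bandpass in SOS form; ``order`` is the total pole count."""
    if order < 2 or order % 2:
        raise ValueError(f"bandpass order must be a positive even pole count, got {order}")
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= fs / 2:
        raise ValueError(
            f"high cutoff {high} Hz must be below the Nyquist frequency {fs / 2} Hz"
        )
    return signal.butter(order // 2, [low, high], btype="bandpass", fs=fs, output="sos")


def design_lowpass(cutoff: float, fs: float, order: int = 4) -> np.ndarray:
    """Butterworth lowpass in SOS form."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if cutoff >= fs / 2:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below the Nyquist frequency {fs / 2} Hz"
        )
    return signal.butter(order, cutoff, btype="low", fs=fs, output="sos")


def bandpass_emg(
    rec: EmgRecording, low: float = 20.0, high: float = 400.0, order: int = 8
) -> EmgRecording:
    """Zero-phase 8th-order Butterworth bandpass of one sEMG channel."""
    sos = design_bandpass(low, high, rec.fs, order=order)
    return EmgRecording(
        samples=signal.sosfiltfilt(sos, rec.samples), fs=rec.fs, muscle=rec.muscle
    )


def lowpass_accel(rec: AccelRecording, cutoff: float = 10.0, order: int = 4) -> AccelRecording:
    """Zero-phase 4th-order Butterworth lowpass, applied identically per axis."""
    sos = design_lowpass(cutoff, rec.fs, order=order)
    return AccelRecording(
        ax=signal.sosfiltfilt(sos, rec.ax),
        ay=signal.sosfiltfilt(sos, rec.ay),
        az=signal.sosfiltfilt(sos, rec.az),
        fs=rec.fs,
    )


def trim(samples: np.ndarray, fs: float, head_s: float = 2.0, tail_s: float = 2.0) -> np.ndarray:
    """Drop ``round(head_s*fs)`` leading and ``round(tail_s*fs)`` trailing samples."""
    samples = np.asarray(samples)
    n_head = int(round(head_s * fs))
    n_tail = int(round(tail_s * fs))
    if samples.size <= n_head + n_tail:
        raise ValueError(
            f"signal of {samples.size} samples too short to trim "
            f"{n_head} + {n_tail} samples"
        )
    return samples[n_head : samples.size - n_tail]


def resultant(rec: AccelRecording) -> np.ndarray:
    """Elementwise Euclidean norm of the three axes (the knee-wobble signal)."""
    return np.sqrt(rec.ax**2 + rec.ay**2 + rec.az**2)


@dataclass
class SegmentedSeries:
    """Equal-length, contiguous, temporally ordered intervals of one signal."""

    intervals: list[np.ndarray]
    fs: float
    interval_duration: float

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)


def segment(samples: np.ndarray, fs: float, n_intervals: int = 10) -> SegmentedSeries:
    """Split into ``n_intervals`` equal pieces, dropping any tail remainder."""
    samples = np.asarray(samples)
    if n_intervals < 1:
        raise ValueError(f"n_intervals must be >= 1, got {n_intervals}")
    if samples.size < n_intervals:
        raise ValueError(
            f"cannot split {samples.size} samples into {n_intervals} intervals"
        )
    length = samples.size // n_intervals
    intervals = [samples[i * length : (i + 1) * length] for i in range(n_intervals)]
    return SegmentedSeries(intervals=intervals, fs=fs, interval_duration=length / fs)


def magnitude_db(sos: np.ndarray, freqs: np.ndarray, fs: float) -> np.ndarray:
    """Single-pass magnitude response in dB at the given frequencies."""
    _, h = signal.sosfreqz(sos, worN=np.atleast_1d(freqs), fs=fs)
    return 20.0 * np.log10(np.abs(h))


def band_edges_3db(sos: np.ndarray, fs: float) -> tuple[float, float]:
    """Frequencies where the single-pass magnitude crosses -3 dB (|H|² = 1/2).

    Located by root-finding on a log-spaced magnitude grid; for a bandpass the
    first and last crossings are the lower and upper band edges, for a lowpass
    both values coincide with the single cutoff.
    """
    grid = np.logspace(np.log10(fs / 2 * 1e-4), np.log10(fs / 2 * 0.999), 4000)
    mag = magnitude_db(sos, grid, fs)
    above = mag > -3.0103  # |H|^2 > 1/2

    def f(freq: float) -> float:
        _, h = signal.sosfreqz(sos, worN=[freq], fs=fs)
        return float(np.abs(h[0]) ** 2 - 0.5)

    crossings = []
    for i in np.nonzero(np.diff(above))[0]:
        crossings.append(brentq(f, grid[i], grid[i + 1], xtol=1e-9))
    if not crossings:
        raise ValueError("magnitude response never crosses -3 dB on the grid")
    return crossings[0], crossings[-1]
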