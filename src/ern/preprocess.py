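"""Filtering, resampling, baseline-mean subtraction, band splits, windowing.

The preprocessing chain for a raw trial is:

1. band-pass 4-45 Hz (zero-phase), optionally a narrower rhythm band;
2. resample to the working rate (128 Hz);
3. cut the pre-stimulus baseline into N fixed-length segments, average them
   into a per-channel reference matrix Z (C x L), and subtract Z from each of
   the M stimulus segments;
4. slice the corrected signal into fixed windows (1 s or 2 s, optionally with
   0.5 s overlap).

Filters are 4th-order Butterworth applied forward-backward (zero phase,
order effectively doubled).  Windows are half-open [start, start+len) with
0-based sample indexing; trailing samples that do not fill a window are
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

__all__ = [
    "BANDS",
    "BandSpec",
    "WindowSpec",
    "bandpass",
    "resample",
    "split_trial",
    "baseline_mean",
    "subtract_baseline",
    "correct_baseline",
    "window_segments",
    "band_decompose",
]


@dataclass(frozen=True)
class BandSpec:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"invalid band {self.low_hz}-{self.high_hz} Hz")


#: Conventional rhythm bands, consistent with the 4-45 Hz broadband.
BANDS: dict[str, BandSpec] = {
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 13.0),
    "beta": BandSpec("beta", 13.0, 30.0),
    "gamma": BandSpec("gamma", 30.0, 45.0),
    "broadband": BandSpec("broadband", 4.0, 45.0),
}


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window parameters in seconds."""

    length_s: float = 1.0
    overlap_s: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_s < self.length_s:
            raise ValueError("overlap must be non-negative and shorter than the window")


def bandpass(
    x: np.ndarray, fs: float, low: float = 4.0, high: float = 45.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    nyq = fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band {low}-{high} Hz outside (0, {nyq}) for fs={fs}")
    sos = scipy.signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return scipy.signal.sosfiltfilt(sos, x, axis=-1)


def resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-aliased rational resampling along the last axis.

    Output length is round(n * fs_out / fs_in).
    """
    if fs_out <= 0:
        raise ValueError("fs_out must be positive")
    if fs_in < fs_out:
        raise ValueError("upsampling is not supported; fs_in must be >= fs_out")
    if fs_in == fs_out:
        return np.asarray(x).copy()
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return scipy.signal.resample_poly(x, frac.numerator, frac.denominator, axis=-1)


def split_trial(
    trial: np.ndarray, fs: float, baseline_s: float, L: int
) -> tuple[np.ndarray, np.ndarray]:
    """Cut a C x S trial into baseline and stimulus segments of length L.

    Returns (baseline [N x C x L], stimulus [M x C x L]); concatenating them
    along time in order reconstructs the trial exactly.
    """
    trial = np.asarray(trial)
    C, S = trial.shape
    n_base = int(round(baseline_s * fs))
    n_stim = S - n_base
    if n_base % L or n_stim % L:
        raise ValueError(
            f"baseline ({n_base}) and stimulus ({n_stim}) sample counts must "
            f"both divide by segment length L={L}"
        )
    N, M = n_base // L, n_stim // L
    baseline = trial[:, :n_base].reshape(C, N, L).transpose(1, 0, 2)
    stimulus = trial[:, n_base:].reshape(C, M, L).transpose(1, 0, 2)
    return baseline, stimulus


def baseline_mean(segments: np.ndarray) -> np.ndarray:
    """Elementwise mean Z (C x L) of N baseline segments [N x C x L]."""
    segments = np.asarray(segments)
    if segments.ndim != 3 or segments.shape[0] < 1:
        raise ValueError("need at least one N x C x L baseline segment")
    return segments.mean(axis=0)


def subtract_baseline(stimulus: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Subtract the baseline reference Z from every stimulus segment."""
    stimulus, Z = np.asarray(stimulus), np.asarray(Z)
    if stimulus.ndim != 3 or stimulus.shape[1:] != Z.shape:
        raise ValueError(
            f"stimulus segments {stimulus.shape} incompatible with Z {Z.shape}"
        )
    return stimulus - Z[None, :, :]


def correct_baseline(
    trial: np.ndarray, fs: float, baseline_s: float, L: int | None = None
) -> np.ndarray:
    """Full baseline correction of one trial; returns the merged C x (S - baseline)
    stimulus signal with the mean baseline segment subtracted.

    L defaults to one second of samples.
    """
    L = int(round(fs)) if L is None else L
    base, stim = split_trial(trial, fs, baseline_s, L)
    if base.shape[0] == 0:
        corrected = stim
    else:
        corrected = subtract_baseline(stim, baseline_mean(base))
    M, C, _ = corrected.shape
    return corrected.transpose(1, 0, 2).reshape(C, M * L)


def window_segments(x: np.ndarray, fs: float, w: WindowSpec) -> np.ndarray:
    """Slice a C x S signal into K x C x (length_s*fs) windows.

    K = 1 + floor((S - win) / step) with step = (length_s - overlap_s)*fs;
    trailing samples that do not fill a window are dropped.
    """
    x = np.asarray(x)
    C, S = x.shape
    win = int(round(w.length_s * fs))
    step = int(round((w.length_s - w.overlap_s) * fs))
    if S < win:
        raise ValueError(f"signal of {S} samples shorter than window of {win}")
    K = 1 + (S - win) // step
    out = np.empty((K, C, win), dtype=x.dtype)
    for k in range(K):
        out[k] = x[:, k * step : k * step + win]
    return out


def band_decompose(x: np.ndarray, fs: float, band: BandSpec | str) -> np.ndarray:
    """Band-pass with a named rhythm band (theta/alpha/beta/gamma/broadband)."""
    if isinstance(band, str):
        band = BANDS[band]
    if not (BANDS["broadband"].low_hz <= band.low_hz
            and band.high_hz <= BANDS["broadband"].high_hz):
        raise ValueError(f"band {band.name} outside the 4-45 Hz analysis range")
    return bandpass(x, fs, band.low_hz, band.high_hz)
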