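"""Synthetic multichannel EEG with controllable class-conditional structure.

Two generators emulate the structure of the public affective-EEG benchmarks:

* ``generate_deap_like`` — 32-channel, 63-s trials at 128 Hz (3-s pre-stimulus
  baseline followed by 60 s of stimulus), one continuous valence/arousal
  rating pair per trial.
* ``generate_seed4_like`` — 15 subjects x 3 sessions x 15 one-second clips at
  128 Hz with categorical four-class labels.

Background activity is 1/f ("pink") noise, the broadband spectral shape of
resting EEG.  Each emotion class adds a band-limited oscillation in its own
carrier band (theta 6 Hz, alpha 10 Hz, beta 20 Hz, gamma 35 Hz) on a fixed
frontal/parietal channel subset, at amplitude ``class_effect`` times the
background RMS, so the class is decodable from band power topography.  With
``class_effect = 0`` the labels are statistically independent of the data.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import DEAP_32_CHANNELS, LabelRecord, RawTrialSet

__all__ = [
    "SynthSpec",
    "CLASS_CARRIER_HZ",
    "SIGNATURE_CHANNELS",
    "pink_noise",
    "generate_deap_like",
    "generate_seed4_like",
]

#: Carrier frequency (Hz) of the oscillation injected for each class.
#: One disjoint band per class inside the 4-45 Hz analysis range.
CLASS_CARRIER_HZ: tuple[float, ...] = (6.0, 10.0, 20.0, 35.0)

#: Channels carrying the class signature: frontal and parietal sites, where
#: emotion effects are typically reported.
SIGNATURE_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "Fz", "P3", "P4", "Pz",
)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic recording.

    ``class_effect`` is the ratio of class-oscillation amplitude to the
    background noise RMS on the signature channels; 1.0 (the default) gives a
    clearly learnable but not trivial four-class problem, 0 gives pure noise.
    """

    n_subjects: int = 1
    n_trials: int = 40
    n_channels: int = 32
    fs: float = 128.0
    trial_seconds: float = 63.0
    baseline_seconds: float = 3.0
    class_effect: float = 1.0
    noise_model: str = "pink"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_effect < 0:
            raise ValueError("class_effect must be >= 0")
        if self.noise_model not in ("pink", "white"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        n = self.trial_seconds * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"trial_seconds*fs = {n} is not an integer sample count"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_seconds * self.fs))


def pink_noise(n_samples: int, seed: int | np.random.Generator) -> np.ndarray:
    """Zero-mean noise whose power spectrum falls off approximately as 1/f.

    Generated by shaping a white spectrum with 1/sqrt(f) amplitude weights
    (flat below 1 Hz to avoid the DC divergence) and inverse FFT; the series
    is normalised to unit RMS.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # frequency bins of an rfft at unit sampling rate; the shaping only needs
    # relative frequencies, the caller's fs drops out of the spectral slope
    freqs = np.fft.rfftfreq(n_samples, d=1.0)
    weights = 1.0 / np.sqrt(np.maximum(freqs, freqs[1] if n_samples > 1 else 1.0))
    weights[0] = 0.0  # no DC -> zero mean
    spectrum = weights * (
        rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    )
    x = np.fft.irfft(spectrum, n=n_samples)
    rms = np.sqrt(np.mean(x**2))
    return (x / rms) if rms > 0 else x


def _noise(spec: SynthSpec, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_model == "pink":
        return pink_noise(n_samples, rng)
    return rng.standard_normal(n_samples)


def _class_signal(
    cls: int, n_samples: int, fs: float, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Band-limited oscillation at the class carrier with a random phase."""
    t = np.arange(n_samples) / fs
    phase = rng.uniform(0, 2 * np.pi)
    return amplitude * np.sin(2 * np.pi * CLASS_CARRIER_HZ[cls] * t + phase)


def _rating_for_class(cls: int, rng: np.random.Generator) -> LabelRecord:
    """Uniform rating in the class's quadrant of the [1,9]^2 valence/arousal
    square; low is [1,5], high is (5,9], so threshold-5 discretisation
    recovers the class exactly."""
    high_v, high_a = cls >= 2, cls % 2 == 1
    valence = 9.0 - rng.uniform(0.0, 4.0) if high_v else rng.uniform(1.0, 5.0)
    arousal = 9.0 - rng.uniform(0.0, 4.0) if high_a else rng.uniform(1.0, 5.0)
    return LabelRecord(valence=float(valence), arousal=float(arousal))


def _balanced_classes(n: int, rng: np.random.Generator) -> np.ndarray:
    """A shuffled near-balanced class sequence (counts differ by at most 1)."""
    return rng.permutation(np.arange(n) % 4)


def generate_deap_like(spec: SynthSpec | None = None, **kwargs) -> RawTrialSet:
    """DEAP-like recording for one subject.

    Each trial is ``trial_seconds`` long; the first ``baseline_seconds`` are
    noise only (pre-stimulus), the remainder adds the class oscillation on
    the signature channels.  Ratings are drawn from the class quadrant.
    """
    spec = replace(spec or SynthSpec(), **kwargs) if kwargs or spec is None else spec
    rng = np.random.default_rng(spec.seed)
    n_samples = spec.n_samples
    n_base = int(round(spec.baseline_seconds * spec.fs))
    names = list(DEAP_32_CHANNELS[: spec.n_channels])
    sig_idx = [names.index(c) for c in SIGNATURE_CHANNELS if c in names]

    classes = _balanced_classes(spec.n_trials, rng)
    data = np.empty((spec.n_trials, spec.n_channels, n_samples))
    labels = []
    for i, cls in enumerate(classes):
        for c in range(spec.n_channels):
            data[i, c] = _noise(spec, n_samples, rng)
        if spec.class_effect > 0:
            for c in sig_idx:
                sig = _class_signal(
                    int(cls), n_samples - n_base, spec.fs, spec.class_effect, rng
                )
                data[i, c, n_base:] += sig
        labels.append(_rating_for_class(int(cls), rng))
    return RawTrialSet(f"synth-deap-{spec.seed}", data, spec.fs, names, labels)


def generate_seed4_like(spec: SynthSpec | None = None, **kwargs) -> RawTrialSet:
    """SEED-IV-like set: ``n_subjects x 3 sessions x n_trials`` one-second
    clips with categorical labels (0 happy, 1 sad, 2 neutral, 3 fear).

    All clips are stacked into one RawTrialSet in subject-major, then
    session-major, then clip order.
    """
    if spec is None or kwargs:
        spec = replace(
            spec or SynthSpec(n_subjects=15, n_trials=15, trial_seconds=1.0,
                              baseline_seconds=0.0),
            **kwargs,
        )
    rng = np.random.default_rng(spec.seed)
    n_sessions = 3
    n_clips = spec.n_subjects * n_sessions * spec.n_trials
    n_samples = spec.n_samples
    names = list(DEAP_32_CHANNELS[: spec.n_channels])
    sig_idx = [names.index(c) for c in SIGNATURE_CHANNELS if c in names]

    classes = _balanced_classes(n_clips, rng)
    data = np.empty((n_clips, spec.n_channels, n_samples))
    labels = []
    for i, cls in enumerate(classes):
        for c in range(spec.n_channels):
            data[i, c] = _noise(spec, n_samples, rng)
        if spec.class_effect > 0:
            for c in sig_idx:
                data[i, c] += _class_signal(
                    int(cls), n_samples, spec.fs, spec.class_effect, rng
                )
        labels.append(LabelRecord(categorical=int(cls)))
    return RawTrialSet(f"synth-seed4-{spec.seed}", data, spec.fs, names, labels)
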