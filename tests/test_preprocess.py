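"""Filtering, resampling, baseline subtraction and windowing contracts."""

import numpy as np
import pytest

from ern.preprocess import (
    BANDS,
    BandSpec,
    WindowSpec,
    band_decompose,
    bandpass,
    baseline_mean,
    correct_baseline,
    resample,
    split_trial,
    subtract_baseline,
    window_segments,
)

FS = 128.0


def sine(freq, fs=FS, seconds=4.0):
    t = np.arange(int(seconds * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_passband_tone_preserved(self):
        x = sine(10.0)
        y = bandpass(x, FS, 4.0, 45.0)
        mid = slice(64, -64)  # ignore filter edge transients
        amp = np.sqrt(2) * np.sqrt(np.mean(y[mid] ** 2))
        assert abs(amp - 1.0) < 0.05

    def test_stopband_tone_suppressed(self):
        x = sine(1.0)
        y = bandpass(x, FS, 4.0, 45.0)
        assert np.sqrt(np.mean(y**2)) < 0.1 * np.sqrt(np.mean(x**2))

    def test_zero_in_zero_out(self):
        np.testing.assert_array_equal(bandpass(np.zeros(256), FS), 0.0)

    def test_zero_phase_no_delay(self):
        """Forward-backward filtering leaves a passband tone in phase."""
        x = sine(10.0)
        y = bandpass(x, FS, 4.0, 45.0)
        mid = slice(64, -64)
        corr = np.corrcoef(x[mid], y[mid])[0, 1]
        assert corr > 0.99

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(64), FS, 4.0, 70.0)


class TestResample:
    def test_63s_at_512_gives_8064(self):
        x = np.zeros(63 * 512)
        assert resample(x, 512.0, 128.0).shape == (8064,)

    def test_identity_when_rates_match(self):
        x = np.arange(100.0)
        np.testing.assert_array_equal(resample(x, 128.0, 128.0), x)

    def test_tone_frequency_preserved(self):
        x = np.sin(2 * np.pi * 10.0 * np.arange(512 * 4) / 512.0)
        y = resample(x, 512.0, 128.0)
        spec = np.abs(np.fft.rfft(y))
        f = np.fft.rfftfreq(len(y), 1 / 128.0)
        assert abs(f[spec.argmax()] - 10.0) < 0.1

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            resample(np.zeros(10), 128.0, 0.0)
        with pytest.raises(ValueError):
            resample(np.zeros(10), 128.0, 256.0)


class TestBaseline:
    def test_deap_shapes(self):
        trial = np.arange(32 * 8064, dtype=float).reshape(32, 8064)
        base, stim = split_trial(trial, FS, baseline_s=3.0, L=128)
        assert base.shape == (3, 32, 128)
        assert stim.shape == (60, 32, 128)

    def test_split_then_concat_is_identity(self, rng):
        trial = rng.standard_normal((4, 512))
        base, stim = split_trial(trial, FS, baseline_s=1.0, L=128)
        merged = np.concatenate(
            [np.concatenate(list(base), axis=1), np.concatenate(list(stim), axis=1)],
            axis=1,
        )
        np.testing.assert_array_equal(merged, trial)

    def test_zero_baseline_all_stimulus(self):
        trial = np.ones((2, 256))
        base, stim = split_trial(trial, FS, baseline_s=0.0, L=128)
        assert base.shape[0] == 0 and stim.shape[0] == 2

    def test_indivisible_length_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            split_trial(np.ones((2, 300)), FS, baseline_s=0.0, L=128)

    def test_mean_of_constant_segments(self):
        segs = np.stack([np.ones((3, 4)), 3 * np.ones((3, 4))])
        np.testing.assert_array_equal(baseline_mean(segs), 2 * np.ones((3, 4)))

    def test_mean_single_segment_is_identity(self, rng):
        seg = rng.standard_normal((1, 3, 8))
        np.testing.assert_array_equal(baseline_mean(seg), seg[0])

    def test_mean_permutation_invariant(self, rng):
        segs = rng.standard_normal((5, 3, 8))
        np.testing.assert_allclose(
            baseline_mean(segs), baseline_mean(segs[::-1]), rtol=1e-12
        )

    def test_subtract_constant_case(self):
        stim = 5.0 * np.ones((2, 3, 4))
        Z = 2.0 * np.ones((3, 4))
        np.testing.assert_array_equal(subtract_baseline(stim, Z), 3.0)

    def test_subtract_identical_gives_zero(self, rng):
        Z = rng.standard_normal((3, 4))
        stim = np.broadcast_to(Z, (5, 3, 4)).copy()
        np.testing.assert_array_equal(subtract_baseline(stim, Z), 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subtract_baseline(np.ones((2, 3, 4)), np.ones((3, 5)))

    def test_corrected_trial_merges_to_32x7680(self):
        trial = np.random.default_rng(0).standard_normal((32, 8064))
        out = correct_baseline(trial, FS, baseline_s=3.0)
        assert out.shape == (32, 7680)

    def test_shift_cancellation(self, rng):
        """Adding a constant to baseline and stimulus leaves the corrected
        signal unchanged."""
        trial = rng.standard_normal((4, 640))
        shifted = trial + 7.5
        np.testing.assert_allclose(
            correct_baseline(trial, FS, baseline_s=1.0),
            correct_baseline(shifted, FS, baseline_s=1.0),
            atol=1e-9,
        )


class TestWindows:
    @pytest.mark.parametrize(
        "seconds,length_s,overlap_s,expected",
        [(60, 1.0, 0.0, 60), (60, 1.0, 0.5, 119), (2, 2.0, 0.0, 1),
         (60, 2.0, 0.0, 30), (60, 2.0, 0.5, 39)],
    )
    def test_window_counts(self, seconds, length_s, overlap_s, expected):
        x = np.zeros((32, int(seconds * FS)))
        out = window_segments(x, FS, WindowSpec(length_s, overlap_s))
        assert out.shape == (expected, 32, int(length_s * FS))

    def test_single_window_equals_input(self, rng):
        x = rng.standard_normal((3, 256))
        out = window_segments(x, FS, WindowSpec(2.0, 0.0))
        np.testing.assert_array_equal(out[0], x)

    def test_non_overlapping_windows_partition_signal(self, rng):
        x = rng.standard_normal((2, 5 * 128))
        out = window_segments(x, FS, WindowSpec(1.0, 0.0))
        np.testing.assert_array_equal(
            np.concatenate(list(out), axis=1), x
        )

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            window_segments(np.zeros((2, 64)), FS, WindowSpec(1.0, 0.0))

    def test_overlap_must_be_shorter_than_window(self):
        with pytest.raises(ValueError):
            WindowSpec(1.0, 1.0)


class TestBands:
    def test_broadband_equals_default_bandpass(self, rng):
        x = rng.standard_normal(512)
        np.testing.assert_allclose(
            band_decompose(x, FS, "broadband"), bandpass(x, FS, 4.0, 45.0)
        )

    def test_alpha_band_keeps_10hz(self):
        y = band_decompose(sine(10.0), FS, BANDS["alpha"])
        mid = slice(64, -64)
        amp = np.sqrt(2) * np.sqrt(np.mean(y[mid] ** 2))
        assert abs(amp - 1.0) < 0.05

    def test_theta_band_rejects_10hz(self):
        y = band_decompose(sine(10.0), FS, BANDS["theta"])
        assert np.sqrt(np.mean(y**2)) < 0.1

    def test_band_outside_analysis_range_rejected(self):
        with pytest.raises(ValueError):
            band_decompose(np.zeros(128), FS, BandSpec("wide", 1.0, 45.0))
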