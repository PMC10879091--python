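"""The forward-backward transform: oracles, identities and properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fbft import (
    TFMap,
    default_pad_len,
    fbft,
    fbft_reference,
    fbft_signal,
    prefix_spectra,
    ridge_frequency,
    suffix_spectra,
)

from conftest import dft_mag_onesided


class TestSpectraOracles:
    def test_prefix_all_zero(self):
        assert not prefix_spectra(np.zeros(16), pad_len=32).any()

    def test_suffix_all_zero(self):
        assert not suffix_spectra(np.zeros(16), pad_len=32).any()

    def test_prefix_last_column_is_full_signal_fft(self, rng):
        x = rng.standard_normal(50)
        cols = prefix_spectra(x, pad_len=128)
        np.testing.assert_allclose(
            cols[:, -1], np.abs(np.fft.rfft(x, n=128)), atol=1e-12
        )

    def test_suffix_first_column_is_full_signal_fft(self, rng):
        x = rng.standard_normal(50)
        cols = suffix_spectra(x, pad_len=128)
        np.testing.assert_allclose(
            cols[:, 0], np.abs(np.fft.rfft(x, n=128)), atol=1e-12
        )

    def test_prefix_matches_direct_dft(self, rng):
        x = rng.standard_normal(64)
        pad = 128
        cols = prefix_spectra(x, pad_len=pad)
        for u in range(64):
            np.testing.assert_allclose(
                cols[:, u], dft_mag_onesided(x[: u + 1], pad), atol=1e-9
            )

    def test_suffix_matches_direct_dft(self, rng):
        x = rng.standard_normal(64)
        pad = 128
        cols = suffix_spectra(x, pad_len=pad)
        for u in range(64):
            np.testing.assert_allclose(
                cols[:, u], dft_mag_onesided(x[u:], pad), atol=1e-9
            )

    def test_pad_shorter_than_signal_rejected(self, rng):
        with pytest.raises(ValueError, match="pad"):
            prefix_spectra(rng.standard_normal(64), pad_len=32)


class TestFbft:
    def test_zero_signal_gives_zero_map(self):
        tf = fbft(np.zeros(32), fs=32.0)
        assert not tf.magnitude.any()

    def test_axes_conventions(self, rng):
        x = rng.standard_normal(40)
        tf = fbft(x, fs=100.0, pad_len=128)
        assert tf.magnitude.shape == (65, 40)
        np.testing.assert_allclose(tf.freqs, np.arange(65) * 100.0 / 128)
        np.testing.assert_allclose(tf.times, np.arange(40) / 100.0)
        assert tf.freqs[0] == 0.0 and tf.freqs[-1] == 50.0

    def test_is_pointwise_minimum_of_both_spectra(self, rng):
        x = rng.standard_normal(48)
        tf = fbft(x, fs=48.0, pad_len=128)
        fwd = prefix_spectra(x, 128)
        bwd = suffix_spectra(x, 128)
        np.testing.assert_array_equal(tf.magnitude, np.minimum(fwd, bwd))
        assert (tf.magnitude <= fwd + 1e-15).all()
        assert (tf.magnitude <= bwd + 1e-15).all()

    def test_full_record_sinusoid_peak_in_interior(self):
        fs, f0, n = 128.0, 16.0, 256
        x = np.sin(2 * np.pi * f0 * np.arange(n) / fs)
        tf = fbft(x, fs=fs)
        bin_w = tf.freqs[1] - tf.freqs[0]
        for u in range(int(0.1 * n) + 1, int(0.9 * n)):
            col = tf.magnitude[1:, u]
            f_peak = tf.freqs[1 + np.argmax(col)]
            assert abs(f_peak - f0) <= bin_w

    def test_impulse_closed_form(self):
        """A lone impulse at m survives the minimum only at u == m, as a flat spectrum."""
        n, m, amp = 32, 10, 2.5
        x = np.zeros(n)
        x[m] = amp
        tf = fbft(x, fs=32.0, pad_len=64)
        for u in range(n):
            # prefix holds the impulse iff u >= m, suffix iff u <= m;
            # the minimum is the flat |x[m]| spectrum only where both do
            expected = amp if u == m else 0.0
            np.testing.assert_allclose(tf.magnitude[:, u], expected, atol=1e-12)

    def test_minimal_two_sample_signal(self):
        tf = fbft(np.array([1.0, -1.0]), fs=2.0)
        assert tf.magnitude.shape[1] == 2
        assert np.isfinite(tf.magnitude).all()

    def test_normalize_divides_by_subarray_length(self, rng):
        x = rng.standard_normal(20)
        raw_f = prefix_spectra(x, 64)
        raw_b = suffix_spectra(x, 64)
        tf = fbft(x, fs=20.0, pad_len=64, normalize=True)
        lengths_f = np.arange(1, 21)
        lengths_b = 20 - np.arange(20)
        expected = np.minimum(raw_f / lengths_f, raw_b / lengths_b)
        np.testing.assert_allclose(tf.magnitude, expected, atol=1e-15)

    def test_signal_wrapper_selects_channel(self, small_signal):
        tf = fbft_signal(small_signal, channel="b", pad_len=512)
        np.testing.assert_array_equal(
            tf.magnitude, fbft(small_signal.channel("b"), 100.0, pad_len=512).magnitude
        )
        with pytest.raises(ValueError):
            fbft_signal(small_signal)


class TestReferenceEquivalence:
    def test_fast_path_equals_reference_on_random_signals(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(16, 257))
            x = rng.standard_normal(n)
            fast = fbft(x, fs=float(n), stride=1)
            ref = fbft_reference(x, fs=float(n))
            assert np.max(np.abs(fast.magnitude - ref.magnitude)) <= 1e-12
            np.testing.assert_array_equal(fast.freqs, ref.freqs)
            np.testing.assert_array_equal(fast.times, ref.times)

    def test_stride_restricts_to_same_columns(self, rng):
        x = rng.standard_normal(100)
        ref = fbft_reference(x, fs=100.0)
        for stride in (3, 7, 32):
            thinned = fbft(x, fs=100.0, stride=stride)
            grid = np.arange(0, 100, stride)
            if grid[-1] != 99:
                grid = np.append(grid, 99)
            np.testing.assert_allclose(
                thinned.magnitude, ref.magnitude[:, grid], atol=1e-12
            )
            np.testing.assert_allclose(thinned.times, grid / 100.0)


class TestProperties:
    def test_time_reversal_equivariance(self, rng):
        x = rng.standard_normal(64)
        a = fbft(x, fs=64.0, pad_len=256)
        b = fbft(x[::-1], fs=64.0, pad_len=256)
        np.testing.assert_allclose(b.magnitude, a.magnitude[:, ::-1], atol=1e-9)

    @given(c=st.floats(-100.0, 100.0, allow_nan=False))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_amplitude_linearity(self, c):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(48)
        base = fbft(x, fs=48.0, pad_len=128).magnitude
        scaled = fbft(c * x, fs=48.0, pad_len=128).magnitude
        np.testing.assert_allclose(scaled, abs(c) * base, rtol=1e-12, atol=1e-12)

    def test_shift_magnitude_invariance(self, rng):
        """|FFT| of a circularly shifted sequence equals the original |FFT|."""
        x = rng.standard_normal(128)
        for shift in (1, 17, 64):
            np.testing.assert_allclose(
                np.abs(np.fft.rfft(np.roll(x, shift))),
                np.abs(np.fft.rfft(x)),
                atol=1e-9,
            )

    def test_default_pad_len_is_power_of_two_at_least_double(self):
        for n, expected in [(2, 4), (3, 8), (64, 128), (65, 256), (1500, 4096)]:
            assert default_pad_len(n) == expected


class TestRidgeFrequency:
    def test_single_nonzero_row(self):
        mag = np.zeros((5, 4))
        mag[3] = 1.0
        tf = TFMap(mag, freqs=np.arange(5.0), times=np.arange(4.0))
        assert ridge_frequency(tf) == 3.0

    def test_pure_tone_within_one_bin(self):
        fs, f0 = 200.0, 10.0
        x = np.sin(2 * np.pi * f0 * np.arange(400) / fs)
        tf = fbft(x, fs=fs)
        bin_w = tf.freqs[1] - tf.freqs[0]
        assert ridge_frequency(tf) == pytest.approx(f0, abs=bin_w)

    def test_all_zero_map_yields_sentinel(self):
        tf = TFMap(np.zeros((5, 4)), freqs=np.arange(5.0), times=np.arange(4.0))
        assert ridge_frequency(tf) is None
        assert ridge_frequency(tf, top_k=3) == []

    def test_empty_interval_is_an_error(self):
        tf = TFMap(np.ones((3, 4)), freqs=np.arange(3.0), times=np.arange(4.0))
        with pytest.raises(ValueError):
            ridge_frequency(tf, t_start=10.0, t_end=20.0)

    def test_top_k_orders_by_prominence(self):
        mag = np.zeros((10, 2))
        mag[3] = 5.0
        mag[7] = 2.0
        tf = TFMap(mag, freqs=np.arange(10.0), times=np.arange(2.0))
        assert ridge_frequency(tf, top_k=2) == [3.0, 7.0]


class TestTFMapInvariants:
    def test_rejects_negative_magnitude(self):
        with pytest.raises(ValueError):
            TFMap(-np.ones((2, 2)), freqs=np.arange(2.0), times=np.arange(2.0))

    def test_rejects_non_increasing_axes(self):
        with pytest.raises(ValueError):
            TFMap(np.ones((2, 2)), freqs=np.array([1.0, 0.0]), times=np.arange(2.0))

    def test_rejects_shape_mismatch(self):
        with pytest.raises(ValueError):
            TFMap(np.ones((2, 3)), freqs=np.arange(2.0), times=np.arange(2.0))
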