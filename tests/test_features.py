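import numpy as np
import pytest
from scipy.signal import hilbert

from neowave import (EpochGrid, SharpnessParams, band_powers,
                     complex_envelope, degree_of_nonlinearity, detect_extrema,
                     energy_ratio, extract_features, rms, sharpness)
from neowave.errors import DataError
from neowave.features import peak_sharpness
from conftest import sine


class TestEnvelope:
    def test_constant_amplitude_tone(self, fs):
        assert complex_envelope(sine(3, fs, 1.0, amplitude=2.0)) == \
            pytest.approx(2.0, rel=0.02)

    def test_zero_signal(self):
        assert complex_envelope(np.zeros(256)) == 0.0

    def test_am_signal_tracks_modulator(self, fs):
        t = np.arange(int(4 * fs)) / fs
        modulator = 1 + 0.5 * np.cos(2 * np.pi * 0.5 * t)
        x = modulator * np.cos(2 * np.pi * 10 * t)
        step = int(fs)
        for i in range(4):
            got = complex_envelope(x[i * step:(i + 1) * step])
            want = np.median(modulator[i * step:(i + 1) * step])
            assert got == pytest.approx(want, rel=0.05)

    def test_scales_linearly(self, fs):
        x = sine(4, fs, 1.0)
        assert complex_envelope(3 * x) == pytest.approx(
            3 * complex_envelope(x), rel=1e-9)


class TestExtremaDetection:
    def test_sine_peaks_found_per_cycle(self, fs):
        x = sine(3, fs, 1.0)
        peaks = detect_extrema(x, SharpnessParams(both_polarities=False))
        true_maxima = [int(round(k * fs / 3)) for k in range(3)]
        interior = [p for p in true_maxima if 0 < p < len(x) - 1]
        assert len(peaks) >= len(interior) - 1
        for p in peaks:
            assert min(abs(p - m) for m in true_maxima) <= 2

    def test_monotone_ramp_has_no_extrema(self):
        x = np.linspace(0, 1, 300)
        assert len(detect_extrema(x)) == 0

    def test_scale_invariance(self, fs):
        rng = np.random.default_rng(0)
        x = sine(3, fs, 1.0) + 0.1 * rng.standard_normal(int(fs))
        np.testing.assert_array_equal(detect_extrema(x),
                                      detect_extrema(10 * x))

    def test_offset_invariance(self, fs):
        x = sine(3, fs, 1.0)
        np.testing.assert_array_equal(detect_extrema(x),
                                      detect_extrema(x + 100.0))

    def test_short_signal_rejected(self):
        with pytest.raises(DataError):
            detect_extrema(np.zeros(32), SharpnessParams(window_len=64))


class TestSharpness:
    def test_flank_arithmetic_is_exact(self):
        """Peak of 10 with flank voltages 6 and 4 at +/-7 ms scores (4+6)/2 = 5."""
        fs = 1000.0  # 7 ms == exactly 7 samples
        x = np.zeros(100)
        x[50] = 10.0
        x[43], x[57] = 6.0, 4.0
        vals = peak_sharpness(x, np.array([50]), fs, flank_ms=7.0)
        assert vals[0] == 5.0

    def test_peaked_wave_sharper_than_sine(self, fs):
        t = np.arange(int(2 * fs)) / fs
        u = np.cos(2 * np.pi * 4 * t)
        peaked = np.sign(u) * np.abs(u) ** 8
        assert sharpness(peaked, fs) > sharpness(u, fs)

    def test_offset_invariance(self, fs):
        x = sine(4, fs, 2.0) + 0.3 * sine(11, fs, 2.0)
        assert sharpness(x + 100.0, fs) == pytest.approx(
            sharpness(x, fs), rel=1e-9)

    def test_scales_linearly_with_amplitude(self, fs):
        x = sine(4, fs, 2.0) + 0.3 * sine(11, fs, 2.0)
        assert sharpness(5 * x, fs) == pytest.approx(
            5 * sharpness(x, fs), rel=1e-6)

    def test_no_extrema_flags_missing(self, fs):
        assert np.isnan(sharpness(np.linspace(0, 1, 300), fs))


class TestDegreeOfNonlinearity:
    def test_pure_sinusoid_is_linear(self, fs):
        assert degree_of_nonlinearity(sine(3, fs, 4.0), fs) < 0.02

    @pytest.mark.parametrize("eps", [0.1, 0.2, 0.3, 0.4])
    def test_recovers_modulation_depth(self, fs, eps):
        """DoN of cos(wt + eps sin wt) is eps/sqrt(2)."""
        t = np.arange(int(4 * fs)) / fs
        theta = 2 * np.pi * 3 * t
        x = np.cos(theta + eps * np.sin(theta))
        assert degree_of_nonlinearity(x, fs) == pytest.approx(
            eps / np.sqrt(2), rel=0.15)

    def test_linear_in_eps(self, fs):
        t = np.arange(int(4 * fs)) / fs
        theta = 2 * np.pi * 3 * t
        d2 = degree_of_nonlinearity(np.cos(theta + 0.2 * np.sin(theta)), fs)
        d4 = degree_of_nonlinearity(np.cos(theta + 0.4 * np.sin(theta)), fs)
        assert d4 == pytest.approx(2 * d2, rel=0.1)

    def test_amplitude_invariant(self, fs):
        t = np.arange(int(4 * fs)) / fs
        theta = 2 * np.pi * 3 * t
        x = np.cos(theta + 0.3 * np.sin(theta))
        assert degree_of_nonlinearity(7 * x, fs) == pytest.approx(
            degree_of_nonlinearity(x, fs), rel=1e-9)

    def test_no_crossings_flags_missing(self, fs):
        assert np.isnan(degree_of_nonlinearity(np.full(1024, 5.0), fs))


class TestBandPowers:
    def test_delta_tone(self, fs):
        bp = band_powers(sine(2, fs, 1.0), fs)
        assert bp[0] / bp.sum() > 0.9

    def test_beta_tone(self, fs):
        bp = band_powers(sine(20, fs, 1.0), fs)
        assert bp[3] / bp.sum() > 0.9

    def test_zero_signal(self, fs):
        np.testing.assert_array_equal(band_powers(np.zeros(256), fs), 0.0)


class TestEnergyRatio:
    def test_stated_formula(self):
        assert energy_ratio(np.array([5.0, 1.0, 1.0, 3.0, 1.0])) == 2.0

    def test_beta_tone_high(self, fs):
        assert energy_ratio(band_powers(sine(20, fs, 1.0), fs)) > 10

    def test_theta_tone_low(self, fs):
        assert energy_ratio(band_powers(sine(5, fs, 1.0), fs)) < 0.1

    def test_zero_denominator_flags_missing(self):
        assert np.isnan(energy_ratio(np.array([1.0, 0.0, 0.0, 1.0, 1.0])))


class TestRms:
    def test_unit_sine(self, fs):
        assert rms(sine(4, fs, 1.0)) == pytest.approx(1 / np.sqrt(2), rel=1e-6)

    def test_constant(self):
        assert rms(np.full(100, -3.0)) == 3.0

    def test_energy_additive_over_epochs(self, fs):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(256), rng.standard_normal(256)
        whole = rms(np.concatenate([a, b])) ** 2
        assert whole == pytest.approx((rms(a) ** 2 + rms(b) ** 2) / 2, rel=1e-9)


class TestExtractFeatures:
    def test_tidy_table_shape(self, small_recording):
        rec, _ = small_recording
        table = extract_features(rec, EpochGrid(1.0),
                                 channels=[rec.channel_labels[0]],
                                 features=("envelope", "rms"))
        assert set(table.columns) == {"channel", "epoch", "feature", "value"}
        assert len(table) == 2 * 60  # two features x 60 epochs
        assert table["epoch"].max() == 59

    def test_partial_final_epoch_dropped(self, fs):
        from neowave import Recording
        rec = Recording(np.random.default_rng(0)
                        .standard_normal((1, int(2.5 * fs))), fs, ["c"])
        table = extract_features(rec, EpochGrid(1.0), features=("rms",))
        assert table["epoch"].max() == 1
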