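import numpy as np
import pytest
from scipy.signal import butter, sosfreqz

from neowave import (PreprocessConfig, Recording, correct_out_of_range,
                     highpass_filter, notch_filter, pca_denoise, zscore)
from conftest import sine


def _rec(x, fs=256.0, label="C4-P4"):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return Recording(x, fs, [f"{label}{i}" if x.shape[0] > 1 else label
                             for i in range(x.shape[0])])


def _edge_trim(x, fs, seconds=1.0):
    n = int(seconds * fs)
    return x[n:-n]


class TestOutOfRange:
    def test_in_range_signal_untouched(self):
        rec = _rec(sine(5, 256, 2, amplitude=100))
        out = correct_out_of_range(rec, 200.0)
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_spike_on_ramp_restored_to_ramp(self):
        x = np.linspace(-50, 50, 500)
        x[250] = 500.0
        out = correct_out_of_range(_rec(x), 200.0)
        # monotone cubic interpolation of a line reproduces the line
        assert out.samples[0, 250] == pytest.approx(
            np.linspace(-50, 50, 500)[250], abs=1e-9)

    def test_edge_run_filled_with_nearest_valid(self):
        x = np.full(100, 10.0)
        x[:3] = 400.0
        out = correct_out_of_range(_rec(x), 200.0)
        np.testing.assert_allclose(out.samples[0, :3], 10.0)

    def test_mostly_bad_channel_flagged(self):
        x = np.full(100, 300.0)
        x[:10] = 0.0
        with pytest.warns(UserWarning, match="unusable"):
            out = correct_out_of_range(_rec(x), 200.0)
        assert out.meta["unusable_channels"] == ["C4-P4"]
        assert np.isfinite(out.samples).all()


class TestNotch:
    def test_mains_tone_removed(self, fs):
        x = sine(50, fs, 6)
        out = notch_filter(_rec(x, fs)).samples[0]
        assert np.sqrt(np.mean(_edge_trim(out, fs) ** 2)) < 0.05 / np.sqrt(2)

    def test_passband_preserved(self, fs):
        x = sine(10, fs, 6)
        out = notch_filter(_rec(x, fs)).samples[0]
        ratio = (np.sqrt(np.mean(_edge_trim(out, fs) ** 2))
                 / np.sqrt(np.mean(_edge_trim(x, fs) ** 2)))
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_zero_in_zero_out(self, fs):
        out = notch_filter(_rec(np.zeros(1024), fs))
        np.testing.assert_array_equal(out.samples, 0.0)


class TestHighpass:
    def test_dc_rejected(self, fs):
        x = sine(10, fs, 6) + 10.0
        out = highpass_filter(_rec(x, fs)).samples[0]
        assert abs(_edge_trim(out, fs).mean()) < 0.01

    def test_deep_stopband(self, fs):
        x = sine(0.1, fs, 30)
        out = highpass_filter(_rec(x, fs)).samples[0]
        trim = _edge_trim(out, fs, 10)
        assert np.sqrt(np.mean(trim ** 2)) < 0.01 / np.sqrt(2)

    def test_passband_flat_at_10hz(self, fs):
        x = sine(10, fs, 6)
        out = highpass_filter(_rec(x, fs)).samples[0]
        ratio = (np.sqrt(np.mean(_edge_trim(out, fs) ** 2))
                 / np.sqrt(np.mean(_edge_trim(x, fs) ** 2)))
        assert ratio == pytest.approx(1.0, abs=0.02)

    def test_butterworth_single_pass_half_power_at_cutoff(self, fs):
        cfg = PreprocessConfig()
        sos = butter(cfg.hp_order, cfg.hp_cutoff, btype="highpass",
                     fs=fs, output="sos")
        w, h = sosfreqz(sos, worN=[cfg.hp_cutoff], fs=fs)
        assert abs(h[0]) == pytest.approx(1 / np.sqrt(2), rel=1e-6)

    def test_zero_phase(self, fs):
        """Cross-correlation peak between input and output sits at lag 0."""
        rng = np.random.default_rng(0)
        x = np.convolve(rng.standard_normal(int(6 * fs)),
                        np.hamming(17), mode="same")  # band-limited noise
        out = highpass_filter(_rec(x, fs)).samples[0]
        a, b = _edge_trim(x, fs), _edge_trim(out, fs)
        lags = np.arange(-20, 21)
        xc = [np.dot(a[20 + l:len(a) - 20 + l], b[20:-20]) for l in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_linearity(self, fs):
        x = sine(4, fs, 4)
        y = sine(11, fs, 4)
        lhs = highpass_filter(_rec(2 * x + 3 * y, fs)).samples[0]
        rhs = (2 * highpass_filter(_rec(x, fs)).samples[0]
               + 3 * highpass_filter(_rec(y, fs)).samples[0])
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)


class TestZscore:
    def test_closed_form_population_sd(self):
        out = zscore(_rec([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out.samples[0],
                                   [-1.22474487, 0.0, 1.22474487])

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        rec = _rec(rng.standard_normal(1000))
        once = zscore(rec)
        twice = zscore(once)
        np.testing.assert_allclose(once.samples, twice.samples, atol=1e-12)

    def test_constant_channel_zeroed_and_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            out = zscore(_rec(np.full(100, 7.0)))
        np.testing.assert_array_equal(out.samples, 0.0)
        assert out.meta["constant_channels"] == ["C4-P4"]


class TestPca:
    def test_full_variance_is_identity(self):
        rng = np.random.default_rng(4)
        rec = Recording(rng.standard_normal((5, 400)), 256.0,
                        [f"c{i}" for i in range(5)])
        out = pca_denoise(rec, variance=1.0)
        np.testing.assert_allclose(out.samples, rec.samples, atol=1e-9)

    def test_identical_channels_need_one_component(self):
        x = np.sin(np.linspace(0, 20, 500))
        rec = Recording(np.vstack([x, x]), 256.0, ["a", "b"])
        out = pca_denoise(rec, variance=0.95)
        assert out.meta["pca"]["n_components"] == 1
        np.testing.assert_allclose(out.samples, rec.samples, atol=1e-9)

    def test_retained_variance_meets_threshold(self):
        rng = np.random.default_rng(5)
        rec = Recording(rng.standard_normal((18, 2000)), 256.0,
                        [f"c{i}" for i in range(18)])
        out = pca_denoise(rec, variance=0.95)
        x = rec.samples - rec.samples.mean(axis=1, keepdims=True)
        explained = 1 - np.var(x - (out.samples
                                    - out.samples.mean(axis=1, keepdims=True))
                               ).sum() / np.var(x).sum()
        assert out.meta["pca"]["retained_variance"] >= 0.95
        assert explained >= 0.94  # reconstruction matches the eigen accounting
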