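"""Wavelet denoising, thresholding rules, cardiac CWT, spike detection."""

import numpy as np
import pytest

from cordtrace import ValidationError
from cordtrace.config import DenoiseConfig, GeneratorConfig
from cordtrace import synth
from cordtrace.wavelet import (
    denoise,
    detect_spikes,
    detection_rule,
    estimate_sigma,
    extract_cardiac,
    hard_threshold,
    universal_threshold,
    ThresholdRule,
)
from conftest import make_noiseless


class TestSigmaEstimate:
    def test_mad_constant(self):
        # coefficients all at the 0.75-quantile of N(0,1) give sigma 1
        assert estimate_sigma(np.full(100, 0.6745)) == pytest.approx(1.0)

    def test_zero_band(self):
        assert estimate_sigma(np.zeros(10)) == 0.0

    def test_monte_carlo_consistency(self):
        x = np.random.default_rng(0).normal(0, 2.0, 100_000)
        assert 1.96 <= estimate_sigma(x) <= 2.04

    def test_empty_band_rejected(self):
        with pytest.raises(ValidationError):
            estimate_sigma(np.empty(0))


class TestUniversalThreshold:
    @pytest.mark.parametrize(
        "sigma,n,expected",
        [
            (1.0, 1, 0.0),
            (0.0, 12345, 0.0),
            (1.0, 1000, 3.7169221888498384),  # sqrt(2 ln 1000), 20-digit eval
            (2.5, 1000, 2.5 * 3.7169221888498384),
        ],
    )
    def test_closed_form(self, sigma, n, expected):
        assert universal_threshold(sigma, n) == pytest.approx(expected, abs=1e-12)

    def test_invalid_n(self):
        with pytest.raises(ValidationError):
            universal_threshold(1.0, 0)


class TestHardThreshold:
    def test_zero_threshold_is_identity(self):
        np.testing.assert_array_equal(hard_threshold(np.array([5.0]), 0.0), [5.0])

    def test_equality_maps_to_zero(self):
        assert hard_threshold(np.array([2.0]), 2.0)[0] == 0.0

    def test_elementwise_rule(self):
        out = hard_threshold(np.array([-3.0, 0.5, 2.0, -0.9]), 1.0)
        np.testing.assert_array_equal(out, [-3.0, 0.0, 2.0, 0.0])


class TestDenoise:
    def test_all_zero_signal(self):
        np.testing.assert_allclose(denoise(np.zeros(1024)), 0.0)

    @pytest.mark.parametrize("variant", ["swt", "dwt"])
    def test_zero_threshold_roundtrip(self, variant, rng):
        x = rng.normal(size=4096)
        params = DenoiseConfig(variant=variant)
        out = denoise(x, params, threshold_scale=0.0)
        assert np.abs(out - x).max() < 1e-6 * np.ptp(x)

    def test_pure_noise_suppression(self, rng):
        x = rng.normal(0, 1.0, 100_000)
        out = denoise(x)
        assert out.var() <= 0.15 * x.var()

    def test_scale_equivariance(self, rng):
        x = rng.normal(size=8192) + np.sin(np.linspace(0, 40, 8192))
        a = 7.5
        np.testing.assert_allclose(denoise(a * x), a * denoise(x), atol=1e-9)

    def test_embedded_ecap_peak_preserved(self, rng):
        """A strong evoked waveform survives denoising within 20%."""
        fs = 10_000.0
        wave, peak = synth.ECAPTemplate(amplitude_uV=50.0).sample(fs)
        x = np.zeros(20_000)
        x[10_000 : 10_000 + wave.size] = wave
        noisy = x + rng.normal(0, 2.0, x.size)
        out = denoise(noisy)
        k = 10_000 + peak
        assert abs(out[k - 3 : k + 4].max() - 50.0) <= 0.2 * 50.0

    def test_nan_rejected(self):
        x = np.zeros(1024)
        x[5] = np.nan
        with pytest.raises(ValidationError):
            denoise(x)


class TestExtractCardiac:
    def test_matched_pulse_peaks_at_center(self):
        fs = 1000.0
        t = (np.arange(2001) - 1000) / fs
        x = synth.ricker(t, 0.005)
        resp = extract_cardiac(x, fs, scale_ms=5.0)
        assert resp.size == x.size
        assert abs(int(np.argmax(resp)) - 1000) <= 2

    def test_zero_input_zero_output(self):
        np.testing.assert_allclose(extract_cardiac(np.zeros(500), 1000.0), 0.0, atol=1e-12)

    def test_ecg_train_beats_recovered(self):
        """Beat times of a 6-Hz ECG-like train are found within 2 ms."""
        cfg = make_noiseless(GeneratorConfig(sample_rate_hz=2000.0, duration_s=8.0))
        cfg.ecap_amplitude_uV = 0.0
        cfg.ecg_amplitude_uV = 20.0
        rec, _, truth = synth.simulate_session(cfg, seed=2)
        resp = extract_cardiac(rec.data[0], cfg.sample_rate_hz, scale_ms=cfg.ecg_width_ms)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(resp, height=0.5 * resp.max(), distance=100)
        peak_t = peaks / cfg.sample_rate_hz
        hits = sum(np.min(np.abs(peak_t - tb)) <= 0.002 for tb in truth.ecg_beat_times_s)
        assert hits >= 0.9 * truth.ecg_beat_times_s.size

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValidationError):
            extract_cardiac(np.zeros(100), 1000.0, scale_ms=0.0)


class TestDetectSpikes:
    def test_subthreshold_constant_gives_empty(self):
        rule = ThresholdRule(sigma=1.0, n_samples=100, threshold=5.0)
        assert detect_spikes(np.ones(100), 1000.0, rule) == []

    def test_refractory_keeps_larger_peak(self):
        """Two peaks 1 ms apart under a 4-ms refractory: larger one wins."""
        fs = 10_000.0
        x = np.zeros(1000)
        x[500] = 10.0
        x[510] = 8.0
        rule = ThresholdRule(sigma=1.0, n_samples=1000, threshold=5.0)
        spikes = detect_spikes(x, fs, rule, refractory_ms=4.0)
        assert len(spikes) == 1
        assert spikes[0].peak_time_s == pytest.approx(500 / fs)
        assert spikes[0].peak_amplitude_uV == 10.0

    def test_window_length_and_edge_flag(self):
        fs = 10_000.0
        x = np.zeros(100)
        x[5] = 10.0  # too close to the start for a full centred window
        rule = ThresholdRule(sigma=1.0, n_samples=100, threshold=5.0)
        (spike,) = detect_spikes(x, fs, rule, window_ms=4.0)
        assert spike.waveform.size == 40
        assert spike.edge

    def test_noiseless_session_recovery(self, tiny_noiseless):
        """Every event yields a spike at the true peak time on the hotspot channel."""
        rec, events, truth = synth.simulate_session(tiny_noiseless, seed=0)
        fs = rec.sample_rate
        for e in range(len(events)):
            ch = int(np.argmax(truth.clean_peak_uV[e]))
            rule = ThresholdRule(
                sigma=0.0, n_samples=rec.n_samples,
                threshold=0.5 * truth.clean_peak_uV[e, ch],
            )
            spikes = detect_spikes(rec.data[ch], fs, rule, refractory_ms=100.0)
            times = np.asarray([s.peak_time_s for s in spikes])
            err = np.min(np.abs(times - truth.peak_times_s[e])) * fs
            assert err <= 1.0

    def test_detection_rule_threshold_consistency(self, rng):
        x = rng.normal(0, 2.0, 50_000)
        rule = detection_rule(x)
        assert rule.threshold == pytest.approx(
            rule.sigma * np.sqrt(2 * np.log(x.size))
        )
        assert 1.9 <= rule.sigma <= 2.1
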