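"""VMC estimation chain: band-pass, comb, blanking, ARV, smoothing."""

import numpy as np
import pytest
from scipy.signal import sosfreqz

from mecfes import (
    BIN_LEN,
    ConfigurationError,
    EstimatorConfig,
    ShapeError,
    SignalTrace,
    VmcEnvelope,
    apply_blanking,
    arv,
    bandpass,
    comb_filter,
    estimate_vmc,
    expected_arv_factor,
    segment_bins,
    smooth,
    synthesize_emg,
)
from mecfes.signal_synth import FS, emg_band_sos
from mecfes.vmc_estimator import design_bandpass


def tone(freq, n_samples, amplitude=1.0):
    t = np.arange(n_samples) / FS
    return SignalTrace(samples=amplitude * np.sin(2 * np.pi * freq * t))


class TestBandpass:
    def test_dc_is_rejected(self, estimator_config):
        out = bandpass(SignalTrace(samples=np.ones(40 * BIN_LEN)), estimator_config)
        assert np.max(np.abs(out.samples[20 * BIN_LEN:])) <= 0.1

    @pytest.mark.parametrize("freq,lo,hi", [(100.0, 0.89, 1.12), (1000.0, 0.0, 0.5)])
    def test_tone_gain(self, estimator_config, freq, lo, hi):
        # oracle: the designed transfer function evaluated at the tone
        w, h = sosfreqz(design_bandpass(estimator_config), worN=[freq], fs=FS)
        expected = np.abs(h[0])
        assert lo <= expected <= hi
        out = bandpass(tone(freq, 100 * BIN_LEN), estimator_config)
        steady = out.samples[50 * BIN_LEN:]
        measured = np.sqrt(2.0) * steady.std()
        assert measured == pytest.approx(expected, abs=0.02)

    def test_corner_frequencies_at_minus_3db(self, estimator_config):
        w, h = sosfreqz(design_bandpass(estimator_config), worN=[16.0, 500.0], fs=FS)
        np.testing.assert_allclose(np.abs(h), 1 / np.sqrt(2), atol=0.01)

    def test_empty_trace_rejected(self, estimator_config):
        with pytest.raises(ShapeError):
            bandpass(SignalTrace(samples=np.zeros(0)), estimator_config)


class TestSegmentBins:
    def test_two_bins(self):
        bins = segment_bins(SignalTrace(samples=np.arange(240.0)))
        assert bins.shape == (2, BIN_LEN)

    def test_single_bin_is_identity(self):
        x = np.arange(120.0)
        bins = segment_bins(SignalTrace(samples=x))
        assert np.array_equal(bins[0], x)

    def test_concatenation_reproduces_trace(self, rng):
        x = rng.standard_normal(7 * BIN_LEN)
        bins = segment_bins(SignalTrace(samples=x))
        assert np.array_equal(bins.reshape(-1), x)


class TestCombFilter:
    def test_periodic_input_annihilated(self, rng):
        one = rng.standard_normal(BIN_LEN)
        bins = np.tile(one, (10, 1))
        out = comb_filter(bins)
        assert np.all(out == 0.0)

    def test_constant_bins_oracle(self):
        # direct subtraction oracle on bins of constants 0,1,2,3
        bins = np.outer([0.0, 1.0, 2.0, 3.0], np.ones(BIN_LEN))
        out = comb_filter(bins)
        np.testing.assert_array_equal(out[:, 0], [0.0, 1.0, 1.0, 1.0])

    def test_single_bin_becomes_zero(self, rng):
        out = comb_filter(rng.standard_normal((1, BIN_LEN)))
        assert np.all(out == 0.0)

    def test_disabled_returns_input(self, rng):
        bins = rng.standard_normal((5, BIN_LEN))
        assert np.array_equal(comb_filter(bins, enabled=False), bins)


class TestBlankingAndArv:
    def test_exactly_80_samples_retained(self, estimator_config, rng):
        retained = apply_blanking(rng.standard_normal(BIN_LEN), estimator_config)
        assert retained.shape == (80,)

    @pytest.mark.parametrize("window", [slice(0, 20), slice(70, 90), slice(80, 81)])
    def test_contamination_in_blanked_windows_invisible(self, estimator_config, window):
        bin_ = np.zeros(BIN_LEN)
        bin_[window] = 1e6
        assert np.all(apply_blanking(bin_, estimator_config) == 0.0)

    def test_arv_of_constant(self, estimator_config):
        assert arv(np.full(BIN_LEN, 3.5), estimator_config.retained_mask) == 3.5

    def test_arv_of_alternating_sign(self, estimator_config):
        bin_ = np.where(np.arange(BIN_LEN) % 2 == 0, 1.0, -1.0)
        assert arv(bin_, estimator_config.retained_mask) == 1.0

    def test_arv_of_gaussian_is_half_normal(self, estimator_config, rng):
        # Monte-Carlo oracle: many 80-sample Gaussian bins, sigma = 4
        sigma = 4.0
        vals = [arv(rng.normal(0, sigma, BIN_LEN), estimator_config.retained_mask)
                for _ in range(3000)]
        assert np.mean(vals) == pytest.approx(sigma * np.sqrt(2 / np.pi), rel=0.02)

    def test_empty_retained_set_rejected(self):
        with pytest.raises(ConfigurationError):
            arv(np.ones(BIN_LEN), np.zeros(BIN_LEN, dtype=bool))


class TestSmooth:
    def test_unity_dc_gain(self):
        cfg = EstimatorConfig(tau=1.0)
        out = smooth(np.full(200, 7.0), cfg)  # 12 s >> 10 tau
        assert out.values[-1] == pytest.approx(7.0, rel=1e-3)

    def test_step_reaches_63_percent_at_tau(self):
        cfg = EstimatorConfig(tau=1.0)
        out = smooth(np.ones(50), cfg)
        k = int(round(1.0 / 0.06)) - 1  # bin ending closest to t = 1 s
        assert out.values[k] == pytest.approx(1 - np.exp(-1), abs=0.02)

    def test_tiny_tau_is_passthrough(self, rng):
        cfg = EstimatorConfig(tau=0.001)
        x = rng.uniform(0, 5, 30)
        out = smooth(x, cfg)
        np.testing.assert_allclose(out.values, x, rtol=1e-10)


class TestEstimateVmc:
    def test_zero_trace_gives_zero_estimate(self, estimator_config):
        est = estimate_vmc(SignalTrace(samples=np.zeros(20 * BIN_LEN)), estimator_config)
        assert np.all(est.values == 0.0)

    def test_periodic_artifact_annihilated(self, rng):
        # quasi-stationary response, no EMG: estimate stays exactly zero
        cfg = EstimatorConfig(bandpass_enabled=False)
        one = np.zeros(BIN_LEN)
        one[20:60] = 500.0 * rng.standard_normal(40)
        est = estimate_vmc(SignalTrace(samples=np.tile(one, 50)), cfg)
        assert np.all(est.values == 0.0)

    def test_blanked_contamination_bit_exact_immunity(self, rng):
        # contamination confined to [0,20) u [70,90) never changes the
        # digital estimate (band-pass stage off: it would smear support)
        cfg = EstimatorConfig(bandpass_enabled=False)
        clean = rng.standard_normal(30 * BIN_LEN)
        dirty = clean.copy().reshape(-1, BIN_LEN)
        dirty[:, 0:20] += 1e5 * rng.standard_normal((30, 20))
        dirty[:, 70:90] += 1e5 * rng.standard_normal((30, 20))
        a = estimate_vmc(SignalTrace(samples=clean), cfg)
        b = estimate_vmc(SignalTrace(samples=dirty.reshape(-1)), cfg)
        assert np.array_equal(a.values, b.values)

    def test_composition_equals_manual_stages(self, estimator_config, rng):
        trace = SignalTrace(samples=rng.standard_normal(40 * BIN_LEN))
        est = estimate_vmc(trace, estimator_config)
        bins = segment_bins(bandpass(trace, estimator_config))
        combed = comb_filter(bins, estimator_config.comb_enabled)
        arvs = np.array([arv(b, estimator_config.retained_mask) for b in combed])
        manual = smooth(arvs, estimator_config)
        assert np.array_equal(est.values, manual.values)
        assert np.array_equal(est.arv_raw, manual.arv_raw)

    def test_clean_emg_steady_state_half_normal(self):
        # comb doubles the variance of stochastic EMG: reading = A*sqrt(4/pi)
        cfg = EstimatorConfig(bandpass_enabled=False)
        env = VmcEnvelope(values=np.full(500, 10.0), duration=30.0)
        est = estimate_vmc(synthesize_emg(env, 11), cfg)
        expected = 10.0 * np.sqrt(4.0 / np.pi)
        assert np.mean(est.values[200:]) == pytest.approx(expected, rel=0.07)

    def test_clean_emg_steady_state_with_bandpass(self):
        # independent frequency-domain oracle for the band-pass power loss
        cfg = EstimatorConfig()
        w, h_est = sosfreqz(design_bandpass(cfg), worN=4096, fs=FS)
        _, h_syn = sosfreqz(emg_band_sos(), worN=4096, fs=FS)
        p_syn = np.abs(h_syn) ** 2
        g = np.sqrt(np.trapezoid(p_syn * np.abs(h_est) ** 2, w)
                    / np.trapezoid(p_syn, w))
        env = VmcEnvelope(values=np.full(500, 10.0), duration=30.0)
        est = estimate_vmc(synthesize_emg(env, 11), cfg)
        expected = 10.0 * np.sqrt(4.0 / np.pi) * g
        assert np.mean(est.values[200:]) == pytest.approx(expected, rel=0.07)
        assert expected_arv_factor(cfg) * 10.0 == pytest.approx(expected, rel=1e-6)

    def test_monotone_scaling_doubles_estimate(self):
        env1 = VmcEnvelope(values=np.full(100, 10.0), duration=6.0)
        env2 = VmcEnvelope(values=np.full(100, 20.0), duration=6.0)
        e1 = estimate_vmc(synthesize_emg(env1, 13))
        e2 = estimate_vmc(synthesize_emg(env2, 13))
        np.testing.assert_allclose(e2.values[1:], 2.0 * e1.values[1:], rtol=1e-9)


class TestEstimatorConfig:
    def test_overlapping_blanking_rejected(self):
        with pytest.raises(ConfigurationError):
            EstimatorConfig(blank1=(0, 80), blank2=(70, 90))

    def test_out_of_bin_blanking_rejected(self):
        with pytest.raises(ConfigurationError):
            EstimatorConfig(blank2=(100, 130))

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ConfigurationError):
            EstimatorConfig(tau=0.0)
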