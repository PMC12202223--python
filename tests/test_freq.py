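"""Harmonic-model frequency tracking, quality index and gating."""

import numpy as np
import pytest

from fwavetilt.freq import (FrequencyTrend, analytic_signal, fit_harmonic_segment,
                            frequency_trend, phase_median_frequency, quality_index,
                            recording_gate, welch_anchor)


def harmonic_window(f, a1, a2, p1, p2, n=25, fs=50.0):
    k = np.arange(n)
    return (a1 * np.exp(1j * (2 * np.pi * f * k / fs + p1))
            + a2 * np.exp(1j * (2 * np.pi * 2 * f * k / fs + p2)))


class TestAnalyticSignal:
    def test_real_part_equals_input_and_energy_doubles(self):
        t = np.arange(30000) / 50.0
        x = np.cos(2 * np.pi * 7 * t) + 0.3 * np.cos(2 * np.pi * 9.1 * t + 1.0)
        xa = analytic_signal(x)
        assert np.allclose(xa.real, x)
        assert np.sum(np.abs(xa) ** 2) == pytest.approx(2 * np.sum(x ** 2), rel=0.01)

    def test_tone_phase_advances_at_frequency(self):
        t = np.arange(5000) / 50.0
        xa = analytic_signal(np.cos(2 * np.pi * 7 * t))
        inst = np.diff(np.unwrap(np.angle(xa))) * 50.0 / (2 * np.pi)
        assert np.allclose(inst[100:-100], 7.0, atol=0.01)


class TestWelchAnchor:
    def test_pure_tone(self):
        t = np.arange(6000) / 50.0
        assert welch_anchor(np.cos(2 * np.pi * 6.8 * t)) == pytest.approx(6.8, abs=0.1)

    def test_dominant_of_two_tones(self):
        t = np.arange(6000) / 50.0
        x = np.cos(2 * np.pi * 6.8 * t) + 0.3 * np.cos(2 * np.pi * 9 * t)
        assert welch_anchor(x) == pytest.approx(6.8, abs=0.1)

    def test_short_record_rejected(self):
        with pytest.raises(ValueError, match="60 s"):
            welch_anchor(np.zeros(1000))


class TestHarmonicFit:
    def test_exact_noiseless_recovery(self):
        fit = fit_harmonic_segment(harmonic_window(7.1, 1.0, 0.4, 0.3, -1.0),
                                   (5.6, 8.6))
        assert fit.f == pytest.approx(7.1, abs=1e-3)
        assert fit.a1 == pytest.approx(1.0, abs=1e-3)
        assert fit.a2 == pytest.approx(0.4, abs=1e-3)
        assert fit.phi1 == pytest.approx(0.3, abs=1e-3)
        assert fit.phi2 == pytest.approx(-1.0, abs=1e-3)

    def test_absent_harmonic_fitted_near_zero(self):
        fit = fit_harmonic_segment(harmonic_window(6.5, 1.0, 0.0, 0.0, 0.0),
                                   (5.0, 8.0))
        assert fit.a2 < 1e-2

    def test_noisy_recovery_within_tolerance(self, rng):
        errs = []
        for _ in range(60):
            f = rng.uniform(6.0, 7.5)
            w = harmonic_window(f, 1.0, 0.4, rng.uniform(-3, 3), rng.uniform(-3, 3))
            noise_sd = 10 ** (-10 / 20) / np.sqrt(2)  # 10 dB SNR on the fundamental
            w = w + noise_sd * (rng.standard_normal(25) + 1j * rng.standard_normal(25))
            errs.append(abs(fit_harmonic_segment(w, (5.2, 8.2)).f - f))
        assert np.median(errs) < 0.15

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_harmonic_segment(harmonic_window(7, 1, 0, 0, 0), (8.0, 8.0))


class TestFrequencyTrend:
    def test_constant_tone_trend(self):
        t = np.arange(3000) / 50.0
        xa = analytic_signal(np.cos(2 * np.pi * 7 * t))
        trend, _ = frequency_trend(xa, 7.0)
        assert trend.f.size == 3000
        assert np.allclose(trend.f[trend.valid], 7.0, atol=0.01)
        # first/last 0.25 s marked invalid
        assert not trend.valid[:12].any() and not trend.valid[-12:].any()

    def test_tracks_modulated_truth_noiseless(self):
        fs = 50.0
        t = np.arange(6000) / fs
        f_true = 6.7 + 0.08 * np.sin(2 * np.pi * 0.14 * t)
        phase = 2 * np.pi * np.cumsum(f_true) / fs
        xa = analytic_signal(np.cos(phase) + 0.35 * np.cos(2 * phase + 1.0))
        trend, _ = frequency_trend(xa, 6.7)
        err = np.abs(trend.f[trend.valid] - f_true[trend.valid])
        assert err.max() < 0.01

    def test_valid_samples_respect_constraint(self, single_phase):
        from fwavetilt import preprocess
        from fwavetilt.freq import estimate_frequency_trend

        record, _ = single_phase
        beats = preprocess.classify_ectopic(record, preprocess.detect_beats(record))
        fsig = preprocess.resample_to_50hz(
            preprocess.cancel_qrst(record, beats, "V1"), record.fs)
        trend = estimate_frequency_trend(fsig)
        f = trend.f[trend.valid]
        assert np.all(f >= trend.f0 - 1.5 - 1e-9)
        assert np.all(f <= trend.f0 + 1.5 + 1e-9)


class TestQualityIndex:
    def test_perfect_and_null_reconstruction(self):
        t = np.arange(500) / 50.0
        xa = analytic_signal(np.cos(2 * np.pi * 7 * t))
        s, valid = quality_index(xa, xa.copy())
        assert np.allclose(s, 1.0)
        assert valid.all()
        s0, valid0 = quality_index(xa, np.zeros_like(xa))
        assert np.allclose(s0, 0.0, atol=1e-9)
        assert not valid0.any()

    def test_noise_never_increases_s(self, rng):
        t = np.arange(1000) / 50.0
        xa = analytic_signal(np.cos(2 * np.pi * 7 * t))
        recon = xa * 0.9
        s_clean, _ = quality_index(xa, recon)
        for sd in (0.1, 0.3, 1.0):
            noisy = xa + sd * (rng.standard_normal(xa.size)
                               + 1j * rng.standard_normal(xa.size))
            s_noisy, _ = quality_index(noisy, recon)
            assert np.all(s_noisy <= s_clean + 1e-12)

    def test_zero_variance_block_warns(self):
        xa = np.zeros(500, dtype=complex)
        with pytest.warns(UserWarning, match="zero-variance"):
            s, valid = quality_index(xa, np.zeros_like(xa))
        assert np.isnan(s[0]) and not valid.any()


class TestGatesAndMedians:
    def test_recording_gate_boundary(self):
        good, bad = 0.8, 0.1
        assert recording_gate(np.array([good] * 90 + [bad] * 10))
        assert not recording_gate(np.array([good] * 89 + [bad] * 11))
        assert recording_gate(np.array([good] * 5))

    def test_phase_median(self):
        f = np.full(9000, 6.7)
        trend = FrequencyTrend(f=f, valid=np.ones(9000, bool),
                               s_blocks=np.ones(3), f0=6.7)
        assert phase_median_frequency(trend, (0.0, 180.0)) == pytest.approx(6.7)
        t = np.arange(9000) / 50.0
        trend.f = 6.7 + 0.08 * np.sin(2 * np.pi * 0.14 * t)
        # median of a symmetric oscillation over (nearly) whole cycles
        assert phase_median_frequency(trend, (0.0, 178.6)) == pytest.approx(6.7, abs=0.002)

    def test_insufficient_valid_fraction_missing(self):
        valid = np.zeros(9000, bool)
        valid[:4000] = True
        trend = FrequencyTrend(f=np.full(9000, 6.7), valid=valid,
                               s_blocks=np.ones(3), f0=6.7)
        with pytest.warns(UserWarning, match="valid"):
            assert np.isnan(phase_median_frequency(trend, (0.0, 180.0)))


class TestShiftEquivariance:
    @pytest.mark.parametrize("delta", [-0.5, 0.25])
    def test_fundamental_shift_shifts_trend(self, delta):
        fs = 50.0
        t = np.arange(3000) / fs
        meds = []
        for f0 in (6.7, 6.7 + delta):
            xa = analytic_signal(np.cos(2 * np.pi * f0 * t))
            trend, _ = frequency_trend(xa, 6.7)
            meds.append(np.median(trend.f[trend.valid]))
        assert meds[1] - meds[0] == pytest.approx(delta, abs=1e-3)
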