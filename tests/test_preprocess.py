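"""Beat detection, ectopic classification, QRST cancellation, resampling."""

import numpy as np
import pytest

from fwavetilt.preprocess import (BeatSet, ECGRecord, cancel_qrst,
                                  classify_ectopic, detect_beats,
                                  mean_heart_rate, resample_to_50hz)
from fwavetilt.synthetic import (FWaveGenParams, PhaseSpec, VentricularGenParams,
                                 generate_phase_recording)


def _record(samples, fs=500.0, leads=("V1",), duration=None):
    samples = np.atleast_2d(samples)
    dur = duration or samples.shape[1] / fs
    return ECGRecord(samples=samples, fs=fs, lead_names=list(leads),
                     timeline=[("B1", 0.0, dur)])


class TestDetectBeats:
    def test_regular_rhythm_rr_recovered(self):
        phase = PhaseSpec("B1", 60.0,
                          fwave=FWaveGenParams(noise_sd=0.0, mod_amplitude=0.0,
                                               drift_sd=0.0),
                          ventricular=VentricularGenParams(mean_hr=90.0, rr_cv=0.0,
                                                           ectopic_rate=0.0))
        record, _ = generate_phase_recording(phase, seed=0)
        r = detect_beats(record)
        rr = np.diff(r) / record.fs * 1000
        assert np.all(np.abs(rr - 666.7) <= 2.0)

    def test_matches_truth_on_default_noise(self, short_tilt):
        record, truth = short_tilt
        det_t = detect_beats(record) / record.fs
        matched = sum(np.min(np.abs(det_t - bt)) <= 0.020 for bt in truth.beat_times)
        assert matched / truth.beat_times.size >= 0.99

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError, match="10 s"):
            detect_beats(_record(np.zeros((1, 2500))))
        with pytest.raises(ValueError, match="no beats"):
            detect_beats(_record(np.zeros((1, 30000))))


class TestClassifyEctopic:
    def test_sensitivity_specificity_on_generator_truth(self):
        phase = PhaseSpec("B1", 300.0,
                          ventricular=VentricularGenParams(ectopic_rate=0.05))
        record, truth = generate_phase_recording(phase, seed=21)
        beats = classify_ectopic(record, detect_beats(record))
        det_t = beats.r_times
        idx = np.array([np.argmin(np.abs(truth.beat_times - t)) for t in det_t])
        true_lab = truth.ectopic[idx]
        sens = (beats.ectopic & true_lab).sum() / max(true_lab.sum(), 1)
        spec = (~beats.ectopic & ~true_lab).sum() / max((~true_lab).sum(), 1)
        assert sens >= 0.9
        assert spec >= 0.98

    def test_clean_regular_record_no_flags(self):
        phase = PhaseSpec("B1", 60.0,
                          fwave=FWaveGenParams(noise_sd=0.0, a1=0.01, a2=0.0,
                                               mod_amplitude=0.0, drift_sd=0.0),
                          ventricular=VentricularGenParams(rr_cv=0.0,
                                                           ectopic_rate=0.0,
                                                           resp_morph_gain=0.0))
        record, _ = generate_phase_recording(phase, seed=0)
        beats = classify_ectopic(record, detect_beats(record))
        assert not beats.ectopic.any()
        assert np.all(beats.correlation > 0.99)

    def test_insufficient_beats_raise(self, short_tilt):
        record, _ = short_tilt
        with pytest.raises(ValueError, match="insufficient beats"):
            classify_ectopic(record, np.arange(5) * 300)


class TestCancelQRST:
    def test_ventricular_only_residual_small(self):
        phase = PhaseSpec("B1", 120.0,
                          fwave=FWaveGenParams(a1=1e-6, a2=0.0, noise_sd=0.0,
                                               mod_amplitude=0.0, drift_sd=0.0))
        record, _ = generate_phase_recording(phase, seed=3)
        beats = classify_ectopic(record, detect_beats(record))
        residual = cancel_qrst(record, beats, "V1")
        assert np.std(residual) < 0.05 * np.std(record.lead("V1"))

    def test_empty_beatset_is_identity(self):
        x = np.sin(2 * np.pi * 6.7 * np.arange(30000) / 500.0)
        record = _record(x)
        beats = BeatSet(r_peaks=np.array([], dtype=int),
                        ectopic=np.array([], dtype=bool), templates={},
                        correlation=np.array([]), fs=500.0)
        assert np.array_equal(cancel_qrst(record, beats, "V1"), x)

    def test_residual_keeps_fwave_spectral_peak(self, single_phase):
        from scipy.signal import welch

        record, truth = single_phase
        beats = classify_ectopic(record, detect_beats(record))
        residual = cancel_qrst(record, beats, "V1")
        f, pxx = welch(residual, fs=record.fs, nperseg=8192)
        sel = (f >= 4) & (f <= 12)
        peak = f[sel][np.argmax(pxx[sel])]
        assert peak == pytest.approx(6.7, abs=0.3)

    def test_linearity_in_record_amplitude(self, single_phase):
        record, _ = single_phase
        beats = classify_ectopic(record, detect_beats(record))
        r1 = cancel_qrst(record, beats, "V1")
        scaled = ECGRecord(samples=record.samples * 2.5, fs=record.fs,
                           lead_names=record.lead_names, timeline=record.timeline)
        beats2 = BeatSet(r_peaks=beats.r_peaks, ectopic=beats.ectopic,
                         templates={k: 2.5 * v for k, v in beats.templates.items()},
                         correlation=beats.correlation, fs=beats.fs)
        r2 = cancel_qrst(scaled, beats2, "V1")
        assert np.allclose(r2, 2.5 * r1, atol=1e-8)


class TestResample:
    def test_inband_tone_preserved(self):
        t = np.arange(100000) / 1000.0
        y = resample_to_50hz(np.cos(2 * np.pi * 7 * t), 1000.0)
        assert y.fs == 50.0
        amp = np.sqrt(2) * np.std(y.x[200:-200])
        assert amp == pytest.approx(1.0, rel=0.01)

    def test_out_of_band_tone_attenuated(self):
        t = np.arange(100000) / 1000.0
        y = resample_to_50hz(np.cos(2 * np.pi * 30 * t), 1000.0)
        att_db = 20 * np.log10(max(np.sqrt(2) * np.std(y.x[200:-200]), 1e-12))
        assert att_db <= -40.0

    def test_length_contract(self):
        y = resample_to_50hz(np.zeros(900 * 1000), 1000.0)
        assert y.x.size == 45000
        y = resample_to_50hz(np.zeros(45000), 500.0)
        assert y.x.size == 4500

    def test_low_source_rate_rejected(self):
        with pytest.raises(ValueError):
            resample_to_50hz(np.zeros(1000), 80.0)


class TestMeanHeartRate:
    def _beats(self, times_s, ectopic, fs=500.0):
        r = (np.asarray(times_s) * fs).astype(int)
        return BeatSet(r_peaks=r, ectopic=np.asarray(ectopic, bool),
                       templates={}, correlation=np.ones(r.size), fs=fs)

    def test_constant_rr(self):
        beats = self._beats(np.arange(50) * 0.6, np.zeros(50))
        assert mean_heart_rate(beats, (0.0, 30.0)) == pytest.approx(100.0)

    def test_ectopic_adjacent_intervals_dropped(self):
        ect = np.zeros(50, bool)
        ect[20] = True
        beats = self._beats(np.arange(50) * 0.6, ect)
        assert mean_heart_rate(beats, (0.0, 30.0)) == pytest.approx(100.0)

    def test_too_few_beats_missing(self):
        beats = self._beats([0.5], [False])
        with pytest.warns(UserWarning, match="fewer than 2"):
            assert np.isnan(mean_heart_rate(beats, (0.0, 30.0)))

    def test_recovers_generator_rate(self, single_phase):
        record, truth = single_phase
        beats = classify_ectopic(record, detect_beats(record))
        fhr = mean_heart_rate(beats, (0.0, 180.0))
        assert fhr == pytest.approx(truth.per_phase["B1"]["fhr"], abs=2.0)
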