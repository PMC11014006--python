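"""Generator contracts: RR statistics, waveform morphology, noise, cohorts."""

import numpy as np
import pytest
from scipy.signal import periodogram
from scipy.stats import mannwhitneyu

import hfwave as hw
from hfwave.ecg_features import detect_r_peaks, hrv_time_domain
from hfwave.errors import InvalidParameterError, ResolutionError
from hfwave.ppg_features import detect_ppg_fiducials
from hfwave.records import SubjectParameters


class TestGenerateRrSeries:
    def test_zero_variability_limit_gives_constant_series(self):
        params = SubjectParameters(mean_hr=60.0, sdnn_target=0.0)
        rr = hw.generate_rr_series(params, 120.0)
        assert np.all(rr == 1000.0)

    def test_recovered_sdnn_matches_target(self):
        # oracle: the HRV summary definition applied to the emitted series
        params = SubjectParameters(mean_hr=60.0, sdnn_target=50.0,
                                   pnn50_target=0.10, seed=5)
        rr = hw.generate_rr_series(params, 600.0)
        summary = hrv_time_domain(rr)
        assert summary.sdnn == pytest.approx(50.0, rel=0.15)

    def test_mean_rr_matches_heart_rate(self):
        params = SubjectParameters(mean_hr=72.0, sdnn_target=60.0, seed=9)
        rr = hw.generate_rr_series(params, 240.0)
        assert np.mean(rr) == pytest.approx(60000.0 / 72.0, rel=0.02)
        assert np.cumsum(rr)[-1] <= 240_000.0

    def test_seed_determinism(self):
        params = SubjectParameters(mean_hr=80.0, sdnn_target=40.0, seed=11)
        a = hw.generate_rr_series(params, 300.0)
        b = hw.generate_rr_series(params, 300.0)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("duration", [0.0, -5.0])
    def test_nonpositive_duration_rejected(self, duration):
        with pytest.raises(InvalidParameterError):
            hw.generate_rr_series(SubjectParameters(), duration)

    def test_nonpositive_heart_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            SubjectParameters(mean_hr=0.0)


class TestSynthesizeEcg:
    def test_null_morphology_is_constant_zero(self):
        params = SubjectParameters(p_amplitude=0.0, qrs_amplitude=0.0, t_amplitude=0.0)
        rec = hw.synthesize_ecg([800.0, 800.0, 800.0], params)
        assert np.all(rec.samples == 0.0)

    def test_true_r_positions_at_cumulative_rr(self):
        rec = hw.synthesize_ecg([1000.0, 1000.0, 1000.0], SubjectParameters(), fs=125.0)
        np.testing.assert_array_equal(rec.truth.r_positions, [125, 250, 375])

    def test_noise_free_roundtrip_with_r_detector(self, clean_params):
        rr = hw.generate_rr_series(clean_params, 120.0)
        rec = hw.synthesize_ecg(rr, clean_params)
        detected = detect_r_peaks(rec).r_indices
        truth = rec.truth.r_positions
        assert detected.size == truth.size
        assert np.max(np.abs(detected - truth)) <= 2

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ResolutionError):
            hw.synthesize_ecg([800.0], SubjectParameters(qrs_duration=0.08), fs=20.0)

    def test_empty_rr_rejected(self):
        with pytest.raises(InvalidParameterError):
            hw.synthesize_ecg([], SubjectParameters())


class TestSynthesizePpg:
    def test_pulse_amplitude_by_construction(self):
        params = SubjectParameters(ppg_pulse_amplitude=0.8, ppg_diastolic_level=0.2,
                                   augmentation_fraction=0.0)
        rec = hw.synthesize_ppg([900.0] * 20, params)
        x = rec.samples
        feet = rec.truth.foot_positions
        spans = [x[feet[i]:feet[i + 1]] for i in range(len(feet) - 1)]
        for seg in spans:
            assert seg.max() - seg.min() == pytest.approx(0.8, rel=0.01)

    def test_feet_at_cumulative_rr(self):
        rec = hw.synthesize_ppg([1000.0, 1000.0, 1000.0], SubjectParameters(), fs=125.0)
        np.testing.assert_array_equal(rec.truth.foot_positions, [125, 250, 375])

    def test_noise_free_fiducial_roundtrip(self, clean_params):
        rr = hw.generate_rr_series(clean_params, 120.0)
        rec = hw.synthesize_ppg(rr, clean_params)
        beats = detect_ppg_fiducials(rec)
        truth_peaks = rec.truth.peak_positions
        # match each true peak to the nearest detection
        for tp in truth_peaks[1:-1]:
            assert np.min(np.abs(beats.sys_peaks - tp)) <= 2
        for tf in rec.truth.foot_positions[1:-1]:
            assert np.min(np.abs(beats.feet - tf)) <= 2


class TestAddNoise:
    def test_zero_amplitudes_identity(self):
        params = SubjectParameters(noise_levels=(0.0, 0.0, 0.0))
        rec = hw.synthesize_ecg([800.0] * 5, params)
        out = hw.add_noise(rec, params)
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_powerline_peak_in_periodogram(self):
        params = SubjectParameters(noise_levels=(0.5, 0.0, 0.0), mains_freq=50.0)
        rec = hw.synthesize_ecg([800.0] * 60, params)
        out = hw.add_noise(rec, params)
        freqs, power = periodogram(out.samples, fs=rec.fs)
        band = (freqs > 45) & (freqs < 55)
        peak_freq = freqs[band][np.argmax(power[band])]
        assert peak_freq == pytest.approx(50.0, abs=0.5)

    def test_seeded_reproducibility(self):
        params = SubjectParameters(noise_levels=(0.1, 0.1, 0.05), seed=3)
        rec = hw.synthesize_ecg([800.0] * 10, params)
        a = hw.add_noise(rec, params).samples
        b = hw.add_noise(rec, params).samples
        np.testing.assert_array_equal(a, b)


class TestGenerateCohort:
    def test_counts_and_pairing(self):
        subjects = hw.generate_cohort(3, 4, 1, duration=240.0)
        assert len(subjects) == 7
        assert sum(s.label == "HF" for s in subjects) == 3
        for s in subjects:
            assert s.ecg.samples.size == s.ppg.samples.size
            assert s.ecg.duration >= 240.0

    def test_all_control_when_no_hf(self):
        subjects = hw.generate_cohort(0, 3, 1, duration=240.0)
        assert all(s.label == "control" for s in subjects)

    def test_master_seed_reproducibility(self):
        a = hw.generate_cohort(2, 2, 42, duration=240.0)
        b = hw.generate_cohort(2, 2, 42, duration=240.0)
        for s, t in zip(a, b):
            np.testing.assert_array_equal(s.ecg.samples, t.ecg.samples)
            np.testing.assert_array_equal(s.ppg.samples, t.ppg.samples)
            assert s.params == t.params

    def test_label_separation_in_key_features(self):
        # HF and control distributions must differ in location for SDNN,
        # QRS duration and augmentation index
        # 260 s keeps every fragment above the strict 30,000-point minimum
        matrix, _ = hw.extract_cohort_features(
            hw.iter_cohort(100, 100, 314, duration=260.0))
        hf = matrix.data[matrix.labels == "HF"]
        ctl = matrix.data[matrix.labels == "control"]
        for col in ("sdnn", "qrs_interval", "augmentation_index"):
            p = mannwhitneyu(hf[col], ctl[col]).pvalue
            assert p < 1e-6, f"no location difference in {col}"
        assert hf["sdnn"].mean() < ctl["sdnn"].mean()
        assert hf["qrs_interval"].mean() > ctl["qrs_interval"].mean()
        assert hf["augmentation_index"].mean() > ctl["augmentation_index"].mean()
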