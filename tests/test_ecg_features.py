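"""ECG fiducials, interval features, time-domain HRV, risk stratification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hfwave as hw
from hfwave.ecg_features import EcgBeats
from hfwave.errors import (ContractViolationError, InsufficientDataError,
                           InvalidParameterError)
from hfwave.records import SubjectParameters


def brute_force_hrv(rr):
    """Independent literal transcription of the time-domain definitions."""
    rr = list(map(float, rr))
    n = len(rr)
    mean = sum(rr) / n
    sdnn = (sum((v - mean) ** 2 for v in rr) / (n - 1)) ** 0.5
    diffs = [rr[i + 1] - rr[i] for i in range(n - 1)]
    rmssd = (sum(d * d for d in diffs) / len(diffs)) ** 0.5
    nn50 = sum(1 for d in diffs if abs(d) > 50.0)
    return mean, sdnn, rmssd, nn50, 100.0 * nn50 / len(diffs)


class TestDetectRPeaks:
    def test_regular_rhythm_spacing(self, clean_params):
        rr = hw.generate_rr_series(
            SubjectParameters(mean_hr=60.0, sdnn_target=0.0), 120.0)
        rec = hw.synthesize_ecg(rr, clean_params, fs=125.0)
        beats = hw.detect_r_peaks(rec)
        spacing = np.diff(beats.r_indices)
        assert np.all(np.abs(spacing - 125) <= 2)

    def test_flat_record_gives_no_detections(self):
        rec = hw.synthesize_ecg(
            [800.0] * 5, SubjectParameters(p_amplitude=0.0, qrs_amplitude=0.0,
                                           t_amplitude=0.0))
        beats = hw.detect_r_peaks(rec)
        assert beats.r_indices.size == 0
        assert beats.warning == "no_peaks"

    def test_moderate_noise_does_not_change_count(self, clean_params):
        # high-frequency noise sd at 10% of the QRS amplitude
        rr = hw.generate_rr_series(clean_params, 120.0)
        clean = hw.synthesize_ecg(rr, clean_params)
        noisy_params = SubjectParameters(
            mean_hr=clean_params.mean_hr, noise_levels=(0.0, 0.0, 0.1),
            seed=clean_params.seed)
        noisy = hw.preprocess_record(hw.add_noise(clean, noisy_params))
        assert hw.detect_r_peaks(noisy).r_indices.size == \
            hw.detect_r_peaks(clean).r_indices.size

    def test_strictly_increasing_invariant(self, clean_params):
        rr = hw.generate_rr_series(clean_params, 120.0)
        beats = hw.detect_r_peaks(hw.synthesize_ecg(rr, clean_params))
        assert np.all(np.diff(beats.r_indices) > 0)
        assert np.min(np.diff(beats.r_indices)) >= int(0.2 * 125)


class TestDelineateWaves:
    def test_qrs_width_recovery(self, clean_params):
        rr = hw.generate_rr_series(clean_params, 120.0)
        params = SubjectParameters(mean_hr=60.0, qrs_duration=0.10, seed=1)
        rec = hw.synthesize_ecg(rr, params)
        beats = hw.delineate_waves(rec, hw.detect_r_peaks(rec))
        assert 0.08 <= np.nanmean(beats.qrs_durations) <= 0.12

    def test_absent_p_marked_not_dropped(self, clean_params):
        rr = hw.generate_rr_series(clean_params, 60.0)
        params = SubjectParameters(p_amplitude=0.0)
        rec = hw.synthesize_ecg(rr, params)
        beats = hw.delineate_waves(rec, hw.detect_r_peaks(rec))
        assert beats.p_amplitudes.size == beats.r_indices.size
        assert np.all(np.isnan(beats.p_amplitudes))

    def test_p_duration_recovery_noise_free(self):
        params = SubjectParameters(mean_hr=65.0, sdnn_target=30.0,
                                   p_duration=0.10, seed=8)
        rr = hw.generate_rr_series(params, 120.0)
        rec = hw.synthesize_ecg(rr, params)
        beats = hw.delineate_waves(rec, hw.detect_r_peaks(rec))
        assert np.nanmean(beats.p_durations) == pytest.approx(0.10, rel=0.20)

    def test_amplitude_scale_invariance_of_intervals(self, clean_params):
        rr = hw.generate_rr_series(clean_params, 60.0)
        rec = hw.synthesize_ecg(rr, clean_params)
        scaled = rec.with_samples(rec.samples * 3.7)
        a = hw.delineate_waves(rec, hw.detect_r_peaks(rec))
        b = hw.delineate_waves(scaled, hw.detect_r_peaks(scaled))
        np.testing.assert_array_equal(a.r_indices, b.r_indices)
        np.testing.assert_allclose(a.qrs_durations, b.qrs_durations, atol=1e-9)


class TestRrIntervals:
    def test_regular_indices(self):
        beats = EcgBeats(r_indices=np.array([0, 125, 250]), fs=125.0)
        np.testing.assert_allclose(hw.rr_intervals(beats), [1000.0, 1000.0])

    def test_single_peak_errors(self):
        with pytest.raises(InsufficientDataError):
            hw.rr_intervals(EcgBeats(r_indices=np.array([5]), fs=125.0))

    def test_non_monotone_indices_rejected(self):
        with pytest.raises(ContractViolationError):
            EcgBeats(r_indices=np.array([10, 5, 20]), fs=125.0)


class TestHrvTimeDomain:
    def test_worked_example(self):
        # successive differences 60, -40, 80 -> two exceed 50 ms
        s = hw.hrv_time_domain([800.0, 860.0, 820.0, 900.0])
        assert s.nn50 == 2
        assert s.pnn50 == pytest.approx(66.7, abs=0.05)
        assert s.rmssd == pytest.approx(62.18, abs=0.05)

    def test_constant_series_zero_variability(self):
        s = hw.hrv_time_domain([900.0] * 10)
        assert (s.sdnn, s.rmssd, s.nn50) == (0.0, 0.0, 0)

    def test_heart_rate_identity(self):
        s = hw.hrv_time_domain([1000.0] * 5)
        assert s.heart_rate == 60.0
        assert s.heart_rate == pytest.approx(60000.0 / s.mean_rr)

    def test_too_few_intervals_error(self):
        with pytest.raises(InsufficientDataError):
            hw.hrv_time_domain([800.0])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=300.0, max_value=2000.0),
                    min_size=2, max_size=60))
    def test_matches_brute_force_oracle(self, rr):
        s = hw.hrv_time_domain(rr)
        mean, sdnn, rmssd, nn50, pnn50 = brute_force_hrv(rr)
        assert s.mean_rr == pytest.approx(mean)
        assert s.sdnn == pytest.approx(sdnn, abs=1e-9)
        assert s.rmssd == pytest.approx(rmssd, abs=1e-9)
        assert s.nn50 == nn50
        assert s.pnn50 == pytest.approx(pnn50)
        assert 0.0 <= s.pnn50 <= 100.0
        assert s.nn50 <= len(rr) - 1


class TestClassifyHrvRisk:
    @pytest.mark.parametrize("sdnn,pnn50,expected", [
        (40.0, 10.0, "high"),
        (75.0, 10.0, "moderate"),
        (120.0, 10.0, "normal"),
        (120.0, 2.0, "high"),   # low pNN50 dominates
        (100.0, 10.0, "moderate"),  # band edge belongs to moderate
    ])
    def test_threshold_rule(self, sdnn, pnn50, expected):
        assert hw.classify_hrv_risk(sdnn, pnn50) == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            hw.classify_hrv_risk(-1.0, 10.0)
        with pytest.raises(InvalidParameterError):
            hw.classify_hrv_risk(60.0, 150.0)
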