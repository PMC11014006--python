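"""Synthetic two-channel (ECG + PPG) cohort generation.

The generator realizes the statistical structure the analysis assumes so that
every downstream stage can be validated without access to credentialed
bedside-monitor data:

* beat-to-beat RR series from an AR(1)-perturbed Gaussian process whose two
  free knobs map one-to-one onto SDNN (marginal dispersion) and pNN50
  (dispersion of successive differences);
* ECG morphology as a sum of smooth raised-cosine kernels per beat (P, QRS
  and T waves), so every fiducial is analytically known;
* PPG morphology as a primary systolic lobe plus a delayed reflected lobe
  scaled by the augmentation fraction, riding on a diastolic baseline;
* the three classical contamination sources: mains interference at 50/60 Hz,
  sub-0.5 Hz baseline wander, and broadband high-frequency muscle noise.

Heart-failure subjects are drawn from distributions shifted outside the
normal adult ranges (low SDNN/pNN50, prolonged QRS, reduced pulse amplitude,
elevated wave reflection); controls are drawn inside them. The shifts are
distributional, so the two classes overlap and classification is non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri

from .errors import InvalidParameterError, ResolutionError
from .records import DEFAULT_FS, RecordTruth, SubjectParameters, WaveformRecord

__all__ = [
    "generate_rr_series",
    "synthesize_ecg",
    "synthesize_ppg",
    "add_noise",
    "iter_cohort",
    "generate_cohort",
    "SubjectRecord",
    "DEFAULT_NOISE_LEVELS",
]

# (powerline amplitude, baseline-wander amplitude, high-frequency sd), signal units
DEFAULT_NOISE_LEVELS = (0.05, 0.10, 0.02)

# ECG kernel layout relative to the R peak, seconds
_P_CENTER_OFFSET = 0.16  # P-wave center precedes R by this much
_T_CENTER_OFFSET = 0.28
_T_WIDTH = 0.18

# PPG lobe layout as fractions of the beat period
_PPG_SYS_PEAK_FRAC = 0.20  # systolic peak position after the foot
_PPG_SYS_WIDTH_FRAC = 0.40
_PPG_REFL_PEAK_FRAC = 0.55  # reflected-wave peak position
_PPG_REFL_WIDTH_FRAC = 0.40


def _ar1_phi_for_pnn50(sdnn: float, pnn50: float) -> float:
    """AR(1) coefficient that yields the requested pNN50 at the given SDNN.

    For a stationary AR(1) series with marginal sd ``sdnn``, successive
    differences are Gaussian with sd ``sdnn * sqrt(2 * (1 - phi))``; the
    fraction exceeding 50 ms in absolute value is ``2 * Phi(-50 / sd_diff)``.
    Inverting gives the coefficient; it is clipped to (-1, 1) when the target
    is unreachable at this SDNN.
    """
    if sdnn <= 0:
        return 0.0
    if pnn50 <= 0:
        return 0.999
    if pnn50 >= 1:
        return -0.999
    z = -ndtri(pnn50 / 2.0)  # Phi^{-1}(1 - pnn50/2) > 0
    sd_diff = 50.0 / z
    phi = 1.0 - (sd_diff / sdnn) ** 2 / 2.0
    return float(np.clip(phi, -0.999, 0.999))


def generate_rr_series(params: SubjectParameters, duration: float) -> np.ndarray:
    """Generate a beat-to-beat RR-interval series (ms) spanning ``duration`` seconds.

    The series is mean ``60000 / mean_hr`` with an AR(1) Gaussian perturbation
    standardized to hit ``sdnn_target`` exactly in sample standard deviation
    (and the mean exactly), so the cumulative beat times never exceed the
    requested duration and HRV summaries of the output recover the targets.
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be positive")
    mean_rr = 60000.0 / params.mean_hr  # ms
    n = int(np.floor(duration * 1000.0 / mean_rr))
    if n < 1:
        raise InvalidParameterError(
            f"duration {duration} s is shorter than one beat at {params.mean_hr} bpm"
        )
    if params.sdnn_target == 0.0 or n == 1:
        return np.full(n, mean_rr)

    phi = _ar1_phi_for_pnn50(params.sdnn_target, params.pnn50_target)
    rng = np.random.default_rng(params.seed)
    innov = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = innov[0]
    scale = np.sqrt(1.0 - phi**2)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + scale * innov[i]
    # standardize the realized path: exact sample mean 0, exact sample sd target
    x -= x.mean()
    sd = x.std(ddof=1)
    if sd > 0:
        x *= params.sdnn_target / sd
    rr = np.clip(mean_rr + x, 250.0, None)  # physiological floor; rarely active
    total = float(np.cumsum(rr)[-1])
    if total > duration * 1000.0:  # guard float round-up of the exact mean
        rr *= (duration * 1000.0 / total) * (1.0 - 1e-12)
    return rr


def _place_kernel(signal: np.ndarray, fs: float, center: float, width: float,
                  amplitude: float) -> None:
    """Add a raised-cosine (Hann) lobe of total ``width`` seconds in place."""
    if amplitude == 0.0 or width <= 0.0:
        return
    i0 = max(0, int(np.ceil((center - width / 2.0) * fs)))
    i1 = min(signal.size - 1, int(np.floor((center + width / 2.0) * fs)))
    if i1 < i0:
        return
    t = np.arange(i0, i1 + 1) / fs
    signal[i0:i1 + 1] += amplitude * 0.5 * (1.0 + np.cos(2.0 * np.pi * (t - center) / width))


def _beat_times(rr_ms: np.ndarray) -> np.ndarray:
    """Cumulative beat positions in seconds (first beat one RR in)."""
    return np.cumsum(np.asarray(rr_ms, dtype=float)) / 1000.0


def _check_rr(rr) -> np.ndarray:
    rr = np.asarray(rr, dtype=float)
    if rr.size == 0:
        raise InvalidParameterError("RR series must be non-empty")
    if np.any(rr <= 0):
        raise InvalidParameterError("RR intervals must be positive")
    return rr


def synthesize_ecg(rr, params: SubjectParameters, fs: float = DEFAULT_FS,
                   duration: float | None = None) -> WaveformRecord:
    """Render a noise-free ECG for the given RR series.

    Each beat is a sum of three raised-cosine kernels: a P wave (duration and
    amplitude from ``params``) centered 160 ms before R, a QRS lobe whose
    total width equals ``params.qrs_duration``, and a T wave. True R
    positions are stored in the record's truth block.
    """
    rr = _check_rr(rr)
    if fs * params.qrs_duration < 4:
        raise ResolutionError(
            f"fs={fs} Hz resolves only {fs * params.qrs_duration:.1f} samples per QRS; need >= 4"
        )
    beats = _beat_times(rr)
    if duration is None:
        duration = beats[-1] + 0.5
    n = int(round(duration * fs))
    signal = np.zeros(n)
    for t_r in beats:
        _place_kernel(signal, fs, t_r - _P_CENTER_OFFSET, params.p_duration, params.p_amplitude)
        _place_kernel(signal, fs, t_r, params.qrs_duration, params.qrs_amplitude)
        _place_kernel(signal, fs, t_r + _T_CENTER_OFFSET, _T_WIDTH, params.t_amplitude)
    r_idx = np.round(beats * fs).astype(int)
    r_idx = r_idx[r_idx < n]
    truth = RecordTruth(params=params, r_positions=r_idx)
    return WaveformRecord(samples=signal, fs=fs, channel="ECG", truth=truth, label=params.label)


def synthesize_ppg(rr, params: SubjectParameters, fs: float = DEFAULT_FS,
                   duration: float | None = None) -> WaveformRecord:
    """Render a noise-free PPG for the given RR series.

    Each beat rides on the diastolic baseline: a primary systolic lobe of
    amplitude ``ppg_pulse_amplitude`` peaking at 20% of the beat period after
    the foot, plus a reflected lobe scaled by ``augmentation_fraction``
    peaking at 55%. The two lobes barely overlap, so the per-beat maximum is
    the systolic level and the reflected amplitude ratio equals the
    augmentation fraction by construction.
    """
    rr = _check_rr(rr)
    feet = _beat_times(rr)
    periods = np.empty_like(feet)
    periods[:-1] = np.diff(feet)
    periods[-1] = rr[-1] / 1000.0
    if fs * _PPG_SYS_WIDTH_FRAC * periods.min() < 4:
        raise ResolutionError("fs too low to resolve the systolic lobe")
    if duration is None:
        duration = feet[-1] + periods[-1]
    n = int(round(duration * fs))
    signal = np.full(n, params.ppg_diastolic_level)
    amp = params.ppg_pulse_amplitude
    for foot, period in zip(feet, periods):
        _place_kernel(signal, fs, foot + _PPG_SYS_PEAK_FRAC * period,
                      _PPG_SYS_WIDTH_FRAC * period, amp)
        if params.augmentation_fraction > 0:
            _place_kernel(signal, fs, foot + _PPG_REFL_PEAK_FRAC * period,
                          _PPG_REFL_WIDTH_FRAC * period,
                          params.augmentation_fraction * amp)
    foot_idx = np.round(feet * fs).astype(int)
    peak_idx = np.round((feet + _PPG_SYS_PEAK_FRAC * periods) * fs).astype(int)
    keep = (foot_idx < n) & (peak_idx < n)
    truth = RecordTruth(params=params, foot_positions=foot_idx[keep],
                        peak_positions=peak_idx[keep])
    return WaveformRecord(samples=signal, fs=fs, channel="PPG", truth=truth, label=params.label)


def add_noise(record: WaveformRecord, params: SubjectParameters) -> WaveformRecord:
    """Contaminate a record with the three classical noise sources.

    Adds (A) a mains sinusoid at ``params.mains_freq``, (B) low-frequency
    (< 0.5 Hz) baseline wander realized as two seeded sinusoids, and (C)
    white Gaussian high-frequency noise. Fully reproducible: the realization
    is a pure function of ``params.seed`` and the channel.
    """
    a_pl, a_bw, sd_hf = params.noise_levels
    if a_pl == 0.0 and a_bw == 0.0 and sd_hf == 0.0:
        return record
    rng = np.random.default_rng([params.seed, 7 if record.channel == "ECG" else 11])
    n = record.samples.size
    t = np.arange(n) / record.fs
    noise = np.zeros(n)
    if a_pl > 0:
        noise += a_pl * np.sin(2.0 * np.pi * params.mains_freq * t
                               + rng.uniform(0, 2 * np.pi))
    if a_bw > 0:
        for _ in range(2):
            f = rng.uniform(0.05, 0.45)
            noise += (a_bw / 2.0) * np.sin(2.0 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    if sd_hf > 0:
        noise += sd_hf * rng.standard_normal(n)
    return record.with_samples(record.samples + noise)


@dataclass
class SubjectRecord:
    """A labeled synthetic subject: paired ECG and PPG records plus truth."""

    subject_id: str
    label: str
    params: SubjectParameters
    ecg: WaveformRecord
    ppg: WaveformRecord


def _draw(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _draw_control(rng: np.random.Generator, seed: int, noise_levels, mains_freq) -> SubjectParameters:
    # centered inside the normal adult ranges, with enough within-class
    # spread that the two classes overlap and classification is non-trivial
    return SubjectParameters(
        label="control",
        mean_hr=_draw(rng, 75.0, 10.0, 50.0, 110.0),
        sdnn_target=_draw(rng, 65.0, 18.0, 25.0, 130.0),
        pnn50_target=_draw(rng, 0.10, 0.05, 0.0, 0.35),
        qrs_duration=_draw(rng, 0.095, 0.010, 0.070, 0.125),
        p_duration=_draw(rng, 0.095, 0.008, 0.070, 0.125),
        p_amplitude=_draw(rng, 0.15, 0.03, 0.05, 0.28),
        ppg_pulse_amplitude=_draw(rng, 1.0, 0.18, 0.40, 1.50),
        ppg_diastolic_level=_draw(rng, 0.20, 0.05, 0.05, 0.40),
        augmentation_fraction=_draw(rng, 0.32, 0.10, 0.02, 0.70),
        noise_levels=noise_levels,
        mains_freq=mains_freq,
        seed=seed,
    )


def _draw_hf(rng: np.random.Generator, seed: int, noise_levels, mains_freq) -> SubjectParameters:
    # shifted outside the normal ranges (~1.5 sd per feature): depressed HRV,
    # prolonged QRS/P, weaker pulse, stronger wave reflection, elevated rate
    return SubjectParameters(
        label="HF",
        mean_hr=_draw(rng, 85.0, 12.0, 55.0, 120.0),
        sdnn_target=_draw(rng, 40.0, 14.0, 8.0, 80.0),
        pnn50_target=_draw(rng, 0.03, 0.025, 0.0, 0.15),
        qrs_duration=_draw(rng, 0.120, 0.015, 0.085, 0.170),
        p_duration=_draw(rng, 0.110, 0.012, 0.080, 0.150),
        p_amplitude=_draw(rng, 0.13, 0.035, 0.04, 0.25),
        ppg_pulse_amplitude=_draw(rng, 0.72, 0.18, 0.25, 1.25),
        ppg_diastolic_level=_draw(rng, 0.23, 0.06, 0.05, 0.45),
        augmentation_fraction=_draw(rng, 0.50, 0.12, 0.10, 0.92),
        noise_levels=noise_levels,
        mains_freq=mains_freq,
        seed=seed,
    )


def iter_cohort(n_hf: int, n_control: int, master_seed: int, *,
                duration: float = 600.0, fs: float = DEFAULT_FS,
                noise_levels: tuple[float, float, float] = DEFAULT_NOISE_LEVELS,
                mains_freq: float = 50.0):
    """Yield labeled paired ECG+PPG subjects one at a time.

    Heart-failure and control subject parameters are drawn from the shifted
    and normal distributions respectively; each subject's two channels share
    one RR series and one noise seed. Deterministic given ``master_seed``.
    Streaming keeps memory at one subject's waveforms regardless of cohort
    size.
    """
    if n_hf < 0 or n_control < 0:
        raise InvalidParameterError("subject counts must be non-negative")
    rng = np.random.default_rng(master_seed)
    specs = [("HF", i) for i in range(n_hf)] + [("control", i) for i in range(n_control)]
    for label, i in specs:
        seed = int(rng.integers(0, 2**31 - 1))
        draw = _draw_hf if label == "HF" else _draw_control
        params = draw(rng, seed, noise_levels, mains_freq)
        rr = generate_rr_series(params, duration)
        ecg = add_noise(synthesize_ecg(rr, params, fs, duration=duration), params)
        ppg = add_noise(synthesize_ppg(rr, params, fs, duration=duration), params)
        sid = f"{'hf' if label == 'HF' else 'ctl'}{i:04d}"
        ecg.subject_id = ppg.subject_id = sid
        yield SubjectRecord(subject_id=sid, label=label, params=params, ecg=ecg, ppg=ppg)


def generate_cohort(n_hf: int, n_control: int, master_seed: int, *,
                    duration: float = 600.0, fs: float = DEFAULT_FS,
                    noise_levels: tuple[float, float, float] = DEFAULT_NOISE_LEVELS,
                    mains_freq: float = 50.0) -> list[SubjectRecord]:
    """Materialized list form of :func:`iter_cohort` (same determinism)."""
    return list(iter_cohort(n_hf, n_control, master_seed, duration=duration, fs=fs,
                            noise_levels=noise_levels, mains_freq=mains_freq))
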