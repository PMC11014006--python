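"""Denoising filters and record-quality screening.

All filters are 4th-order Butterworth designs applied forward-backward
(zero phase), so fiducial timing is preserved. Baseline wander is removed
with a 0.5 Hz high-pass, mains interference with a narrow IIR notch, and
broadband muscle noise optionally with a 40 Hz low-pass. Screening
reproduces the fragment-retention rules of the emulated study design: a
minimum fragment length (30,000 points, i.e. 4 min at 125 Hz), a sensor-off
flatline check, and a missing-beat check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InvalidParameterError
from .records import WaveformRecord

__all__ = [
    "remove_baseline_wander",
    "lowpass_muscle_noise",
    "notch_powerline",
    "quality_screen",
    "preprocess_record",
    "ScreenResult",
    "minutes",
    "DEFAULT_MIN_POINTS",
]

DEFAULT_MIN_POINTS = 30_000
DEFAULT_HP_CUTOFF = 0.5  # Hz
DEFAULT_LP_CUTOFF = 40.0  # Hz


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of quality screening for one record."""

    retained: bool
    reason: str  # {ok, too_short, sensor_off, missing_peaks, abnormal_morphology}

    def __post_init__(self) -> None:
        if self.retained != (self.reason == "ok"):
            raise InvalidParameterError("retained must hold exactly when reason == 'ok'")


def minutes(min_points: int, fs: float) -> float:
    """Length of a fragment of ``min_points`` samples, in minutes."""
    return min_points / (fs * 60.0)


def _check_cutoff(cutoff: float, fs: float) -> None:
    if not 0 < cutoff < fs / 2:
        raise InvalidParameterError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={fs / 2} Hz)"
        )


def remove_baseline_wander(record: WaveformRecord,
                           cutoff: float = DEFAULT_HP_CUTOFF) -> WaveformRecord:
    """Zero-phase high-pass to remove baseline drift (and the DC offset)."""
    _check_cutoff(cutoff, record.fs)
    sos = sps.butter(4, cutoff, btype="highpass", fs=record.fs, output="sos")
    return record.with_samples(sps.sosfiltfilt(sos, record.samples))


def lowpass_muscle_noise(record: WaveformRecord,
                         cutoff: float = DEFAULT_LP_CUTOFF) -> WaveformRecord:
    """Zero-phase low-pass attenuating broadband high-frequency noise."""
    _check_cutoff(cutoff, record.fs)
    sos = sps.butter(4, cutoff, btype="lowpass", fs=record.fs, output="sos")
    return record.with_samples(sps.sosfiltfilt(sos, record.samples))


def notch_powerline(record: WaveformRecord, mains_freq: float = 50.0,
                    quality: float = 30.0) -> WaveformRecord:
    """Zero-phase IIR notch at the mains frequency (50 or 60 Hz).

    The notch is narrow (quality factor 30 by default): gain at the mains
    frequency is suppressed by well over 20 dB while the passband away from
    the notch stays within 1 dB of unity.
    """
    if not 0 < mains_freq < record.fs / 2:
        raise InvalidParameterError(
            f"mains frequency {mains_freq} Hz must be below Nyquist ({record.fs / 2} Hz)"
        )
    b, a = sps.iirnotch(mains_freq, quality, fs=record.fs)
    return record.with_samples(sps.filtfilt(b, a, record.samples))


def _detect_any_peaks(samples: np.ndarray, fs: float) -> np.ndarray:
    # lightweight beat finder used only for screening; channel-agnostic
    x = samples - np.median(samples)
    spread = np.percentile(np.abs(x), 99)
    if spread <= 0:
        return np.array([], dtype=int)
    peaks, _ = sps.find_peaks(x, height=0.4 * spread, distance=max(1, int(0.2 * fs)))
    return peaks


def quality_screen(record: WaveformRecord, min_points: int = DEFAULT_MIN_POINTS,
                   flatline_epsilon: float = 1e-4,
                   fs: float | None = None) -> ScreenResult:
    """Decide whether a fragment is usable for feature extraction.

    Rejection reasons, checked in order: ``too_short`` (fewer than
    ``min_points`` samples — 30,000 at 125 Hz is 4 minutes), ``sensor_off``
    (any >= 5 s window whose sample range is below ``flatline_epsilon``),
    and ``missing_peaks`` (detected beats imply an inter-beat gap > 3 s
    anywhere, including the record edges).
    """
    fs = fs if fs is not None else record.fs
    x = record.samples
    if x.size <= min_points:
        return ScreenResult(False, "too_short")

    win = int(5 * fs)
    if win >= 1 and x.size >= win:
        # rolling range via cumulative extrema over strided windows (hop = 1 s)
        hop = max(1, int(fs))
        for start in range(0, x.size - win + 1, hop):
            seg = x[start:start + win]
            if seg.max() - seg.min() < flatline_epsilon:
                return ScreenResult(False, "sensor_off")

    peaks = _detect_any_peaks(x, fs)
    max_gap = 3.0 * fs
    if peaks.size < 2:
        return ScreenResult(False, "missing_peaks")
    gaps = np.diff(peaks)
    edge_gaps = (peaks[0], x.size - 1 - peaks[-1])
    if gaps.max() > max_gap or max(edge_gaps) > max_gap:
        return ScreenResult(False, "missing_peaks")

    return ScreenResult(True, "ok")


def preprocess_record(record: WaveformRecord, mains_freq: float = 50.0,
                      hp_cutoff: float = DEFAULT_HP_CUTOFF,
                      lp_cutoff: float | None = DEFAULT_LP_CUTOFF) -> WaveformRecord:
    """Standard denoising chain: baseline high-pass, mains notch, optional low-pass."""
    out = remove_baseline_wander(record, hp_cutoff)
    out = notch_powerline(out, mains_freq)
    if lp_cutoff is not None:
        out = lowpass_muscle_noise(out, lp_cutoff)
    return out
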