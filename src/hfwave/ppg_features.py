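"""PPG fiducial detection and pulse-waveform features.

The extractor relies on three readily discernible landmarks per cardiac
cycle — the pulse foot, the peak of the first derivative on the upstroke,
and the systolic peak — from which the amplitude features (systolic and
diastolic levels, pulse pressure, peak-to-peak amplitude), the peak-to-peak
interval, and the augmentation index are derived.

The PPG is uncalibrated, so "systolic/diastolic pressure" are waveform
amplitude levels in arbitrary signal units, not mmHg; the augmentation
index is the ratio of the reflected-wave amplitude above the foot to the
systolic amplitude above the foot, emitted as a fraction (multiply by 100
to display as percent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ContractViolationError, InsufficientDataError, InvalidParameterError
from .records import WaveformRecord

__all__ = [
    "PpgBeats",
    "PpgSummary",
    "detect_ppg_fiducials",
    "amplitude_features",
    "augmentation_index",
    "ppg_feature_row",
]

_MIN_BEAT_SPACING_S = 0.3
_REFL_SEARCH_START_FRAC = 0.25  # reflected wave searched from sys_peak + this * period
_REFRACTORY_PERIOD_FRAC = 0.5  # peak-to-peak refractory as fraction of the beat period
_PERIOD_OUTLIER_BAND = (0.6, 1.5)  # beats outside this multiple of the median period
                                   # are treated as detection gaps, not single beats


def _dominant_period(x: np.ndarray, fs: float, lo_s: float = 0.33,
                     hi_s: float = 2.0) -> float | None:
    """Beat period (s) from the autocorrelation peak in the physiological range.

    Robust against prominent reflected waves: a waveform periodic with the
    cardiac cycle autocorrelates maximally at the full cycle length even when
    each cycle contains two lobes.
    """
    x = x - x.mean()
    n = x.size
    if n < int(2 * hi_s * fs):
        return None
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec))[: n]
    i0, i1 = int(lo_s * fs), min(int(hi_s * fs), n - 1)
    if i1 <= i0:
        return None
    lag = i0 + int(np.argmax(ac[i0:i1]))
    return lag / fs


@dataclass
class PpgBeats:
    """Aligned per-beat PPG fiducials: one foot, derivative peak and systolic
    peak per detected beat (reflected-wave peaks filled by the augmentation
    index computation; NaN where no landmark was found)."""

    feet: np.ndarray
    deriv_peaks: np.ndarray
    sys_peaks: np.ndarray
    fs: float
    reflect_peaks: np.ndarray | None = None
    warning: str | None = None

    def __post_init__(self) -> None:
        self.feet = np.asarray(self.feet, dtype=int)
        self.deriv_peaks = np.asarray(self.deriv_peaks, dtype=int)
        self.sys_peaks = np.asarray(self.sys_peaks, dtype=int)
        if not (self.feet.size == self.deriv_peaks.size == self.sys_peaks.size):
            raise ContractViolationError("fiducial arrays must be aligned per beat")
        if self.feet.size and not (
            np.all(self.feet < self.deriv_peaks) and np.all(self.deriv_peaks < self.sys_peaks)
        ):
            raise ContractViolationError("per beat ordering foot < deriv_peak < sys_peak required")


@dataclass(frozen=True)
class PpgSummary:
    """Per-record PPG feature summary (amplitudes in signal units)."""

    systolic_level: float
    diastolic_level: float
    pulse_pressure: float
    peak_to_peak_interval: float  # s
    peak_to_peak_amplitude: float
    augmentation_index: float = float("nan")  # fraction
    stiffness_index: float = float("nan")  # s, systolic-to-reflected delay (experimental)


def detect_ppg_fiducials(record: WaveformRecord) -> PpgBeats:
    """Detect foot, first-derivative peak and systolic peak for each beat.

    Systolic peaks are prominent maxima at physiological spacing: the beat
    period is first estimated from the signal autocorrelation and peaks are
    required to be at least half a period apart, so a prominent reflected
    (dicrotic) wave is not mistaken for a beat. Each beat's foot is the
    minimum between the previous peak and the current one, and the
    derivative peak the steepest point of the upstroke.
    """
    if record.channel != "PPG":
        raise InvalidParameterError("detect_ppg_fiducials expects a PPG record")
    x = record.samples
    scale = np.percentile(x, 99) - np.percentile(x, 1) if x.size else 0.0
    if scale <= 0:
        return PpgBeats(np.array([], int), np.array([], int), np.array([], int),
                        record.fs, warning="no_beats")
    period = _dominant_period(x, record.fs)
    spacing_s = _REFRACTORY_PERIOD_FRAC * period if period else _MIN_BEAT_SPACING_S
    distance = max(1, int(spacing_s * record.fs))
    peaks, _ = sps.find_peaks(x, prominence=0.3 * scale, distance=distance)
    if peaks.size == 0:
        return PpgBeats(np.array([], int), np.array([], int), np.array([], int),
                        record.fs, warning="no_beats")

    dx = np.diff(x)
    feet, dpeaks, speaks = [], [], []
    for k, pk in enumerate(peaks):
        start = peaks[k - 1] if k > 0 else max(0, pk - int(1.5 * record.fs))
        if pk - start < 3:
            continue
        seg = x[start:pk]
        # last occurrence of the minimum: on a flat diastolic run the foot is
        # the end of the plateau, immediately before the upstroke
        foot = start + (seg.size - 1 - int(np.argmin(seg[::-1])))
        if pk - foot < 2:
            continue
        dpk = int(np.argmax(dx[foot:pk])) + foot
        if not foot < dpk < pk:
            continue
        feet.append(foot)
        dpeaks.append(dpk)
        speaks.append(int(pk))
    if not feet:
        return PpgBeats(np.array([], int), np.array([], int), np.array([], int),
                        record.fs, warning="no_beats")
    return PpgBeats(np.array(feet), np.array(dpeaks), np.array(speaks), record.fs)


def amplitude_features(record: WaveformRecord, beats: PpgBeats) -> PpgSummary:
    """Level, pressure and interval features from detected fiducials.

    Systolic level is the mean per-beat maximum, diastolic level the mean
    foot value, pulse pressure their difference; the peak-to-peak interval
    is the mean spacing of successive systolic peaks and the peak-to-peak
    amplitude the mean per-beat max minus min.
    """
    if beats.sys_peaks.size < 2:
        raise InsufficientDataError("at least two beats are required")
    x = record.samples
    sys_level = float(np.mean(x[beats.sys_peaks]))
    dia_level = float(np.mean(x[beats.feet]))
    # per-beat windows: foot to next foot (last beat: to the end of record)
    bounds = np.append(beats.feet, x.size)
    p2p_amp = float(np.mean([
        x[bounds[i]:bounds[i + 1]].max() - x[bounds[i]:bounds[i + 1]].min()
        for i in range(beats.feet.size)
    ]))
    p2p_interval = float(np.mean(np.diff(beats.sys_peaks)) / beats.fs)
    return PpgSummary(
        systolic_level=sys_level,
        diastolic_level=dia_level,
        pulse_pressure=sys_level - dia_level,
        peak_to_peak_interval=p2p_interval,
        peak_to_peak_amplitude=p2p_amp,
    )


def augmentation_index(record: WaveformRecord, beats: PpgBeats) -> tuple[float, PpgBeats]:
    """Mean augmentation index (fraction) and beats with reflected peaks filled.

    Per beat, the reflected wave is the most prominent local maximum between
    a quarter-period after the systolic peak and the next foot; beats with
    no local maximum fall back to the largest late-systolic landmark (window
    maximum). AIx is (reflected level - foot level) / (systolic level -
    foot level), averaged over beats whose detected period is consistent
    with the record median (gaps from missed beats would otherwise let the
    next systolic peak masquerade as a reflection). NaN when no beat admits
    a window.
    """
    x = record.samples
    feet, speaks = beats.feet, beats.sys_peaks
    if speaks.size < 2:
        raise InsufficientDataError("at least two beats are required")
    med_period = float(np.median(np.diff(feet))) if feet.size > 2 else None
    aix_vals, refl_idx = [], np.full(speaks.size, np.nan)
    for i in range(speaks.size - 1):
        foot, pk, nxt_foot = feet[i], speaks[i], feet[i + 1]
        period = nxt_foot - foot
        if med_period is not None and not (
            _PERIOD_OUTLIER_BAND[0] * med_period <= period
            <= _PERIOD_OUTLIER_BAND[1] * med_period
        ):
            continue
        w0 = pk + int(_REFL_SEARCH_START_FRAC * period)
        if nxt_foot - w0 < 3:
            continue
        seg = x[w0:nxt_foot]
        local, _ = sps.find_peaks(seg)
        if local.size:
            ridx = w0 + local[np.argmax(seg[local])]
        else:
            ridx = w0 + int(np.argmax(seg))  # late-systolic landmark fallback
        sys_amp = x[pk] - x[foot]
        if sys_amp <= 0:
            continue
        aix_vals.append((x[ridx] - x[foot]) / sys_amp)
        refl_idx[i] = ridx
    out = PpgBeats(feet, beats.deriv_peaks, speaks, beats.fs,
                   reflect_peaks=refl_idx, warning=beats.warning)
    if not aix_vals:
        return float("nan"), out
    return float(np.mean(aix_vals)), out


def ppg_feature_row(record: WaveformRecord) -> dict[str, float]:
    """Extract the five PPG-side features of the canonical 13-feature set."""
    beats = detect_ppg_fiducials(record)
    if beats.sys_peaks.size < 3:
        raise InsufficientDataError("too few PPG beats for feature extraction")
    summary = amplitude_features(record, beats)
    aix, beats = augmentation_index(record, beats)
    return {
        "systolic_level": summary.systolic_level,
        "diastolic_level": summary.diastolic_level,
        "pulse_pressure": summary.pulse_pressure,
        "peak_to_peak_interval": summary.peak_to_peak_interval,
        "augmentation_index": aix,
    }
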