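"""Core containers: subject-level generative parameters and waveform records.

A :class:`WaveformRecord` is one uniformly sampled channel (ECG or PPG) with
its sampling rate and an optional ground-truth block describing how it was
generated — synthetic records carry their generating parameters and the true
beat positions, so downstream detectors can be validated by round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ContractViolationError, InvalidParameterError

DEFAULT_FS = 125.0  # Hz; the sampling rate of the bedside-monitor waveforms emulated here


@dataclass(frozen=True)
class SubjectParameters:
    """Generative parameters for one synthetic subject.

    Amplitude quantities are in arbitrary signal units (PPG is uncalibrated;
    ECG amplitudes are normalized to a unit R wave). Control subjects default
    to values inside the normal adult ranges; heart-failure draws shift SDNN
    and pNN50 down, QRS duration up, pulse amplitude down and the reflected
    wave fraction up.
    """

    label: str = "control"  # {"HF", "control"}
    mean_hr: float = 75.0  # beats/min
    sdnn_target: float = 70.0  # ms
    pnn50_target: float = 0.12  # fraction of successive differences > 50 ms
    qrs_duration: float = 0.095  # s
    p_duration: float = 0.095  # s
    p_amplitude: float = 0.15  # signal units (R wave = 1)
    qrs_amplitude: float = 1.0  # R-wave height, signal units
    t_amplitude: float = 0.30  # T-wave height, signal units
    ppg_pulse_amplitude: float = 1.0  # systolic excursion above the foot
    ppg_diastolic_level: float = 0.2  # baseline (foot) level
    augmentation_fraction: float = 0.30  # reflected-wave amplitude / systolic, in [0, 1)
    noise_levels: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # (powerline amplitude, baseline-wander amplitude, high-frequency noise sd)
    mains_freq: float = 50.0  # Hz, 50 or 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label not in ("HF", "control"):
            raise InvalidParameterError(f"label must be 'HF' or 'control', got {self.label!r}")
        if self.mean_hr <= 0:
            raise InvalidParameterError("mean_hr must be positive")
        if self.sdnn_target < 0:
            raise InvalidParameterError("sdnn_target must be non-negative")
        if not 0.0 <= self.pnn50_target <= 1.0:
            raise InvalidParameterError("pnn50_target must be in [0, 1]")
        if self.qrs_duration <= 0 or self.p_duration <= 0:
            raise InvalidParameterError("wave durations must be positive")
        if self.qrs_amplitude < 0 or self.t_amplitude < 0 or self.p_amplitude < 0:
            raise InvalidParameterError("wave amplitudes must be non-negative")
        if not 0.0 <= self.augmentation_fraction < 1.0:
            raise InvalidParameterError("augmentation_fraction must be in [0, 1)")
        if self.mains_freq not in (50.0, 60.0, 50, 60):
            raise InvalidParameterError("mains_freq must be 50 or 60 Hz")
        if any(v < 0 for v in self.noise_levels):
            raise InvalidParameterError("noise amplitudes must be non-negative")


@dataclass(frozen=True)
class RecordTruth:
    """Ground truth attached to synthetic records."""

    params: SubjectParameters
    r_positions: Optional[np.ndarray] = None  # sample indices of true R peaks (ECG)
    foot_positions: Optional[np.ndarray] = None  # sample indices of true pulse feet (PPG)
    peak_positions: Optional[np.ndarray] = None  # sample indices of true systolic peaks (PPG)


@dataclass
class WaveformRecord:
    """One uniformly sampled waveform channel."""

    samples: np.ndarray
    fs: float
    channel: str  # {"ECG", "PPG"}
    units: str = "a.u."
    truth: Optional[RecordTruth] = None
    subject_id: Optional[str] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise InvalidParameterError("sampling rate must be positive")
        if self.channel not in ("ECG", "PPG"):
            raise InvalidParameterError(f"channel must be 'ECG' or 'PPG', got {self.channel!r}")
        if self.samples.ndim != 1:
            raise ContractViolationError("samples must be one-dimensional")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ContractViolationError("samples must be finite")
        if self.truth is not None:
            for pos in (self.truth.r_positions, self.truth.foot_positions,
                        self.truth.peak_positions):
                if pos is not None and len(pos) > 1:
                    if np.any(np.diff(pos) <= 0):
                        raise ContractViolationError("true beat positions must be strictly increasing")
                    if pos[-1] >= self.samples.size or pos[0] < 0:
                        raise ContractViolationError("true beat positions must lie within the record")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    def with_samples(self, samples: np.ndarray) -> "WaveformRecord":
        """Copy of this record with replaced sample values (same metadata)."""
        out = WaveformRecord(
            samples=np.asarray(samples, dtype=float),
            fs=self.fs,
            channel=self.channel,
            units=self.units,
            truth=self.truth,
            subject_id=self.subject_id,
            label=self.label,
        )
        return out


def hf_shifted(params: SubjectParameters, **overrides) -> SubjectParameters:
    """Return a copy of ``params`` with fields replaced."""
    return replace(params, **overrides)
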