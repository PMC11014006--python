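"""Labeled feature matrices and min-max normalization.

Per-subject feature rows from the ECG and PPG extractors are assembled into
a single labeled matrix over the 13 canonical feature columns; single-
modality (ECG-only / PPG-only) views support the integrated-vs-single
comparisons. Normalization maps every column to [0, 1] via
``(x - min(x)) / (max(x) - min(x))`` with the fitted (min, max) stored so
unseen rows can be transformed consistently.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, NormalizationStateError

__all__ = [
    "ECG_FEATURES",
    "PPG_FEATURES",
    "ALL_FEATURES",
    "FeatureMatrix",
    "assemble",
    "minmax_normalize",
]

logger = logging.getLogger(__name__)

ECG_FEATURES = (
    "heart_rate", "rr_interval", "qrs_interval", "p_wave",
    "sdnn", "rmssd", "nn50", "pnn50",
)
PPG_FEATURES = (
    "systolic_level", "diastolic_level", "pulse_pressure",
    "peak_to_peak_interval", "augmentation_index",
)
ALL_FEATURES = ECG_FEATURES + PPG_FEATURES


@dataclass
class FeatureMatrix:
    """A labeled per-subject feature table with normalization bookkeeping."""

    data: pd.DataFrame  # index: subject_id; columns: feature names
    labels: pd.Series  # index: subject_id; values in {"HF", "control"}
    normalization_state: str = "raw"  # {"raw", "minmax"}
    column_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise InvalidParameterError("duplicated subject ids in feature matrix")
        unknown = set(self.data.columns) - set(ALL_FEATURES)
        if unknown:
            raise InvalidParameterError(f"unknown feature columns: {sorted(unknown)}")
        if not self.data.index.equals(self.labels.index):
            self.labels = self.labels.reindex(self.data.index)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def restrict(self, columns) -> "FeatureMatrix":
        """View restricted to a subset of feature columns (e.g. one modality)."""
        cols = [c for c in columns if c in self.data.columns]
        return FeatureMatrix(self.data[cols].copy(), self.labels.copy(),
                             self.normalization_state,
                             {c: r for c, r in self.column_ranges.items() if c in cols})

    def subset_rows(self, ids) -> "FeatureMatrix":
        """View restricted to a subset of subjects."""
        return FeatureMatrix(self.data.loc[ids].copy(), self.labels.loc[ids].copy(),
                             self.normalization_state, dict(self.column_ranges))

    def transform_rows(self, rows: pd.DataFrame, clip: bool = True) -> pd.DataFrame:
        """Apply the stored min-max mapping to unseen rows."""
        if self.normalization_state != "minmax":
            raise NormalizationStateError("matrix has no fitted normalization")
        out = rows.copy()
        for col in out.columns:
            lo, hi = self.column_ranges[col]
            out[col] = 0.0 if hi == lo else (out[col] - lo) / (hi - lo)
        if clip:
            out = out.clip(0.0, 1.0)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Labels + features as a single DataFrame (for delimited-text output)."""
        out = self.data.copy()
        out.insert(0, "label", self.labels)
        out.index.name = "subject_id"
        return out


def assemble(ecg_rows: dict[str, dict[str, float]] | pd.DataFrame,
             ppg_rows: dict[str, dict[str, float]] | pd.DataFrame,
             labels: dict[str, str] | pd.Series,
             how: str = "inner") -> FeatureMatrix:
    """Join per-subject ECG and PPG feature rows into one labeled matrix.

    Rows are keyed by subject id and joined on it (inner join by default:
    subjects missing a modality are dropped with a log entry). Rows with
    non-finite values in any feature are likewise excluded and logged —
    incomplete records do not enter the analysis.
    """
    ecg = pd.DataFrame.from_dict(ecg_rows, orient="index") if isinstance(ecg_rows, dict) \
        else ecg_rows.copy()
    ppg = pd.DataFrame.from_dict(ppg_rows, orient="index") if isinstance(ppg_rows, dict) \
        else ppg_rows.copy()
    for frame, expected in ((ecg, ECG_FEATURES), (ppg, PPG_FEATURES)):
        if frame.index.duplicated().any():
            raise InvalidParameterError("conflicting duplicate subject ids")
        frame.drop(columns=[c for c in frame.columns if c not in expected], inplace=True)

    joined = ecg.join(ppg, how=how)
    dropped = (len(ecg) + len(ppg) - 2 * len(joined)) if how == "inner" else 0
    if dropped > 0:
        logger.warning("assemble: %d single-modality rows dropped by inner join", dropped)
    if joined.empty:
        warnings.warn("assemble produced an empty feature matrix", stacklevel=2)

    incomplete = ~np.isfinite(joined.to_numpy(dtype=float)).all(axis=1) if len(joined) else \
        np.array([], dtype=bool)
    if incomplete.any():
        logger.warning("assemble: %d rows with missing features excluded", int(incomplete.sum()))
        joined = joined.loc[~incomplete]

    labels = pd.Series(labels) if isinstance(labels, dict) else labels
    lab = labels.reindex(joined.index)
    if lab.isna().any():
        raise InvalidParameterError("missing label for assembled subjects")
    order = [c for c in ALL_FEATURES if c in joined.columns]
    out = joined[order]
    out.index.name = "subject_id"
    return FeatureMatrix(out, lab.astype(str))


def minmax_normalize(m: FeatureMatrix) -> FeatureMatrix:
    """Min-max normalize every column to [0, 1], storing the fitted ranges.

    Applied to the whole matrix (train and test together) by default-usage
    fidelity with the emulated study design; for a leakage-safe protocol,
    normalize the training subset and push the mapping onto held-out rows
    with :meth:`FeatureMatrix.transform_rows`. Constant columns map to all
    zeros with a warning. Re-normalizing an already normalized matrix is a
    state error, not a silent no-op.
    """
    if m.normalization_state != "raw":
        raise NormalizationStateError("matrix is already normalized")
    data = m.data.copy()
    ranges: dict[str, tuple[float, float]] = {}
    for col in data.columns:
        x = data[col].to_numpy(dtype=float)
        lo, hi = float(np.min(x)), float(np.max(x))
        ranges[col] = (lo, hi)
        if hi == lo:
            warnings.warn(f"constant feature column {col!r} mapped to 0", stacklevel=2)
            data[col] = 0.0
        else:
            data[col] = (x - lo) / (hi - lo)
    return FeatureMatrix(data, m.labels.copy(), "minmax", ranges)
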