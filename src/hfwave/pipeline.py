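"""End-to-end orchestration: cohort -> denoised records -> feature matrix.

Thin glue over the preprocessing and feature-extraction modules so the
full study chain (screen, denoise, extract 13 features, assemble, label)
is one call for both the library API and the CLI.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd

from .ecg_features import ecg_feature_row
from .errors import InsufficientDataError
from .features import FeatureMatrix, assemble
from .ppg_features import ppg_feature_row
from .preprocess import preprocess_record, quality_screen
from .synth import SubjectRecord

__all__ = ["extract_cohort_features"]

logger = logging.getLogger(__name__)


def extract_cohort_features(subjects: Iterable[SubjectRecord], *,
                            preprocess: bool = True,
                            mains_freq: float = 50.0,
                            screen: bool = True,
                            min_points: int = 30_000,
                            ) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Extract the labeled 13-feature matrix from a cohort of paired records.

    Each subject's channels are (optionally) denoised, screened against the
    fragment-retention rules, and passed through the ECG and PPG extractors.
    Returns the raw (un-normalized) feature matrix plus a screening log with
    one row per subject (id, retained flag, reason).
    """
    ecg_rows: dict[str, dict[str, float]] = {}
    ppg_rows: dict[str, dict[str, float]] = {}
    labels: dict[str, str] = {}
    log_rows = []
    for subj in subjects:
        ecg = preprocess_record(subj.ecg, mains_freq) if preprocess else subj.ecg
        ppg = preprocess_record(subj.ppg, mains_freq) if preprocess else subj.ppg
        reason = "ok"
        if screen:
            for rec in (ecg, ppg):
                res = quality_screen(rec, min_points=min_points)
                if not res.retained:
                    reason = res.reason
                    break
        if reason == "ok":
            try:
                ecg_rows[subj.subject_id] = ecg_feature_row(ecg)
                ppg_rows[subj.subject_id] = ppg_feature_row(ppg)
                labels[subj.subject_id] = subj.label
            except InsufficientDataError as exc:
                reason = "missing_peaks"
                logger.warning("subject %s: %s", subj.subject_id, exc)
        log_rows.append({"subject_id": subj.subject_id, "retained": reason == "ok",
                         "reason": reason})
    log = pd.DataFrame(log_rows, columns=["subject_id", "retained", "reason"])
    if not ecg_rows:
        raise InsufficientDataError("no subject survived screening and extraction")
    matrix = assemble(ecg_rows, ppg_rows, labels)
    return matrix, log
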