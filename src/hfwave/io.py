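"""Plain-text persistence for cohorts, feature tables and reports.

Cohorts are written as one CSV manifest (subject id, label, generating
parameters) plus one two-column CSV per subject holding the ECG and PPG
samples; the sampling rate travels in a commented header line. Feature
tables and metric tables are plain CSV with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import EvaluationReport
from .features import FeatureMatrix
from .records import SubjectParameters, WaveformRecord
from .synth import SubjectRecord

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_feature_table",
    "read_feature_table",
    "reports_to_table",
    "write_reports",
]

_PARAM_FIELDS = [
    "mean_hr", "sdnn_target", "pnn50_target", "qrs_duration", "p_duration",
    "p_amplitude", "qrs_amplitude", "t_amplitude", "ppg_pulse_amplitude",
    "ppg_diastolic_level", "augmentation_fraction", "mains_freq", "seed",
]


def write_cohort(subjects: list[SubjectRecord], out_dir: str | Path) -> Path:
    """Write a cohort as manifest.csv + per-subject record CSVs; returns the dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        row = {"subject_id": s.subject_id, "label": s.label, "fs": s.ecg.fs}
        for f in _PARAM_FIELDS:
            row[f] = getattr(s.params, f)
        pl, bw, hf = s.params.noise_levels
        row.update(noise_powerline=pl, noise_baseline=bw, noise_hf=hf)
        rows.append(row)
        rec_path = out / f"{s.subject_id}.csv"
        with open(rec_path, "w") as fh:
            fh.write(f"# fs={s.ecg.fs}\n")
            pd.DataFrame({"ecg": s.ecg.samples, "ppg": s.ppg.samples}).to_csv(
                fh, index=False)
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    return out


def read_cohort(in_dir: str | Path) -> list[SubjectRecord]:
    """Read a cohort written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    subjects = []
    for _, row in manifest.iterrows():
        params = SubjectParameters(
            label=row["label"],
            noise_levels=(row["noise_powerline"], row["noise_baseline"], row["noise_hf"]),
            **{f: (int(row[f]) if f == "seed" else float(row[f])) for f in _PARAM_FIELDS},
        )
        frame = pd.read_csv(in_dir / f"{row['subject_id']}.csv", comment="#")
        fs = float(row["fs"])
        ecg = WaveformRecord(frame["ecg"].to_numpy(), fs, "ECG",
                             subject_id=row["subject_id"], label=row["label"])
        ppg = WaveformRecord(frame["ppg"].to_numpy(), fs, "PPG",
                             subject_id=row["subject_id"], label=row["label"])
        subjects.append(SubjectRecord(row["subject_id"], row["label"], params, ecg, ppg))
    return subjects


def write_feature_table(m: FeatureMatrix, path: str | Path) -> None:
    """Feature matrix (+ labels) as CSV; normalization ranges alongside as JSON."""
    path = Path(path)
    m.to_frame().to_csv(path)
    if m.normalization_state == "minmax":
        side = path.with_suffix(".norm.json")
        side.write_text(json.dumps(
            {c: list(r) for c, r in m.column_ranges.items()}, indent=1))


def read_feature_table(path: str | Path) -> FeatureMatrix:
    frame = pd.read_csv(path, index_col="subject_id")
    labels = frame.pop("label")
    side = Path(path).with_suffix(".norm.json")
    if side.exists():
        ranges = {c: tuple(r) for c, r in json.loads(side.read_text()).items()}
        return FeatureMatrix(frame, labels, "minmax", ranges)
    return FeatureMatrix(frame, labels)


def reports_to_table(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Metric table with the canonical column order, one row per report."""
    return pd.DataFrame([r.as_row() for r in reports])


def write_reports(reports: list[EvaluationReport], path: str | Path) -> None:
    """Structured JSON dump of evaluation reports (metrics, confusion, CV folds)."""
    payload = []
    for r in reports:
        d = r.as_row()
        d["confusion"] = {"tp": r.confusion.tp, "tn": r.confusion.tn,
                          "fp": r.confusion.fp, "fn": r.confusion.fn}
        d["cv_fold_metrics"] = r.cv_fold_metrics
        d["seed"] = r.seed
        d["model_params"] = {k: v for k, v in r.model_params.items()
                             if isinstance(v, (int, float, str, bool, type(None)))}
        payload.append(d)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=1, default=_default))
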