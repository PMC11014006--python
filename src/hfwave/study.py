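"""The full study design as one reusable routine.

Runs the complete chain on a synthetic cohort: generation, denoising,
screening, 13-feature extraction, whole-dataset min-max normalization,
per-modality and combined ReliefF selection (4 PPG / 6 ECG / 10 integrated
features), a stratified 75/25 split, and held-out evaluation of the nine
classifier families on each feature set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .classify import EvaluationReport, evaluate_models, partition
from .features import ECG_FEATURES, PPG_FEATURES, FeatureMatrix, minmax_normalize
from .pipeline import extract_cohort_features
from .relieff import relieff_weights, select_top
from .synth import DEFAULT_NOISE_LEVELS, iter_cohort

__all__ = ["StudyResult", "run_study", "N_SELECTED"]

# feature counts retained per configuration after ReliefF ranking
N_SELECTED = {"ppg": 4, "ecg": 6, "integrated": 10}


@dataclass
class StudyResult:
    """Everything the integrated-vs-single comparison needs."""

    matrix: FeatureMatrix  # normalized full matrix, all 13 columns
    screen_log: pd.DataFrame
    selections: dict[str, list[str]]  # feature-set name -> selected columns
    reports: dict[str, list[EvaluationReport]] = field(default_factory=dict)

    def accuracy_table(self) -> pd.DataFrame:
        rows = [r.as_row() for reports in self.reports.values() for r in reports]
        return pd.DataFrame(rows)


def select_feature_sets(norm: FeatureMatrix, k: int = 10,
                        seed: int | None = None) -> dict[str, list[str]]:
    """ReliefF selections: top 4 PPG-only, top 6 ECG-only, top 10 combined."""
    per_modality = {
        "ppg": norm.restrict(PPG_FEATURES),
        "ecg": norm.restrict(ECG_FEATURES),
        "integrated": norm,
    }
    return {
        name: select_top(relieff_weights(m, k=k, seed=seed), N_SELECTED[name])
        for name, m in per_modality.items()
    }


def run_study(n_hf: int = 682, n_control: int = 954, master_seed: int = 0, *,
              duration: float = 600.0,
              noise_levels: tuple[float, float, float] = DEFAULT_NOISE_LEVELS,
              train_fraction: float = 0.75,
              folds: int = 10,
              run_cv: bool = False,
              models=None,
              eval_seed: int | None = None) -> StudyResult:
    """Run the full pipeline and classifier comparison on a synthetic cohort.

    ``eval_seed`` (defaults to ``master_seed``) drives the split, fold
    assignment and stochastic model fits; cross-validation is off by default
    because the headline comparison is on the held-out test set.
    """
    eval_seed = master_seed if eval_seed is None else eval_seed
    matrix, log = extract_cohort_features(
        iter_cohort(n_hf, n_control, master_seed, duration=duration,
                    noise_levels=noise_levels))
    norm = minmax_normalize(matrix)
    selections = select_feature_sets(norm)
    result = StudyResult(matrix=norm, screen_log=log, selections=selections)
    for name, columns in selections.items():
        subset = norm.restrict(columns)
        train, test = partition(subset, train_fraction, eval_seed, stratified=True)
        result.reports[name] = evaluate_models(
            train, test, name, models, folds=folds, seed=eval_seed, run_cv=run_cv)
    return result
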