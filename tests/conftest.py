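"""Shared fixtures: small cohorts and their extracted feature tables.

Expensive cohort fixtures are session-scoped so the synthesis + extraction
cost is paid once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

import hfwave as hw
from hfwave.records import SubjectParameters


@pytest.fixture(scope="session")
def clean_params() -> SubjectParameters:
    """A noise-free, deterministic default subject."""
    return SubjectParameters(mean_hr=60.0, sdnn_target=50.0, pnn50_target=0.10, seed=123)


@pytest.fixture(scope="session")
def clean_recovery_cohort():
    """Noise-free 50+50 cohort (600 s records) with its feature matrix.

    Used for ground-truth parameter-recovery checks, so no preprocessing or
    screening is applied between synthesis and extraction.
    """
    subjects = hw.generate_cohort(50, 50, 20260, noise_levels=(0.0, 0.0, 0.0))
    matrix, _ = hw.extract_cohort_features(subjects, preprocess=False, screen=False)
    return subjects, matrix


@pytest.fixture(scope="session")
def small_noisy_matrix():
    """Feature matrix from a small noisy cohort run through the full chain."""
    matrix, log = hw.extract_cohort_features(
        hw.iter_cohort(60, 84, 777, duration=300))
    return matrix, log


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(97)
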