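"""ReliefF feature weighting and top-n selection.

ReliefF scores each feature by how well it separates instances from their
nearest neighbors of the other class (misses) relative to their nearest
neighbors of the same class (hits): for each sampled instance the weight of
feature f is decreased by the mean hit difference and increased by the
prior-weighted mean miss difference, with per-feature differences
normalized by the feature's value range. Neighbors are found under the
Manhattan metric, which matches the accumulated difference function.

On min-max normalized inputs all weights lie in [-1, 1]. Sampling all
instances (the default) makes the weights deterministic; subsampling is
seeded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, NormalizationStateError
from .features import FeatureMatrix

__all__ = ["ReliefFWeights", "relieff_weights", "select_top"]

logger = logging.getLogger(__name__)

DEFAULT_K = 10  # neighbor count per class


@dataclass(frozen=True)
class ReliefFWeights:
    """Per-feature relevance weights with the parameters that produced them."""

    feature_names: tuple[str, ...]
    weights: np.ndarray
    k: int
    m: int  # number of sampled instances
    seed: int | None

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.feature_names, self.weights.tolist()))


def relieff_weights(m: FeatureMatrix, k: int = DEFAULT_K,
                    n_samples: int | None = None,
                    seed: int | None = None) -> ReliefFWeights:
    """Compute ReliefF weights on a normalized two-class feature matrix.

    ``n_samples=None`` iterates every instance (deterministic); an integer
    subsamples that many instances without replacement using ``seed``.
    Requires at least ``k + 1`` members per class so that every instance has
    k same-class neighbors besides itself.
    """
    if m.normalization_state != "minmax":
        raise NormalizationStateError("relieff_weights requires a min-max normalized matrix")
    X = m.data.to_numpy(dtype=float)
    y = m.labels.to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise InvalidParameterError("ReliefF here supports exactly two classes")
    if counts.min() < k + 1:
        raise InvalidParameterError(
            f"every class needs >= k+1 = {k + 1} members; smallest has {counts.min()}"
        )
    n, p = X.shape
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}
    # per-feature value range for the diff normalization (1 after min-max,
    # 0 for constant columns -> those features contribute nothing)
    rng_span = X.max(axis=0) - X.min(axis=0)
    safe_span = np.where(rng_span > 0, rng_span, 1.0)

    if n_samples is None or n_samples >= n:
        sample_idx = np.arange(n)
    else:
        if n_samples < 1:
            raise InvalidParameterError("n_samples must be positive")
        rng = np.random.default_rng(seed)
        sample_idx = np.sort(rng.choice(n, size=n_samples, replace=False))
    m_count = sample_idx.size

    class_members = {c: np.flatnonzero(y == c) for c in classes}
    weights = np.zeros(p)
    for i in sample_idx:
        diffs = np.abs(X - X[i]) / safe_span  # (n, p) normalized differences
        dist = diffs.sum(axis=1)  # Manhattan distance
        own = y[i]
        hits = class_members[own]
        hits = hits[hits != i]
        hit_near = hits[np.argsort(dist[hits], kind="stable")[:k]]
        weights -= diffs[hit_near].sum(axis=0) / (m_count * k)
        for c in classes:
            if c == own:
                continue
            misses = class_members[c]
            miss_near = misses[np.argsort(dist[misses], kind="stable")[:k]]
            factor = priors[c] / (1.0 - priors[own])
            weights += factor * diffs[miss_near].sum(axis=0) / (m_count * k)

    weights[rng_span == 0] = 0.0
    return ReliefFWeights(tuple(m.feature_names), weights, k, m_count, seed)


def select_top(w: ReliefFWeights, n: int, by_abs: bool = False) -> list[str]:
    """Top-``n`` feature names by descending weight (stable on ties).

    ``by_abs=True`` ranks by absolute weight, treating strongly negative
    weights as informative too.
    """
    if n > len(w.feature_names):
        raise InvalidParameterError(
            f"cannot select {n} of {len(w.feature_names)} features"
        )
    key = np.abs(w.weights) if by_abs else w.weights
    order = np.argsort(-key, kind="stable")
    ranked = [w.feature_names[i] for i in order]
    if len(set(np.round(key, 12))) < len(key):
        logger.info("select_top: ties broken by input column order")
    return ranked[:n]
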