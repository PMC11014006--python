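"""Tree-augmented naive Bayes (TAN) over quantile-discretized features.

A Bayesian-network classifier in the Chow-Liu tradition: each feature is
discretized into quantile bins, a maximum-spanning tree over the
class-conditional mutual information between feature pairs augments the
naive-Bayes structure with one feature parent per node, and prediction is
by posterior class probability with Laplace-smoothed conditional tables.

Exposes the small sklearn-style surface (fit / predict / predict_proba)
that the classification harness expects.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, minimum_spanning_tree

__all__ = ["TanBayesClassifier"]


def _conditional_mutual_information(xi: np.ndarray, xj: np.ndarray,
                                    y: np.ndarray, n_bins: int,
                                    n_classes: int) -> float:
    """I(Xi; Xj | Y) from empirical counts (natural log)."""
    total = 0.0
    n = y.size
    for c in range(n_classes):
        mask = y == c
        nc = int(mask.sum())
        if nc == 0:
            continue
        joint = np.zeros((n_bins, n_bins))
        np.add.at(joint, (xi[mask], xj[mask]), 1.0)
        joint /= nc
        pi = joint.sum(axis=1, keepdims=True)
        pj = joint.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(joint > 0, joint / (pi * pj), 1.0)
            total += (nc / n) * float(np.sum(joint * np.log(ratio), where=joint > 0))
    return total


class TanBayesClassifier:
    """Tree-augmented naive Bayes for binary (or small multi-class) problems."""

    def __init__(self, n_bins: int = 10, alpha: float = 1.0, random_state=None):
        self.n_bins = n_bins
        self.alpha = alpha  # Laplace smoothing count
        self.random_state = random_state  # unused; kept for a uniform surface

    # -- discretization -------------------------------------------------
    def _fit_bins(self, X: np.ndarray) -> None:
        qs = np.linspace(0, 1, self.n_bins + 1)[1:-1]
        self.bin_edges_ = [np.unique(np.quantile(X[:, j], qs)) for j in range(X.shape[1])]

    def _discretize(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape, dtype=int)
        for j, edges in enumerate(self.bin_edges_):
            out[:, j] = np.searchsorted(edges, X[:, j], side="right")
        return out

    # -- fitting ---------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, p = X.shape
        k = self.classes_.size
        self._fit_bins(X)
        D = self._discretize(X)
        b = self.n_bins

        # Chow-Liu structure: maximum spanning tree over I(Xi; Xj | Y)
        if p > 1:
            mi = np.zeros((p, p))
            for i in range(p):
                for j in range(i + 1, p):
                    mi[i, j] = _conditional_mutual_information(D[:, i], D[:, j], y_idx, b, k)
            # minimum_spanning_tree on negated weights; shift to keep edges nonzero
            graph = csr_matrix(-(mi + 1e-9))
            tree = minimum_spanning_tree(graph)
            undirected = (tree + tree.T) != 0
            order, preds = breadth_first_order(undirected, i_start=0, directed=False)
            parents = np.full(p, -1)
            for node, par in zip(order, preds[order]):
                if par >= 0:
                    parents[node] = par
        else:
            parents = np.array([-1])
        self.parents_ = parents

        a = self.alpha
        counts = np.bincount(y_idx, minlength=k).astype(float)
        self.class_log_prior_ = np.log((counts + a) / (n + a * k))
        # log P(x_j | parent value, class); root features condition on class only
        self.cpt_ = []
        for j in range(p):
            par = parents[j]
            if par < 0:
                table = np.full((k, 1, b), a)
                np.add.at(table, (y_idx, 0, D[:, j]), 1.0)
            else:
                table = np.full((k, b, b), a)
                np.add.at(table, (y_idx, D[:, par], D[:, j]), 1.0)
            table /= table.sum(axis=2, keepdims=True)
            self.cpt_.append(np.log(table))
        return self

    # -- prediction ------------------------------------------------------
    def _joint_log_likelihood(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        D = self._discretize(X)
        n, p = D.shape
        k = self.classes_.size
        ll = np.tile(self.class_log_prior_, (n, 1))
        for j in range(p):
            par = self.parents_[j]
            pv = D[:, par] if par >= 0 else np.zeros(n, dtype=int)
            for c in range(k):
                ll[:, c] += self.cpt_[j][c, pv, D[:, j]]
        return ll

    def predict_proba(self, X) -> np.ndarray:
        ll = self._joint_log_likelihood(X)
        ll -= ll.max(axis=1, keepdims=True)
        prob = np.exp(ll)
        return prob / prob.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]

    def get_params(self, deep: bool = True) -> dict:
        return {"n_bins": self.n_bins, "alpha": self.alpha,
                "random_state": self.random_state}
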