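"""Stage 3: three-state discretization and greedy mRMR feature selection.

Each feature is mapped to {-2, 0, 2} by its distance from the feature mean
in units of k standard deviations (k = 0.5 by default, population sd):
state 2 for x >= mean + k*sd, -2 for x <= mean - k*sd, 0 otherwise, with the
boundaries inclusive toward +/-2. Mutual information between discrete
vectors is the plug-in contingency-table estimate in bits. Selection is the
canonical greedy incremental mRMR ("MID" form): the first feature maximizes
relevance I(x; y); each later step maximizes relevance minus the mean
redundancy against the already selected set. Ties break toward the earlier
input column. The set-form objective with its 1/|S|^2 redundancy weight has
no tractable exact search; the greedy incremental criterion is the standard
realization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

logger = logging.getLogger(__name__)

DEFAULT_K = 0.5
STATES = (-2, 0, 2)


def discretize(
    X: np.ndarray,
    k: float = DEFAULT_K,
    fit_stats: tuple[np.ndarray, np.ndarray] | None = None,
    ddof: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map a samples-by-features real matrix onto states {-2, 0, 2}.

    Returns ``(states, means, sds)``. When ``fit_stats=(means, sds)`` is
    given, those statistics are used instead of being recomputed — the
    held-out transform. A zero-variance feature collapses to all zeros
    (delta = 0 makes both inequalities hit the mean; the tie resolves to the
    uninformative middle state).
    """
    X = np.asarray(X, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    if fit_stats is not None:
        means, sds = (np.asarray(a, dtype=float) for a in fit_stats)
    else:
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=ddof)
    states = np.zeros(X.shape, dtype=np.int8)
    hi = X >= means + k * sds
    lo = X <= means - k * sds
    states[hi] = 2
    states[lo] = -2
    zero_var = sds == 0
    if zero_var.any():
        states[:, zero_var] = 0
        logger.debug("discretize: %d zero-variance features set to 0", int(zero_var.sum()))
    return states, means, sds


class ThreeStateDiscretizer(TransformerMixin, BaseEstimator):
    """Per-feature mean +/- k*sd discretizer onto {-2, 0, 2}.

    Fit records each feature's mean and (population, unless ``ddof=1``)
    standard deviation; transform applies the recorded thresholds, so
    held-out samples are discretized with the fitting statistics.
    """

    def __init__(self, k: float = DEFAULT_K, ddof: int = 0):
        self.k = k
        self.ddof = ddof

    def fit(self, X, y=None):
        X = validate_data(self, X, dtype=float)
        _, self.means_, self.sds_ = discretize(X, k=self.k, ddof=self.ddof)
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, dtype=float, reset=False)
        states, _, _ = discretize(X, k=self.k, fit_stats=(self.means_, self.sds_))
        return states


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information between two discrete vectors, in bits.

    ``sum_xy p(x,y) log2(p(x,y) / (p(x) p(y)))`` over the observed joint
    contingency table, with 0*log(0) = 0; tiny negative rounding is clamped
    to zero.
    """
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("vectors must be non-empty")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    joint = np.zeros((ai.max() + 1, bi.max() + 1), dtype=float)
    np.add.at(joint, (ai, bi), 1.0)
    pxy = joint / a.size
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    mi = float((pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz])).sum())
    return max(mi, 0.0)


def _mi_against(column: np.ndarray, X: np.ndarray) -> np.ndarray:
    """MI of one discrete vector against every column of a discrete matrix."""
    return np.array([mutual_information(column, X[:, j]) for j in range(X.shape[1])])


@dataclass
class MrmrResult:
    """Greedy selection trace: chosen columns, per-step scores, relevances."""

    selected: list[int]
    step_scores: list[float]
    relevance: np.ndarray


def mrmr_select(states: np.ndarray, y: np.ndarray, n: int) -> MrmrResult:
    """Greedy incremental mRMR over a discrete samples-by-features matrix.

    The first pick maximizes relevance I(x; y); step t maximizes
    ``I(x; y) - (1/|S|) * sum_{s in S} I(x; x_s)`` over unselected columns.
    Ties break toward the smaller column index; the per-step best score is
    recorded. ``y`` is used directly as a finite alphabet (e.g. {-1, +1}).
    """
    states = np.asarray(states)
    y = np.asarray(y)
    n_features = states.shape[1]
    if n > n_features:
        raise ValueError(f"cannot select {n} of {n_features} features")
    if n < 1:
        raise ValueError("n must be at least 1")
    relevance = _mi_against(y, states)
    selected: list[int] = []
    step_scores: list[float] = []
    redundancy_sum = np.zeros(n_features, dtype=float)
    available = np.ones(n_features, dtype=bool)
    for _ in range(n):
        if selected:
            scores = relevance - redundancy_sum / len(selected)
        else:
            scores = relevance.copy()
        scores[~available] = -np.inf
        pick = int(np.argmax(scores))  # argmax keeps the first (lowest) index on ties
        selected.append(pick)
        step_scores.append(float(scores[pick]))
        available[pick] = False
        if len(selected) < n:
            redundancy_sum += _mi_against(states[:, pick], states)
    return MrmrResult(selected, step_scores, relevance)


class MRMRSelector(SelectorMixin, BaseEstimator):
    """Discretize-then-mRMR feature selector.

    Fit discretizes X with the three-state rule (statistics recorded for
    held-out use) and runs the greedy selection against the class labels.

    Attributes
    ----------
    selected_ : list of int
        Column indices in selection order.
    step_scores_ : list of float
        Relevance-minus-mean-redundancy score at each pick.
    relevance_ : ndarray
        I(x; y) in bits per candidate column.
    """

    def __init__(self, n_features: int = 10, k: float = DEFAULT_K, ddof: int = 0):
        self.n_features = n_features
        self.k = k
        self.ddof = ddof

    def fit(self, X, y):
        X, y = validate_data(self, X, y, dtype=float)
        self.discretizer_ = ThreeStateDiscretizer(k=self.k, ddof=self.ddof).fit(X)
        states = self.discretizer_.transform(X)
        result = mrmr_select(states, y, min(self.n_features, X.shape[1]))
        self.selected_ = result.selected
        self.step_scores_ = result.step_scores
        self.relevance_ = result.relevance
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[result.selected] = True
        self.support_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


__all__ = [
    "discretize",
    "ThreeStateDiscretizer",
    "mutual_information",
    "mrmr_select",
    "MrmrResult",
    "MRMRSelector",
    "DEFAULT_K",
    "STATES",
]
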