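"""Shared fixtures: small synthetic cohorts and instrumented stub learners."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin

from triostack import (
    SyntheticSpec,
    aggregate_cpg_to_genes,
    build_design,
    make_probe_gene_map,
    simulate_triple,
)


@pytest.fixture(scope="session")
def tiny_spec():
    """Desk-scale cohort small enough for fast end-to-end tests."""
    return SyntheticSpec(
        n_tumor=30,
        n_normal=12,
        n_pc=150,
        n_nc=80,
        n_genes_meth=40,
        d_pc=6,
        d_nc=4,
        d_meth=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    dataset, truth = simulate_triple(tiny_spec)
    return dataset, truth


@pytest.fixture(scope="session")
def tiny_design(tiny_spec, tiny_dataset):
    dataset, truth = tiny_dataset
    pmap = make_probe_gene_map(tiny_spec)
    aggregated = dataset.with_meth(aggregate_cpg_to_genes(dataset.meth, pmap))
    return build_design(aggregated), truth


class ConstantProbLearner(ClassifierMixin, BaseEstimator):
    """Stub that always reports the same positive-class probability."""

    def __init__(self, p: float = 0.7):
        self.p = p

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict_proba(self, X):
        n = len(X)
        return np.column_stack([np.full(n, 1 - self.p), np.full(n, self.p)])

    def predict(self, X):
        return np.full(len(X), self.classes_[-1])


class IndexProbLearner(ClassifierMixin, BaseEstimator):
    """Stub whose probability is a deterministic function of a sample's own
    identity carried in column 0: p = (id mod 10) / 10."""

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict_proba(self, X):
        p = (np.asarray(X)[:, 0] % 10) / 10.0
        return np.column_stack([1 - p, p])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return np.where(p >= 0.5, self.classes_[-1], self.classes_[0])


class RecordingLearner(ClassifierMixin, BaseEstimator):
    """Stub that records which sample IDs (column 0) each fitted model saw,
    and logs a violation whenever it is asked to predict one of them.

    Class-level logs survive sklearn's clone (which deep-copies parameters).
    """

    violations: list = []
    n_predictions: int = 0

    @classmethod
    def reset(cls):
        cls.violations = []
        cls.n_predictions = 0

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        self.seen_ = set(np.asarray(X)[:, 0].astype(int))
        return self

    def predict_proba(self, X):
        ids = np.asarray(X)[:, 0].astype(int)
        overlap = set(ids) & self.seen_
        if overlap:
            RecordingLearner.violations.append(overlap)
        RecordingLearner.n_predictions += len(ids)
        p = np.full(len(ids), 0.5)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return np.full(len(X), self.classes_[-1])
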