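"""Per-fold diagnosis model: differential filter -> mRMR -> stacked ensemble.

:class:`DiagnosisPipeline` is the supervised model trained inside every
outer cross-validation fold. All label-dependent steps (stage-2 screening
statistics, mRMR discretization thresholds and mutual informations, base
learner tuning, meta-learning) are fit on the learning partition only, so
held-out folds stay untouched. The unsupervised steps — CpG-to-gene
aggregation, quantile normalization — run once, globally, before folds are
drawn (see :func:`build_design`).

Count-scale features enter the classifiers and the discretizer on the
log2(x+1) scale; fold changes are computed on the raw linear scale; beta
features are used as-is everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .containers import BETA, METHYLATED_GENE, TripleDataset
from .differential import DEFAULT_FDR, DifferentialFilter
from .ensemble import DEFAULT_INNER_FOLDS, META_GRID, SecondLearningEnsemble
from .mrmr import DEFAULT_K, MRMRSelector

logger = logging.getLogger(__name__)


@dataclass
class Design:
    """Flattened samples-by-features view of a (possibly subset) triple dataset."""

    X: np.ndarray
    y: np.ndarray
    feature_ids: np.ndarray
    feature_types: np.ndarray
    feature_scales: np.ndarray
    sample_ids: list[str]


def build_design(dataset: TripleDataset, use_blocks=("pc", "nc", "meth")) -> Design:
    """Concatenate the requested blocks into one samples-by-features matrix.

    The methylation block is expected at whatever granularity the caller
    chose (gene level after aggregation, probe level without it). Feature
    scale tags ('counts' / 'beta') follow each block's data scale.
    """
    mats, ids, types, scales = [], [], [], []
    for name in use_blocks:
        block = dataset.blocks[name]
        mats.append(block.values.to_numpy(dtype=float).T)
        ids.append(block.feature_ids.to_numpy(dtype=object))
        types.append(block.feature_types.to_numpy(dtype=object))
        scales.append(np.full(block.n_features, block.data_scale, dtype=object))
    return Design(
        X=np.hstack(mats),
        y=np.asarray(dataset.y, dtype=int),
        feature_ids=np.concatenate(ids),
        feature_types=np.concatenate(types),
        feature_scales=np.concatenate(scales),
        sample_ids=list(dataset.sample_ids),
    )


def modeling_scale(X: np.ndarray, feature_scales: np.ndarray) -> np.ndarray:
    """log2(x+1)-transform count columns; beta columns pass through."""
    X = np.asarray(X, dtype=float)
    is_beta = np.asarray(feature_scales, dtype=object) == BETA
    return np.where(is_beta[None, :], X, np.log2(X + 1.0))


class DiagnosisPipeline(ClassifierMixin, BaseEstimator):
    """Hierarchical feature selection plus probability-stacking classifier.

    fit() screens features by fold change and FDR (stage 2), selects the
    final compact subset with discretized greedy mRMR (stage 3), then trains
    the four-learner stacking ensemble on the selected continuous features.

    Parameters mirror the stage modules; ``feature_types`` and
    ``feature_scales`` are arrays aligned to the columns of X.

    Attributes
    ----------
    selected_idx_ : ndarray — final column indices, in mRMR pick order.
    selected_ids_ : ndarray — their feature IDs (when IDs were given).
    selected_types_ : ndarray — their feature type tags.
    diff_ : fitted DifferentialFilter; mrmr_ : fitted MRMRSelector;
    ensemble_ : fitted SecondLearningEnsemble.
    """

    def __init__(
        self,
        feature_types=None,
        feature_scales=None,
        feature_ids=None,
        log2fc_thresholds=None,
        fdr: float = DEFAULT_FDR,
        pseudocount: float = 1.0,
        test: str = "welch_t",
        pooling: str = "by_block",
        n_features: int = 10,
        k: float = DEFAULT_K,
        base_learners=None,
        n_inner: int = DEFAULT_INNER_FOLDS,
        meta_grid: tuple[int, ...] = META_GRID,
        threshold: float = 0.5,
        stratify_inner: bool = False,
        random_state: int | None = None,
    ):
        self.feature_types = feature_types
        self.feature_scales = feature_scales
        self.feature_ids = feature_ids
        self.log2fc_thresholds = log2fc_thresholds
        self.fdr = fdr
        self.pseudocount = pseudocount
        self.test = test
        self.pooling = pooling
        self.n_features = n_features
        self.k = k
        self.base_learners = base_learners
        self.n_inner = n_inner
        self.meta_grid = meta_grid
        self.threshold = threshold
        self.stratify_inner = stratify_inner
        self.random_state = random_state

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame) and self.feature_ids is None:
            self._ids = X.columns.to_numpy(dtype=object)
        else:
            self._ids = None
        X, y = validate_data(self, X, y, dtype=float)
        self.classes_ = np.unique(y)
        n_total = X.shape[1]
        ids = (
            np.asarray(self.feature_ids, dtype=object)
            if self.feature_ids is not None
            else (self._ids if self._ids is not None else np.arange(n_total).astype(str))
        )

        self.diff_ = DifferentialFilter(
            feature_types=self.feature_types,
            feature_scales=self.feature_scales,
            log2fc_thresholds=self.log2fc_thresholds,
            fdr=self.fdr,
            pseudocount=self.pseudocount,
            test=self.test,
            pooling=self.pooling,
        ).fit(X, y)
        stage2 = self.diff_.support_.copy()
        if not stage2.any():
            # weak-signal fallback: keep the model usable by ranking on q
            logger.warning(
                "stage 2 selected no feature; falling back to the %d smallest q-values",
                self.n_features,
            )
            order = np.argsort(self.diff_.records_["q_value"].to_numpy(), kind="stable")
            stage2[order[: self.n_features]] = True
        stage2_idx = np.flatnonzero(stage2)

        scales = (
            np.asarray(self.feature_scales, dtype=object)
            if self.feature_scales is not None
            else np.full(n_total, "counts", dtype=object)
        )
        Xm = modeling_scale(X, scales)[:, stage2_idx]

        n_sel = min(self.n_features, len(stage2_idx))
        if n_sel < self.n_features:
            logger.warning(
                "only %d features survive stage 2; selecting all of them", n_sel
            )
        self.mrmr_ = MRMRSelector(n_features=n_sel, k=self.k).fit(Xm, y)
        self.selected_idx_ = stage2_idx[np.asarray(self.mrmr_.selected_, dtype=int)]
        self.selected_ids_ = ids[self.selected_idx_]
        ftypes = (
            np.asarray(self.feature_types, dtype=object)
            if self.feature_types is not None
            else np.full(n_total, "protein_coding", dtype=object)
        )
        self.selected_types_ = ftypes[self.selected_idx_]
        self._scales = scales

        self.ensemble_ = SecondLearningEnsemble(
            base_learners=self.base_learners,
            n_inner=self.n_inner,
            meta_grid=self.meta_grid,
            threshold=self.threshold,
            stratify_inner=self.stratify_inner,
            random_state=self.random_state,
        ).fit(modeling_scale(X, scales)[:, self.selected_idx_], y)
        logger.info(
            "pipeline: %d -> %d (stage 2) -> %d (mRMR) features",
            n_total, len(stage2_idx), len(self.selected_idx_),
        )
        return self

    def _check_columns(self, X):
        if isinstance(X, pd.DataFrame) and self._ids is not None:
            missing = [fid for fid in self.selected_ids_ if fid not in X.columns]
            if missing:
                raise ValueError(f"samples are missing selected features: {missing}")

    def predict_proba(self, X):
        check_is_fitted(self)
        self._check_columns(X)
        X = validate_data(self, X, dtype=float, reset=False)
        Xs = modeling_scale(X, self._scales)[:, self.selected_idx_]
        return self.ensemble_.predict_proba(Xs)

    def predict(self, X):
        proba = self.predict_proba(X)[:, 1]
        return np.where(proba >= self.threshold, self.classes_[1], self.classes_[0])


__all__ = ["Design", "build_design", "modeling_scale", "DiagnosisPipeline"]
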