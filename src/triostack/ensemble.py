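"""Second-learning probability ensemble over four heterogeneous classifiers.

Four base learners with complementary biases — an RBF-kernel SVM, a decision
tree, a random forest and AdaBoost — are tuned by grid search on inner
cross-validation folds, then their *out-of-fold* positive-class
probabilities on the learning set are stacked into a 4-column meta dataset
joined with the true labels. A gradient-boosted tree classifier (XGBoost) is
trained on that meta dataset: because boosting fits each round to the
residual of the previous rounds, it learns the probability errors the base
classifiers make and corrects them. At prediction time the base learners
(refit on the full learning set with their tuned parameters) produce four
probabilities per sample and the meta-learner maps them to the final
probability; the label is positive iff that probability reaches the
decision threshold (0.5 by default).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, validate_data
from xgboost import XGBClassifier

logger = logging.getLogger(__name__)

#: default hyper-parameter grids for the four base learners
SVM_GRID = {"C": [0.001, 0.01, 0.1], "gamma": [1.0, 10.0, 100.0]}
RF_GRID = {"n_estimators": [50, 100]}
ADABOOST_N_ESTIMATORS = 50
META_GRID = (100, 200, 300)
DEFAULT_INNER_FOLDS = 5


# ---------------------------------------------------------------------------
# fold plans
# ---------------------------------------------------------------------------

def _partition(
    indices: np.ndarray, n_folds: int, rng: np.random.Generator,
    y: np.ndarray | None = None, stratify: bool = False,
) -> list[np.ndarray]:
    """Split ``indices`` into ``n_folds`` disjoint groups, sizes differing <=1."""
    indices = np.asarray(indices)
    if n_folds > indices.size:
        raise ValueError(f"{n_folds} folds for {indices.size} samples")
    if stratify:
        if y is None:
            raise ValueError("stratified partition needs labels")
        y = np.asarray(y)
        pooled = []
        for cls in np.unique(y):
            cls_idx = indices[y == cls]
            pooled.append(rng.permutation(cls_idx))
        stream = np.concatenate(pooled)
        folds = [stream[f::n_folds] for f in range(n_folds)]
    else:
        folds = np.array_split(rng.permutation(indices), n_folds)
    return [np.sort(f) for f in folds]


@dataclass
class FoldPlan:
    """Outer test-fold partition plus an inner partition per learning set.

    ``outer_folds[f]`` holds the sample indices tested in fold f;
    ``inner_folds[f]`` partitions fold f's learning set (the complement)
    into K validating subsets, all in original index space. Reproducible
    from the seed.
    """

    outer_folds: list[np.ndarray]
    inner_folds: list[list[np.ndarray]]
    seed: int
    n_outer: int
    n_inner: int

    def learning_set(self, f: int) -> np.ndarray:
        n = sum(len(fold) for fold in self.outer_folds)
        mask = np.ones(n, dtype=bool)
        mask[self.outer_folds[f]] = False
        return np.flatnonzero(mask)


def make_fold_plan(
    n_samples: int,
    n_outer: int = 10,
    n_inner: int = DEFAULT_INNER_FOLDS,
    seed: int = 0,
    stratify: bool = False,
    y: np.ndarray | None = None,
) -> FoldPlan:
    """Randomly partition samples into F outer folds and K inner subsets each.

    Outer folds have sizes differing by at most one; every sample lands in
    exactly one outer test fold. Inner subsets partition each outer learning
    set the same way. Deterministic for a given seed; the stratified option
    preserves class ratios per fold.
    """
    if n_outer < 2 or n_inner < 2:
        raise ValueError("need at least 2 outer and 2 inner folds")
    if n_outer > n_samples:
        raise ValueError(f"{n_outer} folds for {n_samples} samples")
    ss = np.random.SeedSequence(seed)
    outer_rng = np.random.default_rng(ss.spawn(1)[0])
    all_idx = np.arange(n_samples)
    outer = _partition(all_idx, n_outer, outer_rng, y=y, stratify=stratify)
    inner: list[list[np.ndarray]] = []
    for f in range(n_outer):
        mask = np.ones(n_samples, dtype=bool)
        mask[outer[f]] = False
        learn = np.flatnonzero(mask)
        child = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1, f)))
        y_learn = y[learn] if (stratify and y is not None) else None
        inner.append(_partition(learn, n_inner, child, y=y_learn, stratify=stratify))
    return FoldPlan(outer, inner, seed, n_outer, n_inner)


# ---------------------------------------------------------------------------
# base learners
# ---------------------------------------------------------------------------

def default_base_learners(random_state: int | None = None) -> list[tuple[str, BaseEstimator, dict]]:
    """The four heterogeneous base classifiers with their default grids.

    SVM runs in probability mode (Platt-style calibration) so it can feed
    the probability-stacking step; the decision tree uses library defaults.
    """
    return [
        (
            "svm_rbf",
            SVC(kernel="rbf", probability=True, random_state=random_state),
            dict(SVM_GRID),
        ),
        ("decision_tree", DecisionTreeClassifier(random_state=random_state), {}),
        (
            "random_forest",
            RandomForestClassifier(random_state=random_state),
            dict(RF_GRID),
        ),
        (
            "adaboost",
            AdaBoostClassifier(n_estimators=ADABOOST_N_ESTIMATORS, random_state=random_state),
            {},
        ),
    ]


def _grid_points(grid: dict) -> list[dict]:
    if not grid:
        return [{}]
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def tune_base_learner(
    estimator: BaseEstimator,
    grid: dict,
    X: np.ndarray,
    y: np.ndarray,
    val_folds: list[np.ndarray],
) -> tuple[dict, list[tuple[dict, float]]]:
    """Pick the grid point with the best mean inner-CV accuracy.

    Each grid point is scored by training on the complement of every
    validating subset and averaging held-out accuracy; ties go to the first
    point in declared grid order. A singleton grid is returned without any
    CV. A grid point whose fit fails scores 0 with a warning.
    """
    points = _grid_points(grid)
    if len(points) == 1:
        return points[0], [(points[0], float("nan"))]
    n = len(y)
    trace = []
    best_params, best_score = None, -np.inf
    for params in points:
        accs = []
        for val_idx in val_folds:
            mask = np.ones(n, dtype=bool)
            mask[val_idx] = False
            est = clone(estimator).set_params(**params)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(X[mask], y[mask])
                accs.append(float(np.mean(est.predict(X[val_idx]) == y[val_idx])))
            except Exception as exc:  # noqa: BLE001 - scored as failure, not fatal
                logger.warning("grid point %s failed (%s); scored 0", params, exc)
                accs.append(0.0)
        score = float(np.mean(accs))
        trace.append((params, score))
        if score > best_score:
            best_params, best_score = params, score
    return best_params, trace


def build_meta_dataset(
    X: np.ndarray,
    y: np.ndarray,
    learners: list[tuple[str, BaseEstimator]],
    val_folds: list[np.ndarray],
    positive_class=1,
) -> pd.DataFrame:
    """Stack out-of-fold positive-class probabilities into the meta dataset.

    For every validating subset, each (already tuned, unfitted) base learner
    is trained on the other subsets and predicts class probabilities on the
    held-out one; stacking all subsets yields one probability row per
    learning-set sample, in original row order, joined with the true label.
    No row is ever predicted by a model trained on it.
    """
    n = len(y)
    cols = {name: np.full(n, np.nan) for name, _ in learners}
    for name, est in learners:
        if not hasattr(est, "predict_proba"):
            raise ValueError(
                f"base learner {name!r} lacks probability outputs (predict_proba)"
            )
    covered = np.zeros(n, dtype=bool)
    for val_idx in val_folds:
        mask = np.ones(n, dtype=bool)
        mask[val_idx] = False
        for name, est in learners:
            model = clone(est)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[mask], y[mask])
            proba = model.predict_proba(X[val_idx])
            pos = np.flatnonzero(model.classes_ == positive_class)
            # a model that saw a single training class is certain of it
            cols[name][val_idx] = proba[:, int(pos[0])] if pos.size else 0.0
        covered[val_idx] = True
    if not covered.all():
        raise ValueError("validating subsets do not cover the learning set")
    meta = pd.DataFrame(cols)
    meta["label"] = np.asarray(y)
    return meta


def train_meta(
    meta: pd.DataFrame,
    grid: tuple[int, ...] = META_GRID,
    val_folds: list[np.ndarray] | None = None,
    random_state: int | None = None,
) -> XGBClassifier:
    """Fit the gradient-boosted meta-learner on the probability columns.

    ``n_estimators`` is chosen from the grid by mean inner-CV accuracy on
    the meta dataset (ties to the first grid value); labels are mapped
    {-1 -> 0, +1 -> 1} internally. Raises on single-class labels.
    """
    Xm = meta.drop(columns=["label"]).to_numpy(dtype=float)
    y = meta["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("meta dataset labels contain a single class")
    y01 = (y == 1).astype(int)

    def make(n_est):
        return XGBClassifier(
            n_estimators=n_est,
            random_state=random_state or 0,
            n_jobs=1,
            verbosity=0,
            eval_metric="logloss",
        )

    grid = tuple(grid)
    if len(grid) == 1 or val_folds is None:
        best = grid[0]
    else:
        best, best_score = None, -np.inf
        for n_est in grid:
            accs = []
            for val_idx in val_folds:
                mask = np.ones(len(y), dtype=bool)
                mask[val_idx] = False
                if len(np.unique(y01[mask])) < 2:
                    accs.append(0.0)
                    continue
                model = make(n_est).fit(Xm[mask], y01[mask])
                accs.append(float(np.mean(model.predict(Xm[val_idx]) == y01[val_idx])))
            score = float(np.mean(accs))
            if score > best_score:
                best, best_score = n_est, score
    model = make(best).fit(Xm, y01)
    return model


# ---------------------------------------------------------------------------
# the stacked classifier
# ---------------------------------------------------------------------------

class SecondLearningEnsemble(ClassifierMixin, BaseEstimator):
    """Probability-stacking ensemble of four heterogeneous classifiers.

    fit() tunes each base learner by grid search over inner CV subsets of
    the learning set, builds the out-of-fold probability meta dataset, fits
    the boosted-tree meta-learner on it, and refits the tuned base learners
    on the full learning set for prediction.

    Parameters
    ----------
    base_learners : list of (name, estimator, grid), optional
        Defaults to the canonical four (RBF SVM, decision tree, random
        forest, AdaBoost) with their default grids. Estimators must expose
        ``predict_proba``.
    n_inner : int, default 5
        Number of inner validating subsets K.
    meta_grid : tuple of int, default (100, 200, 300)
        ``n_estimators`` candidates for the meta-learner.
    threshold : float, default 0.5
        Positive iff the meta probability >= threshold.
    stratify_inner : bool, default False
        Stratify the inner partition by class.
    random_state : int, optional
        Seeds the inner partition and every stochastic learner.

    Attributes
    ----------
    classes_ : ndarray — sorted class labels (positive class is the larger).
    base_params_ : dict — tuned grid point per base learner.
    tuning_trace_ : dict — (params, mean accuracy) pairs per base learner.
    meta_dataset_ : DataFrame — out-of-fold probabilities + true labels.
    meta_model_ : fitted XGBClassifier.
    base_models_ : list of (name, fitted estimator) on the full learning set.
    """

    def __init__(
        self,
        base_learners=None,
        n_inner: int = DEFAULT_INNER_FOLDS,
        meta_grid: tuple[int, ...] = META_GRID,
        threshold: float = 0.5,
        stratify_inner: bool = False,
        random_state: int | None = None,
    ):
        self.base_learners = base_learners
        self.n_inner = n_inner
        self.meta_grid = meta_grid
        self.threshold = threshold
        self.stratify_inner = stratify_inner
        self.random_state = random_state

    def _learners(self):
        if self.base_learners is not None:
            return [(n, e, dict(g)) for n, e, g in self.base_learners]
        return default_base_learners(self.random_state)

    def fit(self, X, y):
        X, y = validate_data(self, X, y, dtype=float)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("the ensemble is a two-class diagnosis model")
        positive = self.classes_[1]
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self.random_state or 0, spawn_key=(2,))
        )
        val_folds = _partition(
            np.arange(len(y)), self.n_inner, rng,
            y=y if self.stratify_inner else None, stratify=self.stratify_inner,
        )
        self.inner_folds_ = val_folds

        self.base_params_ = {}
        self.tuning_trace_ = {}
        tuned = []
        for name, est, grid in self._learners():
            params, trace = tune_base_learner(est, grid, X, y, val_folds)
            self.base_params_[name] = params
            self.tuning_trace_[name] = trace
            tuned.append((name, clone(est).set_params(**params)))

        self.meta_dataset_ = build_meta_dataset(
            X, y, tuned, val_folds, positive_class=positive
        )
        meta = self.meta_dataset_.copy()
        meta["label"] = (meta["label"] == positive).astype(int) * 2 - 1
        self.meta_model_ = train_meta(
            meta, self.meta_grid, val_folds, random_state=self.random_state
        )
        self.base_models_ = []
        for name, est in tuned:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self.base_models_.append((name, est.fit(X, y)))
        return self

    def _base_probabilities(self, X) -> np.ndarray:
        positive = self.classes_[1]
        cols = []
        for _, model in self.base_models_:
            proba = model.predict_proba(X)
            pos_col = int(np.flatnonzero(model.classes_ == positive)[0])
            cols.append(proba[:, pos_col])
        return np.column_stack(cols)

    def predict_proba(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, dtype=float, reset=False)
        base = self._base_probabilities(X)
        pos = self.meta_model_.predict_proba(base)[:, 1]
        return np.column_stack([1.0 - pos, pos])

    def predict(self, X):
        proba = self.predict_proba(X)[:, 1]
        return np.where(proba >= self.threshold, self.classes_[1], self.classes_[0])


__all__ = [
    "FoldPlan",
    "make_fold_plan",
    "default_base_learners",
    "tune_base_learner",
    "build_meta_dataset",
    "train_meta",
    "SecondLearningEnsemble",
    "SVM_GRID",
    "RF_GRID",
    "ADABOOST_N_ESTIMATORS",
    "META_GRID",
    "DEFAULT_INNER_FOLDS",
]
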