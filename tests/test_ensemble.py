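"""Fold plans, grid tuning, meta-dataset stacking and the ensemble classifier."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.tree import DecisionTreeClassifier

from conftest import ConstantProbLearner, IndexProbLearner, RecordingLearner
from triostack import SecondLearningEnsemble, make_fold_plan
from triostack.ensemble import build_meta_dataset, train_meta, tune_base_learner


# ---------------------------------------------------------------------------
# fold plans
# ---------------------------------------------------------------------------

def test_equal_fold_sizes():
    plan = make_fold_plan(20, n_outer=10, n_inner=2, seed=0)
    assert [len(f) for f in plan.outer_folds] == [2] * 10


def test_uneven_fold_sizes_differ_by_at_most_one():
    plan = make_fold_plan(103, n_outer=10, n_inner=5, seed=1)
    sizes = sorted(len(f) for f in plan.outer_folds)
    assert sizes == [10] * 7 + [11] * 3


def test_plan_is_deterministic():
    a = make_fold_plan(37, n_outer=5, n_inner=3, seed=42)
    b = make_fold_plan(37, n_outer=5, n_inner=3, seed=42)
    for fa, fb in zip(a.outer_folds, b.outer_folds):
        np.testing.assert_array_equal(fa, fb)
    for ia, ib in zip(a.inner_folds, b.inner_folds):
        for sa, sb in zip(ia, ib):
            np.testing.assert_array_equal(sa, sb)


def test_plan_partitions_samples():
    plan = make_fold_plan(37, n_outer=5, n_inner=3, seed=3)
    all_idx = np.sort(np.concatenate(plan.outer_folds))
    np.testing.assert_array_equal(all_idx, np.arange(37))
    for f in range(5):
        learn = plan.learning_set(f)
        inner_all = np.sort(np.concatenate(plan.inner_folds[f]))
        np.testing.assert_array_equal(inner_all, learn)


def test_too_many_folds_error():
    with pytest.raises(ValueError):
        make_fold_plan(5, n_outer=10, n_inner=2, seed=0)


def test_stratified_plan_preserves_class_ratios():
    y = np.array([1] * 40 + [-1] * 10)
    plan = make_fold_plan(50, n_outer=5, n_inner=2, seed=7, stratify=True, y=y)
    for fold in plan.outer_folds:
        assert (y[fold] == -1).sum() == 2  # 10 normals spread over 5 folds


# ---------------------------------------------------------------------------
# grid tuning
# ---------------------------------------------------------------------------

def separable_data(n=24, seed=0):
    rng = np.random.default_rng(seed)
    y = np.where(np.arange(n) % 2 == 0, 1, -1)  # interleaved classes
    X = rng.normal(size=(n, 3))
    X[:, 0] += np.where(y == 1, 4.0, -4.0)
    return X, y


def test_singleton_grid_returned_without_cv():
    X, y = separable_data()
    params, trace = tune_base_learner(
        DecisionTreeClassifier(), {"max_depth": [2]}, X, y, val_folds=[]
    )
    assert params == {"max_depth": 2}
    assert len(trace) == 1


def test_winning_grid_point_on_separable_data():
    X, y = separable_data()
    folds = [np.arange(0, 12), np.arange(12, 24)]
    params, trace = tune_base_learner(
        DecisionTreeClassifier(random_state=0),
        {"max_depth": [1, 2]},
        X, y, folds,
    )
    assert params["max_depth"] == 1  # a depth-1 tree already separates; ties -> first
    assert all(s == 1.0 for _, s in trace)


def test_tuning_matches_independent_grid_loop():
    rng = np.random.default_rng(15)
    X = rng.normal(size=(30, 4))
    y = np.where(X[:, 1] + 0.3 * rng.normal(size=30) > 0, 1, -1)
    plan = make_fold_plan(30, n_outer=2, n_inner=3, seed=5)
    folds = plan.inner_folds[0]
    folds = [f for f in folds]
    grid = {"max_depth": [1, 2, 3]}
    est = DecisionTreeClassifier(random_state=0)
    params, trace = tune_base_learner(est, grid, X, y, folds)
    # oracle: independent loop over the grid with the same folds
    best, best_acc = None, -1.0
    for depth in grid["max_depth"]:
        accs = []
        for val in folds:
            mask = np.ones(30, dtype=bool)
            mask[val] = False
            model = DecisionTreeClassifier(random_state=0, max_depth=depth)
            model.fit(X[mask], y[mask])
            accs.append(np.mean(model.predict(X[val]) == y[val]))
        if np.mean(accs) > best_acc:
            best, best_acc = depth, float(np.mean(accs))
    assert params == {"max_depth": best}
    assert abs(dict((tuple(p.items()), s) for p, s in trace)[(("max_depth", best),)] - best_acc) < 1e-12


# ---------------------------------------------------------------------------
# meta dataset
# ---------------------------------------------------------------------------

def test_constant_stub_probabilities_pass_through():
    X, y = separable_data(20)
    folds = [np.arange(0, 10), np.arange(10, 20)]
    meta = build_meta_dataset(X, y, [("c", ConstantProbLearner(0.7))], folds)
    assert (meta["c"] == 0.7).all()
    np.testing.assert_array_equal(meta["label"].to_numpy(), y)


def test_leave_one_out_meta_rows_out_of_fold():
    n = 6
    X = np.arange(n, dtype=float).reshape(-1, 1)
    y = np.array([1, -1, 1, -1, 1, -1])
    folds = [np.array([i]) for i in range(n)]
    RecordingLearner.reset()
    meta = build_meta_dataset(X, y, [("rec", RecordingLearner())], folds)
    assert RecordingLearner.violations == []
    assert RecordingLearner.n_predictions == n
    assert len(meta) == n


def test_deterministic_index_stub_meta_table():
    n = 12
    X = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    y = np.where(np.arange(n) % 2 == 0, 1, -1)
    folds = [np.arange(0, 6), np.arange(6, 12)]
    meta = build_meta_dataset(X, y, [("idx", IndexProbLearner())], folds)
    expected = (np.arange(n) % 10) / 10.0  # hand-written expected table
    np.testing.assert_allclose(meta["idx"].to_numpy(), expected)


def test_learner_without_predict_proba_named_in_error():
    from sklearn.svm import SVC

    X, y = separable_data(20)
    folds = [np.arange(0, 10), np.arange(10, 20)]
    with pytest.raises(ValueError, match="svm_noproba"):
        build_meta_dataset(X, y, [("svm_noproba", SVC(probability=False))], folds)


# ---------------------------------------------------------------------------
# meta learner
# ---------------------------------------------------------------------------

def _meta_frame(cols, y):
    import pandas as pd

    frame = pd.DataFrame(cols)
    frame["label"] = y
    return frame


def test_perfect_meta_feature_reaches_full_training_accuracy():
    y = np.array([1, -1, 1, -1] * 5)
    meta = _meta_frame({"a": (y == 1).astype(float), "b": np.full(20, 0.5)}, y)
    model = train_meta(meta, grid=(50,), random_state=0)
    pred = model.predict(meta[["a", "b"]].to_numpy())
    np.testing.assert_array_equal(pred, (y == 1).astype(int))


def test_constant_meta_columns_fall_back_to_majority():
    y = np.array([1] * 14 + [-1] * 6)
    meta = _meta_frame({"a": np.full(20, 0.5), "b": np.full(20, 0.5)}, y)
    model = train_meta(meta, grid=(50,), random_state=0)
    pred = model.predict(meta[["a", "b"]].to_numpy())
    assert (pred == 1).all()


def test_single_class_meta_error():
    y = np.ones(10, dtype=int)
    meta = _meta_frame({"a": np.full(10, 0.5)}, y)
    with pytest.raises(ValueError, match="single class"):
        train_meta(meta)


def test_meta_training_is_reproducible():
    rng = np.random.default_rng(3)
    y = rng.choice([-1, 1], size=40)
    cols = {f"c{i}": rng.uniform(size=40) for i in range(4)}
    folds = [np.arange(0, 20), np.arange(20, 40)]
    m1 = train_meta(_meta_frame(cols, y), val_folds=folds, random_state=5)
    m2 = train_meta(_meta_frame(cols, y), val_folds=folds, random_state=5)
    X = np.column_stack(list(cols.values()))
    np.testing.assert_array_equal(m1.predict_proba(X), m2.predict_proba(X))


# ---------------------------------------------------------------------------
# the stacked classifier
# ---------------------------------------------------------------------------

def test_ensemble_separates_clean_data():
    X, y = separable_data(n=40, seed=2)
    clf = SecondLearningEnsemble(n_inner=4, meta_grid=(50,), random_state=0).fit(X, y)
    X_test, y_test = separable_data(n=20, seed=9)
    assert (clf.predict(X_test) == y_test).all()
    proba = clf.predict_proba(X_test)
    assert proba.shape == (20, 2)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0)
    assert set(clf.base_params_) == {"svm_rbf", "decision_tree", "random_forest", "adaboost"}
    assert clf.meta_dataset_.shape == (40, 5)


def test_ensemble_out_of_fold_contract_with_instrumented_stub():
    n = 30
    X = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    y = np.where(np.arange(n) % 3 == 0, 1, -1)
    RecordingLearner.reset()
    clf = SecondLearningEnsemble(
        base_learners=[("rec", RecordingLearner(), {})],
        n_inner=5,
        meta_grid=(10,),
        random_state=0,
    ).fit(X, y)
    # every learning-set row predicted exactly once, never by its own model
    assert RecordingLearner.violations == []
    assert RecordingLearner.n_predictions == n
    assert len(clf.meta_dataset_) == n


def test_ensemble_not_worse_than_best_single_learner():
    """Across 5 seeds on the planted-signal synthetic benchmark, the stacked
    ensemble's mean held-out accuracy trails the best single base learner by
    at most 2 accuracy points."""
    from sklearn.base import clone

    from triostack import (
        DifferentialFilter,
        MRMRSelector,
        SyntheticSpec,
        build_design,
        simulate_triple,
    )
    from triostack.ensemble import default_base_learners, tune_base_learner
    from triostack.pipeline import modeling_scale

    ens_accs, best_single_accs = [], []
    for seed in range(5):
        spec = SyntheticSpec(
            n_tumor=45, n_normal=15, n_pc=300, n_nc=150, n_genes_meth=1,
            d_pc=10, d_nc=5, d_meth=0, probes_per_gene_mean=1.0,
            frac_shared_probes=0.0, seed=seed,
        )  # expression-only benchmark; the single-gene meth block is unused
        dataset, _ = simulate_triple(spec)
        design = build_design(dataset, use_blocks=("pc", "nc"))
        idx = np.arange(60)
        train, test = idx[idx % 4 != 0], idx[idx % 4 == 0]
        screen = DifferentialFilter(
            feature_types=design.feature_types, feature_scales=design.feature_scales
        ).fit(design.X[train], design.y[train])
        Xm = modeling_scale(design.X, design.feature_scales)[:, screen.support_]
        sel = MRMRSelector(n_features=min(8, Xm.shape[1])).fit(Xm[train], design.y[train])
        Xs, y = Xm[:, sel.support_], design.y
        clf = SecondLearningEnsemble(n_inner=4, meta_grid=(50,), random_state=seed)
        clf.fit(Xs[train], y[train])
        ens_accs.append(float(np.mean(clf.predict(Xs[test]) == y[test])))
        singles = []
        for _, est, grid in default_base_learners(seed):
            params, _ = tune_base_learner(est, grid, Xs[train], y[train], clf.inner_folds_)
            model = clone(est).set_params(**params).fit(Xs[train], y[train])
            singles.append(float(np.mean(model.predict(Xs[test]) == y[test])))
        best_single_accs.append(max(singles))
    assert np.mean(ens_accs) >= np.mean(best_single_accs) - 0.02


def test_ensemble_reproducible_run_to_run():
    X, y = separable_data(n=36, seed=4)
    a = SecondLearningEnsemble(n_inner=3, meta_grid=(50,), random_state=11).fit(X, y)
    b = SecondLearningEnsemble(n_inner=3, meta_grid=(50,), random_state=11).fit(X, y)
    X_test, _ = separable_data(n=16, seed=5)
    np.testing.assert_array_equal(a.predict_proba(X_test), b.predict_proba(X_test))
    assert a.base_params_ == b.base_params_
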