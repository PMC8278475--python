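"""Fold change, Welch testing, BH step-up and threshold selection."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from triostack import DifferentialFilter, bh_adjust, fold_change, per_feature_test
from triostack.containers import METHYLATED_GENE, NCRNA, PROTEIN_CODING
from triostack.differential import select_differential


# ---------------------------------------------------------------------------
# fold change
# ---------------------------------------------------------------------------

def test_equal_means_fc_one():
    X = np.array([[2.0], [4.0], [2.0], [4.0]])
    y = np.array([1, 1, -1, -1])
    fc, log2fc = fold_change(X, y)
    assert fc[0] == 1.0 and log2fc[0] == 0.0


def test_exact_ratio():
    X = np.array([[8.0], [8.0], [1.0], [1.0]])
    y = np.array([1, 1, -1, -1])
    fc, log2fc = fold_change(X, y, pseudocount=0.0)
    assert fc[0] == 8.0 and log2fc[0] == 3.0


def test_fold_change_matches_two_loop_oracle():
    rng = np.random.default_rng(2)
    X = rng.gamma(2.0, 10.0, size=(15, 20))
    y = np.where(np.arange(15) < 9, 1, -1)
    fc, log2fc = fold_change(X, y, pseudocount=1.0)
    for g in range(20):
        t = [X[i, g] for i in range(15) if y[i] == 1]
        n = [X[i, g] for i in range(15) if y[i] == -1]
        expected = (sum(t) / len(t) + 1.0) / (sum(n) / len(n) + 1.0)
        assert abs(fc[g] - expected) < 1e-12
        assert abs(log2fc[g] - np.log2(expected)) < 1e-12


def test_negative_values_rejected():
    with pytest.raises(ValueError, match="nonnegative"):
        fold_change(np.array([[-1.0], [1.0], [1.0], [1.0]]), np.array([1, 1, -1, -1]))


# ---------------------------------------------------------------------------
# per-feature test
# ---------------------------------------------------------------------------

def test_constant_feature_p_one():
    X = np.array([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]])
    y = np.array([1, 1, 1, -1, -1, -1])
    # identical {1,2,3} vs {1,2,3}: p = 1 (no evidence of difference)
    assert per_feature_test(X, y)[0] == 1.0
    X_const = np.full((6, 1), 5.0)
    assert per_feature_test(X_const, y)[0] == 1.0


def test_welch_matches_textbook_implementation():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(12, 10))
    y = np.where(np.arange(12) < 7, 1, -1)
    p = per_feature_test(X, y)

    def welch(a, b):
        ma, mb = a.mean(), b.mean()
        va, vb = a.var(ddof=1), b.var(ddof=1)
        na, nb = len(a), len(b)
        se2 = va / na + vb / nb
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        return 2 * stats.t.sf(abs(t), df)

    for g in range(10):
        expected = welch(X[y == 1, g], X[y == -1, g])
        assert abs(p[g] - expected) < 1e-10


def test_too_few_samples_error():
    with pytest.raises(ValueError, match="at least 2"):
        per_feature_test(np.ones((3, 1)), np.array([1, 1, -1]))


# ---------------------------------------------------------------------------
# BH step-up
# ---------------------------------------------------------------------------

def bh_oracle(p):
    """Definitional min-over-tails BH: q_(i) = min_{j>=i} p_(j)*m/j, capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        tail = [p[order[j - 1]] * m / j for j in range(rank, m + 1)]
        q[idx] = min(min(tail), 1.0)
    return q


def test_bh_hand_example():
    q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_bh_trivial_cases():
    np.testing.assert_array_equal(bh_adjust(np.ones(5)), np.ones(5))
    assert bh_adjust(np.array([0.05]))[0] == 0.05


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust(np.array([0.5, 1.5]))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=12)
)
def test_bh_equals_min_over_tails_oracle(p):
    p = np.asarray(p)
    np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)


def test_bh_agrees_with_statsmodels():
    rng = np.random.default_rng(4)
    p = rng.uniform(size=200)
    _, q_sm, _, _ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(bh_adjust(p), q_sm, atol=1e-12)


# ---------------------------------------------------------------------------
# selection thresholds
# ---------------------------------------------------------------------------

def records(rows):
    return pd.DataFrame(rows, columns=["feature_id", "feature_type", "log2fc", "q_value"])


def test_methylated_gene_passes_its_gate():
    out = select_differential(records([("g", METHYLATED_GENE, 0.6, 0.01)]))
    assert out["selected"].tolist() == [True]


def test_expression_strict_inequality():
    out = select_differential(records([("g", PROTEIN_CODING, 2.9, 0.001)]))
    assert out["selected"].tolist() == [False]  # fails |log2fc| > 3
    out = select_differential(records([("g", PROTEIN_CODING, 3.0, 0.001)]))
    assert out["selected"].tolist() == [False]  # boundary is excluded
    out = select_differential(records([("g", PROTEIN_CODING, -3.1, 0.001)]))
    assert out["selected"].tolist() == [True]


def test_selection_matches_brute_force_comprehension():
    rng = np.random.default_rng(12)
    types = [PROTEIN_CODING, NCRNA, METHYLATED_GENE]
    rows = [
        (f"f{i}", types[int(rng.integers(3))], float(rng.normal(0, 3)), float(rng.uniform()))
        for i in range(30)
    ]
    out = select_differential(records(rows))
    gates = {PROTEIN_CODING: 3.0, NCRNA: 3.0, METHYLATED_GENE: 0.5}
    expected = [abs(l) > gates[t] and q < 0.05 for _, t, l, q in rows]
    assert out["selected"].tolist() == expected


def test_fdr_monotonicity():
    rng = np.random.default_rng(13)
    rows = [
        (f"f{i}", PROTEIN_CODING, float(rng.normal(0, 4)), float(rng.uniform()))
        for i in range(40)
    ]
    loose = select_differential(records(rows), fdr=0.2)["selected"]
    strict = select_differential(records(rows), fdr=0.05)["selected"]
    assert set(np.flatnonzero(strict)) <= set(np.flatnonzero(loose))


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

def test_filter_selects_planted_features(tiny_design):
    design, truth = tiny_design
    f = DifferentialFilter(
        feature_types=design.feature_types, feature_scales=design.feature_scales
    ).fit(design.X, design.y)
    selected = set(design.feature_ids[f.support_])
    planted = truth.all_features
    assert len(selected & planted) / len(planted) >= 0.8
    assert f.records_.shape[0] == design.X.shape[1]


def test_null_features_controlled_over_seeds():
    """Without planted effects, the fraction of null features selected stays
    below twice the nominal FDR level, averaged over 20 seeds."""
    from triostack import SyntheticSpec, build_design, simulate_triple

    rates = []
    for seed in range(20):
        spec = SyntheticSpec(
            n_tumor=15, n_normal=10, n_pc=150, n_nc=50, n_genes_meth=10,
            d_pc=2, d_nc=1, d_meth=1, planted_log2fc=0.0, planted_delta_beta=0.0,
            probes_per_gene_mean=1.0, frac_shared_probes=0.0, seed=seed,
        )
        ds, _ = simulate_triple(spec)
        design = build_design(ds, use_blocks=("pc", "nc"))
        f = DifferentialFilter(
            feature_types=design.feature_types, feature_scales=design.feature_scales
        ).fit(design.X, design.y)
        rates.append(f.support_.mean())
    assert float(np.mean(rates)) <= 0.10
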