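"""Stage 2: per-feature differential screening by fold change and FDR.

For each feature the tumor/normal fold change is the ratio of group means
(with a pseudocount for count-scale data), and a two-sample test p-value is
corrected across features with the Benjamini-Hochberg step-up procedure.
A feature survives when it clears both the |log2FC| gate for its data type
and the FDR threshold. Default gates: |log2FC| > 0.5 for methylated genes,
|log2FC| > 3 for expression features, FDR q < 0.05 — strict inequalities.

The step-up adjustment and selection rule are deliberately authored here
(rather than delegated) because they are the screened contract of the stage;
the unit tests compare them against independent oracles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .containers import BETA, CPG_PROBE, METHYLATED_GENE, NCRNA, PROTEIN_CODING

logger = logging.getLogger(__name__)

#: default |log2FC| gates per feature type; raw CpG probes (aggregation
#: disabled) use the beta-scale gate of methylated genes
DEFAULT_LOG2FC_THRESHOLDS = {
    METHYLATED_GENE: 0.5,
    PROTEIN_CODING: 3.0,
    NCRNA: 3.0,
    CPG_PROBE: 0.5,
}
DEFAULT_FDR = 0.05


def fold_change(
    X: np.ndarray, y: np.ndarray, pseudocount: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Tumor-over-normal ratio of group means, per feature.

    ``X`` is samples-by-features with nonnegative values, ``y`` labels in
    {-1, +1} (+1 = tumor). ``fc = (mean_tumor + eps) / (mean_normal + eps)``
    with pseudocount ``eps``; returns ``(fc, log2fc)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if (X < 0).any():
        raise ValueError("fold change requires nonnegative values (counts or betas)")
    if not ((y == 1).any() and (y == -1).any()):
        raise ValueError("both classes must be present")
    mean_t = X[y == 1].mean(axis=0)
    mean_n = X[y == -1].mean(axis=0)
    with np.errstate(divide="ignore"):
        fc = (mean_t + pseudocount) / (mean_n + pseudocount)
        log2fc = np.log2(fc)
    return fc, log2fc


def per_feature_test(
    X: np.ndarray, y: np.ndarray, method: str = "welch_t"
) -> np.ndarray:
    """Two-sided per-feature p-values for a tumor/normal difference.

    ``welch_t`` is the default (unequal-variance two-sample t-test);
    ``wilcoxon`` gives the Mann-Whitney rank-sum alternative. Constant
    features (zero variance in both groups, equal means) get p = 1; a
    zero-variance feature whose group means differ gets p = 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    xt, xn = X[y == 1], X[y == -1]
    if xt.shape[0] < 2 or xn.shape[0] < 2:
        raise ValueError("each class needs at least 2 samples for testing")
    if method == "welch_t":
        res = stats.ttest_ind(xt, xn, axis=0, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    elif method == "wilcoxon":
        res = stats.mannwhitneyu(xt, xn, axis=0, alternative="two-sided")
        p = np.asarray(res.pvalue, dtype=float)
    else:
        raise ValueError(f"unknown test {method!r}")
    degenerate = np.isnan(p)
    if degenerate.any():
        equal = np.isclose(xt.mean(axis=0), xn.mean(axis=0))
        p = np.where(degenerate, np.where(equal, 1.0, 0.0), p)
    return np.clip(p, 0.0, 1.0)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Sort p ascending, set ``q_(i) = min_{j>=i} p_(j) * m / j`` capped at 1,
    and map back to input order. Ties keep input-order stability.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


@dataclass
class DifferentialRecord:
    """One feature's screening statistics and decision."""

    feature_id: str
    feature_type: str
    mean_tumor: float
    mean_normal: float
    fc: float
    log2fc: float
    p_value: float
    q_value: float = np.nan
    selected: bool = False


def select_differential(
    records: pd.DataFrame,
    log2fc_thresholds: dict[str, float] | None = None,
    fdr: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Mark records passing their type's |log2FC| gate and the FDR threshold.

    ``records`` needs columns feature_type, log2fc, q_value. Inequalities are
    strict: ``|log2fc| > gate`` and ``q < fdr``.
    """
    gates = dict(DEFAULT_LOG2FC_THRESHOLDS)
    if log2fc_thresholds:
        gates.update(log2fc_thresholds)
    thr = records["feature_type"].map(gates)
    if thr.isna().any():
        bad = sorted(records.loc[thr.isna(), "feature_type"].unique())
        raise ValueError(f"no log2fc threshold for feature types {bad}")
    out = records.copy()
    out["selected"] = (out["log2fc"].abs() > thr) & (out["q_value"] < fdr)
    return out


class DifferentialFilter(SelectorMixin, BaseEstimator):
    """Feature selector combining fold change and BH-adjusted test p-values.

    Parameters
    ----------
    feature_types : array-like of str, shape (n_features,)
        Type tag per column of X (protein_coding / ncRNA / methylated_gene).
    feature_scales : array-like of str, optional
        Scale tag per column ('counts' or 'beta'). Count-scale features are
        tested on log2(x+1) and use ``pseudocount`` in the fold change; beta
        features are tested raw with pseudocount 0. Defaults to counts for
        expression types and beta for methylated genes.
    log2fc_thresholds : dict, optional
        |log2FC| gate per feature type; defaults 0.5 (methylated_gene) and
        3.0 (expression).
    fdr : float, default 0.05
        BH q-value threshold (strict '<').
    pseudocount : float, default 1.0
        Added to both group means for count-scale fold changes.
    test : {'welch_t', 'wilcoxon'}, default 'welch_t'
    pooling : {'by_block', 'global'}, default 'by_block'
        BH correction pooled across expression types but separate for
        methylated genes (gates differ per block), or one global correction.

    Attributes
    ----------
    records_ : pandas.DataFrame
        Per-feature table (feature_id, feature_type, means, fc, log2fc,
        p_value, q_value, selected).
    support_ : ndarray of bool, shape (n_features,)
    """

    def __init__(
        self,
        feature_types=None,
        feature_scales=None,
        log2fc_thresholds=None,
        fdr=DEFAULT_FDR,
        pseudocount=1.0,
        test="welch_t",
        pooling="by_block",
    ):
        self.feature_types = feature_types
        self.feature_scales = feature_scales
        self.log2fc_thresholds = log2fc_thresholds
        self.fdr = fdr
        self.pseudocount = pseudocount
        self.test = test
        self.pooling = pooling

    def fit(self, X, y):
        X, y = validate_data(self, X, y, dtype=float)
        y = np.asarray(y)
        n_features = X.shape[1]
        ftypes = (
            np.asarray(self.feature_types, dtype=object)
            if self.feature_types is not None
            else np.full(n_features, PROTEIN_CODING, dtype=object)
        )
        if ftypes.shape != (n_features,):
            raise ValueError("feature_types length must equal the number of columns")
        if self.feature_scales is not None:
            scales = np.asarray(self.feature_scales, dtype=object)
        else:
            beta_types = np.isin(ftypes.astype(str), [METHYLATED_GENE, CPG_PROBE])
            scales = np.where(beta_types, BETA, "counts").astype(object)
        is_beta = scales == BETA

        eps = np.where(is_beta, 0.0, self.pseudocount)
        mean_t = X[y == 1].mean(axis=0)
        mean_n = X[y == -1].mean(axis=0)
        if (X < 0).any():
            raise ValueError("negative values: fold change needs counts or betas")
        with np.errstate(divide="ignore"):
            fc = (mean_t + eps) / (mean_n + eps)
            log2fc = np.log2(fc)

        X_test = np.where(is_beta[None, :], X, np.log2(X + 1.0))
        p = per_feature_test(X_test, y, method=self.test)

        q = np.empty(n_features, dtype=float)
        if self.pooling == "global":
            q[:] = bh_adjust(p)
        elif self.pooling == "by_block":
            meth_mask = (ftypes == METHYLATED_GENE) | (ftypes == CPG_PROBE)
            for mask in (meth_mask, ~meth_mask):
                if mask.any():
                    q[mask] = bh_adjust(p[mask])
        else:
            raise ValueError(f"unknown pooling {self.pooling!r}")

        records = pd.DataFrame(
            {
                "feature_id": getattr(
                    self, "feature_names_in_", np.arange(n_features).astype(str)
                ),
                "feature_type": ftypes,
                "mean_tumor": mean_t,
                "mean_normal": mean_n,
                "fc": fc,
                "log2fc": log2fc,
                "p_value": p,
                "q_value": q,
            }
        )
        records = select_differential(records, self.log2fc_thresholds, self.fdr)
        self.records_ = records
        self.support_ = records["selected"].to_numpy()
        logger.info(
            "differential filter: %d / %d features selected",
            int(self.support_.sum()),
            n_features,
        )
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


__all__ = [
    "fold_change",
    "per_feature_test",
    "bh_adjust",
    "select_differential",
    "DifferentialRecord",
    "DifferentialFilter",
    "DEFAULT_LOG2FC_THRESHOLDS",
    "DEFAULT_FDR",
]
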