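"""Confusion-matrix metrics, nested cross-validation and stability reports.

The primary tumor is the positive class. Accuracy, sensitivity (recall),
specificity and F1 are reported as percentages; displayed values round
half-up to two decimals while full precision is kept internally. Nested CV
repeats the outer split until every sample has been predicted exactly once
and pools one micro-averaged confusion matrix over the folds; per-fold
selected feature lists feed the stability report (union after overlap
removal, category proportions, repetition rate).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .containers import METHYLATED_GENE, NCRNA
from .ensemble import make_fold_plan
from .pipeline import Design, DiagnosisPipeline

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# confusion matrix and metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count TP/TN/FP/FN with +1 (primary tumor) as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    bad = set(np.unique(np.concatenate([y_true, y_pred]))) - {-1, 1}
    if bad:
        raise ValueError(f"labels must be -1 or +1, got {sorted(bad)}")
    return ConfusionMatrix(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == -1) & (y_pred == -1)).sum()),
        fp=int(((y_true == -1) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == -1)).sum()),
    )


def round_half_up(x: float, decimals: int = 2) -> float:
    """Half-up decimal rounding used for displayed percentages."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class MetricsReport:
    """Accuracy / sensitivity / specificity / F1 as percentages, plus counts.

    A metric whose denominator is empty is reported as None (missing):
    sensitivity needs tp+fn > 0, specificity tn+fp > 0, F1 2tp+fp+fn > 0.
    """

    confusion: ConfusionMatrix
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    f1: float | None
    n_features: int | None = None

    def rounded(self, decimals: int = 2) -> dict[str, float | None]:
        out = {}
        for name in ("accuracy", "sensitivity", "specificity", "f1"):
            v = getattr(self, name)
            out[name] = None if v is None else round_half_up(v, decimals)
        return out


def metrics(cm: ConfusionMatrix, n_features: int | None = None) -> MetricsReport:
    """Standard two-class diagnosis metrics from a confusion matrix.

    accuracy = (tp+tn)/total, sensitivity = tp/(tp+fn),
    specificity = tn/(tn+fp), F1 = 2tp/(2tp+fp+fn); all x100.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    acc = 100.0 * (cm.tp + cm.tn) / cm.total
    sens = 100.0 * cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else None
    spec = 100.0 * cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp > 0 else None
    denom = 2 * cm.tp + cm.fp + cm.fn
    f1 = 100.0 * 2 * cm.tp / denom if denom > 0 else None
    return MetricsReport(cm, acc, sens, spec, f1, n_features)


# ---------------------------------------------------------------------------
# feature stability
# ---------------------------------------------------------------------------

@dataclass
class FeatureReport:
    """Per-fold selected features and their cross-fold stability summary."""

    per_fold: list[list[str]]
    union: list[str]
    counts: dict[str, int]
    category_counts: dict[str, int]
    epigenetic_fraction: float
    repetition_rate: float


def feature_stability(
    per_fold_lists: list[list[str]],
    feature_types: dict[str, str] | None = None,
    method: str = "recurrence",
) -> FeatureReport:
    """Summarize how stable the per-fold selections are.

    The union removes overlapping features; ``repetition_rate`` is, by
    default, the mean over folds of the fraction of that fold's features
    that appear in at least two folds overall (``method='jaccard'`` gives
    the mean pairwise Jaccard overlap instead). The epigenetic fraction is
    the percentage of the union tagged ncRNA or methylated_gene.
    """
    if not per_fold_lists:
        raise ValueError("need at least one fold's feature list")
    occurrence: dict[str, int] = {}
    union: list[str] = []
    for lst in per_fold_lists:
        for fid in lst:
            if fid not in occurrence:
                union.append(fid)
                occurrence[fid] = 0
            occurrence[fid] += 1
    if method == "recurrence":
        fractions = []
        for lst in per_fold_lists:
            if lst:
                fractions.append(
                    sum(occurrence[fid] >= 2 for fid in lst) / len(lst)
                )
        rate = 100.0 * float(np.mean(fractions)) if fractions else 0.0
    elif method == "jaccard":
        vals = []
        F = len(per_fold_lists)
        for i in range(F):
            for j in range(i + 1, F):
                a, b = set(per_fold_lists[i]), set(per_fold_lists[j])
                if a | b:
                    vals.append(len(a & b) / len(a | b))
        rate = 100.0 * float(np.mean(vals)) if vals else 0.0
    else:
        raise ValueError(f"unknown repetition-rate method {method!r}")

    categories: dict[str, int] = {}
    if feature_types:
        for fid in union:
            cat = feature_types.get(fid, "unknown")
            categories[cat] = categories.get(cat, 0) + 1
    epi = (
        100.0
        * (categories.get(NCRNA, 0) + categories.get(METHYLATED_GENE, 0))
        / len(union)
        if union
        else 0.0
    )
    return FeatureReport(
        per_fold=[list(lst) for lst in per_fold_lists],
        union=union,
        counts=occurrence,
        category_counts=categories,
        epigenetic_fraction=epi,
        repetition_rate=rate,
    )


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    fold_reports: list[MetricsReport]
    pooled_confusion: ConfusionMatrix
    pooled: MetricsReport
    features: FeatureReport
    n_features: int

    @property
    def mean_fold_accuracy(self) -> float:
        return float(np.mean([r.accuracy for r in self.fold_reports]))


def run_nested_cv(
    design: Design,
    n_features: int = 10,
    n_outer: int = 10,
    n_inner: int = 5,
    seed: int = 0,
    stratify: bool = False,
    pipeline_kwargs: dict | None = None,
) -> CVResult:
    """Nested CV: per outer fold, select features and train on the learning
    set only, then predict the held-out fold; pool one confusion matrix.

    Every sample is predicted exactly once. ``pipeline_kwargs`` forwards
    extra :class:`DiagnosisPipeline` parameters (thresholds, grids, ...).
    """
    plan = make_fold_plan(
        len(design.y), n_outer=n_outer, n_inner=n_inner, seed=seed,
        stratify=stratify, y=design.y,
    )
    kwargs = dict(pipeline_kwargs or {})
    fold_reports: list[MetricsReport] = []
    per_fold_features: list[list[str]] = []
    pooled = ConfusionMatrix(0, 0, 0, 0)
    for f, test_idx in enumerate(plan.outer_folds):
        learn_idx = plan.learning_set(f)
        y_learn = design.y[learn_idx]
        if len(np.unique(y_learn)) < 2:
            raise ValueError(f"outer fold {f}: learning set has a single class")
        pipe = DiagnosisPipeline(
            feature_types=design.feature_types,
            feature_scales=design.feature_scales,
            feature_ids=design.feature_ids,
            n_features=n_features,
            n_inner=n_inner,
            random_state=int((seed * 1009 + f) % (2**31)),
            **kwargs,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pipe.fit(design.X[learn_idx], y_learn)
            y_pred = pipe.predict(design.X[test_idx])
        cm = confusion(design.y[test_idx], y_pred)
        pooled = pooled + cm
        fold_reports.append(metrics(cm, n_features=len(pipe.selected_ids_)))
        per_fold_features.append([str(fid) for fid in pipe.selected_ids_])
        logger.info(
            "fold %d/%d: acc %.2f%% (%d samples)",
            f + 1, n_outer, fold_reports[-1].accuracy, cm.total,
        )
    type_map = {
        str(fid): str(t) for fid, t in zip(design.feature_ids, design.feature_types)
    }
    features = feature_stability(per_fold_features, type_map)
    return CVResult(
        fold_reports=fold_reports,
        pooled_confusion=pooled,
        pooled=metrics(pooled, n_features=n_features),
        features=features,
        n_features=n_features,
    )


@dataclass
class SweepResult:
    """Mean CV accuracy per candidate feature-count n, and the first peak."""

    accuracies: dict[int, float]
    optimal_n: int
    results: dict[int, CVResult] = field(default_factory=dict)


def first_peak(accuracies: dict[int, float]) -> int:
    """Smallest n attaining the maximum accuracy (the first-peak rule)."""
    if not accuracies:
        raise ValueError("empty sweep")
    best = max(accuracies.values())
    return min(n for n, a in accuracies.items() if a == best)


def sweep_feature_count(
    design: Design,
    n_range=range(5, 31),
    keep_results: bool = False,
    **cv_kwargs,
) -> SweepResult:
    """Run the full nested CV for every candidate n and apply the
    first-peak rule to pick the optimal feature count.

    An n exceeding the available feature count is dropped from the range
    with a warning (the nested CV itself further caps per-fold).
    """
    n_range = [n for n in n_range]
    usable = [n for n in n_range if n <= design.X.shape[1]]
    if len(usable) < len(n_range):
        logger.warning(
            "sweep range truncated to n <= %d available features", design.X.shape[1]
        )
    accuracies: dict[int, float] = {}
    results: dict[int, CVResult] = {}
    for n in usable:
        res = run_nested_cv(design, n_features=n, **cv_kwargs)
        accuracies[n] = res.mean_fold_accuracy
        if keep_results:
            results[n] = res
        logger.info("sweep n=%d: mean fold accuracy %.2f%%", n, accuracies[n])
    return SweepResult(accuracies, first_peak(accuracies), results)


__all__ = [
    "ConfusionMatrix",
    "confusion",
    "metrics",
    "MetricsReport",
    "round_half_up",
    "feature_stability",
    "FeatureReport",
    "run_nested_cv",
    "CVResult",
    "sweep_feature_count",
    "SweepResult",
    "first_peak",
]
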