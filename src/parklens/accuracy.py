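"""Agreement between automated and manual photograph classification.

A stratified random sample of automatically classified photographs is
manually labelled by an observer; the confusion matrix yields overall
accuracy, chance-corrected weighted kappa, and candidate category pairs
for aggregation (pairs with high mutual misclassification).

Category order matters for the distance-based kappa weights; callers
should pass categories in dendrogram leaf order so that adjacent ids are
the most similar clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["ConfusionMatrix", "AccuracyReport", "stratified_sample",
           "confusion", "weighted_kappa", "suggest_aggregation",
           "accuracy_report"]


@dataclass
class ConfusionMatrix:
    categories: list            # ordered category ids
    counts: np.ndarray          # rows = automated, columns = manual

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class AccuracyReport:
    overall_accuracy: float
    weighted_kappa: float
    per_category_recall: pd.Series
    mutual_misclassification: list  # (cat_i, cat_j, rate), descending


def stratified_sample(assignments: pd.Series, per_stratum: int,
                      seed: int) -> list:
    """Sample up to ``per_stratum`` photo ids per category, shuffled.

    Strata smaller than ``per_stratum`` are taken whole (with a
    warning).  Deterministic for a given seed.
    """
    if len(assignments) == 0:
        raise ValidationError("assignments are empty")
    if per_stratum < 1:
        raise ValidationError("per_stratum must be >= 1")
    rng = np.random.default_rng(seed)
    chosen: list = []
    for cat in sorted(assignments.unique()):
        ids = np.sort(assignments.index[assignments == cat].to_numpy())
        if len(ids) < per_stratum:
            warnings.warn(
                f"stratum {cat!r} has only {len(ids)} photos "
                f"(< {per_stratum}); taking all", stacklevel=2)
            chosen.extend(ids)
        else:
            chosen.extend(rng.choice(ids, size=per_stratum, replace=False))
    chosen = np.asarray(chosen, dtype=object)
    rng.shuffle(chosen)  # "mixed" before manual classification
    return list(chosen)


def confusion(auto: pd.Series, manual: pd.Series,
              categories: list | None = None) -> ConfusionMatrix:
    """Cross-tabulate automated (rows) against manual (columns) labels."""
    auto_ids, manual_ids = set(auto.index), set(manual.index)
    if auto_ids != manual_ids:
        raise ValidationError(
            f"photo id mismatch: only-auto={sorted(auto_ids - manual_ids)[:5]}, "
            f"only-manual={sorted(manual_ids - auto_ids)[:5]}")
    manual = manual.reindex(auto.index)
    if categories is None:
        categories = sorted(set(auto) | set(manual))
    index = {c: i for i, c in enumerate(categories)}
    counts = np.zeros((len(categories), len(categories)), dtype=int)
    for a, m in zip(auto, manual):
        counts[index[a], index[m]] += 1
    return ConfusionMatrix(list(categories), counts)


def _kappa_weights(C: int, scheme: str) -> np.ndarray:
    i = np.arange(C)
    diff = np.abs(i[:, None] - i[None, :])
    if scheme == "linear":
        return diff / max(C - 1, 1)
    if scheme == "quadratic":
        return (diff / max(C - 1, 1)) ** 2
    if scheme == "unweighted":
        return (diff > 0).astype(float)
    raise ValidationError(f"unknown kappa weighting scheme: {scheme!r}")


def weighted_kappa(cm: ConfusionMatrix, weights: str = "linear") -> float:
    """Cohen's kappa with distance-based disagreement weights.

    kappa_w = 1 - sum(w * p_obs) / sum(w * p_exp), where p_exp is the
    outer product of the marginals.  ``weights`` is "linear"
    (w_ij = |i-j|/(C-1)), "quadratic", or "unweighted" (0/1).
    """
    total = cm.total
    if total == 0:
        raise ValidationError("confusion matrix has zero total")
    p = cm.counts / total
    w = _kappa_weights(len(cm.categories), weights)
    expected = np.outer(p.sum(axis=1), p.sum(axis=0))
    denom = float((w * expected).sum())
    if denom == 0.0:  # single occupied category: perfect trivially
        return 1.0
    return 1.0 - float((w * p).sum()) / denom


def suggest_aggregation(cm: ConfusionMatrix,
                        rate_threshold: float) -> list:
    """Category pairs with high mutual misclassification.

    For each pair (i, j) the symmetrized off-diagonal rate
    (counts[i,j] + counts[j,i]) / (row_i + row_j totals) is compared to
    the threshold; qualifying pairs are returned as (cat_i, cat_j, rate)
    sorted by decreasing rate.
    """
    row_tot = cm.counts.sum(axis=1)
    out = []
    C = len(cm.categories)
    for i in range(C):
        for j in range(i + 1, C):
            denom = row_tot[i] + row_tot[j]
            if denom == 0:
                continue
            rate = (cm.counts[i, j] + cm.counts[j, i]) / denom
            if rate > rate_threshold:
                out.append((cm.categories[i], cm.categories[j], float(rate)))
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out


def accuracy_report(cm: ConfusionMatrix, weights: str = "linear",
                    rate_threshold: float = 0.2) -> AccuracyReport:
    """Overall accuracy, weighted kappa, recall and aggregation hints."""
    total = cm.total
    if total == 0:
        raise ValidationError("confusion matrix has zero total")
    overall = float(np.trace(cm.counts)) / total
    col_tot = cm.counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(col_tot > 0, np.diag(cm.counts) / col_tot, np.nan)
    return AccuracyReport(
        overall_accuracy=overall,
        weighted_kappa=weighted_kappa(cm, weights),
        per_category_recall=pd.Series(recall, index=cm.categories),
        mutual_misclassification=suggest_aggregation(cm, rate_threshold),
    )
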