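"""Photograph classification from keyword sets.

Each photograph carries a set of up to ten machine-vision keywords.
Photographs are encoded as binary keyword indicators, pairwise Jaccard
distances are computed (the proportion of keywords two photographs do
not share), and the distance matrix is clustered agglomeratively under
Ward's criterion applied directly to the dissimilarities
(Lance-Williams update; "Ward on dissimilarities", not Ward on
coordinates).  The number of categories is chosen by the L-method knee
of an evaluation graph: mean between-cluster minus mean within-cluster
pairwise distance as a function of the number of clusters, computed on
a random sample of the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, leaves_list, linkage
from scipy.spatial.distance import squareform

from .exceptions import ValidationError

__all__ = [
    "BinaryKeywordMatrix", "DistanceMatrix", "Dendrogram", "EvaluationGraph",
    "ClusterModel", "build_binary_matrix", "jaccard_distances", "ward_cluster",
    "evaluation_graph", "lmethod_knee", "cut_and_label", "aggregate_categories",
]


@dataclass
class BinaryKeywordMatrix:
    photo_ids: list[str]
    vocabulary: list[str]
    bits: np.ndarray  # (n_photos, n_keywords) bool


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # square symmetric, zero diagonal, values in [0, 1]


@dataclass
class Dendrogram:
    linkage: np.ndarray  # scipy (n-1, 4) linkage matrix
    leaf_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return self.linkage.shape[0] + 1


@dataclass
class EvaluationGraph:
    k_values: np.ndarray
    eval: np.ndarray  # mean between-cluster minus mean within-cluster distance


@dataclass
class ClusterModel:
    """Chosen clustering: tree, k, assignments and category labels."""

    dendrogram: Dendrogram
    k: int
    assignments: pd.Series          # photo_id -> category id (int)
    labels: dict[int, dict]         # category -> {"name", "top_keywords"}
    aggregation: dict[int, int] = field(default_factory=dict)  # identity default

    @property
    def categories(self) -> list[int]:
        return sorted(self.labels)

    def aggregated_assignments(self) -> pd.Series:
        if not self.aggregation:
            return self.assignments
        return self.assignments.map(lambda c: self.aggregation.get(c, c))


def _keyword_sets(photos: pd.DataFrame) -> pd.Series:
    if "keywords" not in photos.columns:
        raise ValidationError("photo table lacks a 'keywords' column")
    return photos.set_index("photo_id")["keywords"].map(set)


def build_binary_matrix(photos: pd.DataFrame) -> BinaryKeywordMatrix:
    """Encode keyword presence as a photo x keyword boolean matrix.

    The vocabulary is the sorted union of all keywords; duplicate
    keywords within one photo count once (set semantics).
    """
    sets = _keyword_sets(photos)
    empty = [pid for pid, s in sets.items() if not s]
    if empty:
        raise ValidationError(f"photos with empty keyword sets: {empty}")
    vocabulary = sorted(set().union(*sets))
    index = {kw: j for j, kw in enumerate(vocabulary)}
    bits = np.zeros((len(sets), len(vocabulary)), dtype=bool)
    for i, s in enumerate(sets):
        for kw in s:
            bits[i, index[kw]] = True
    return BinaryKeywordMatrix(list(sets.index), vocabulary, bits)


def jaccard_distances(m: BinaryKeywordMatrix) -> DistanceMatrix:
    """Pairwise Jaccard distances d = 1 - |intersection| / |union|."""
    if m.bits.shape[0] < 2:
        raise ValidationError("need at least 2 photos for pairwise distances")
    if not m.bits.any(axis=1).all():
        raise ValidationError("internal invariant violated: empty keyword row")
    # |A∩B| via a float64 matrix product: sums of 0/1 products are exact
    # integers, so this equals set arithmetic while using BLAS speed.
    B = m.bits.astype(np.float64)
    inter = B @ B.T
    sizes = B.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    d = 1.0 - inter / union
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(m.photo_ids), d)


def ward_cluster(dm: DistanceMatrix) -> Dendrogram:
    """Agglomerative merge tree under Ward's criterion on the distances."""
    n = dm.d.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 items to cluster")
    Z = linkage(squareform(dm.d, checks=False), method="ward")
    return Dendrogram(Z, list(dm.ids))


def _cut_labels(dend: Dendrogram, ks) -> np.ndarray:
    """Leaf labels for each requested cluster count (columns follow ks)."""
    return cut_tree(dend.linkage, n_clusters=np.asarray(ks))


def evaluation_graph(
    dend: Dendrogram,
    dm: DistanceMatrix,
    k_max: int,
    sample_fraction: float = 0.1,
    seed: int = 0,
    min_sample: int = 200,
) -> EvaluationGraph:
    """Cluster-quality curve over k = 2..k_max.

    eval(k) is the pair-weighted mean distance across clusters minus the
    mean distance within clusters, computed on one random sample of the
    photographs (re-used across all k).  The sample size is
    max(min_sample, fraction * n), capped at n.
    """
    n = dend.n_leaves
    if not 2 <= k_max <= n - 1:
        raise ValidationError(f"k_max must lie in [2, {n - 1}], got {k_max}")
    rng = np.random.default_rng(seed)
    if sample_fraction < 1.0:
        size = min(n, max(min_sample, int(round(sample_fraction * n))))
        idx = np.sort(rng.choice(n, size=size, replace=False))
    else:
        idx = np.arange(n)
    sub = dm.d[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    dpairs = sub[iu]
    ks = np.arange(2, k_max + 1)
    labels = _cut_labels(dend, ks)[idx]
    evals = np.empty(len(ks))
    for j in range(len(ks)):
        same = labels[iu[0], j] == labels[iu[1], j]
        within = dpairs[same].mean() if same.any() else 0.0
        between = dpairs[~same].mean() if (~same).any() else 0.0
        evals[j] = between - within
    return EvaluationGraph(ks, evals)


def _two_line_break(x: np.ndarray, y: np.ndarray) -> tuple[int, float, bool]:
    """Exhaustive two-segment least-squares search.

    Returns (index of the last left-segment point, weighted RMSE at the
    best break, collinear flag).  Each segment gets >= 2 points.
    """
    b = len(x)
    cs = np.arange(2, b - 1)  # left = points [0, c), right = [c, b)
    totals = np.empty(len(cs))
    for i, c in enumerate(cs):
        rl = _line_rmse(x[:c], y[:c])
        rr = _line_rmse(x[c:], y[c:])
        totals[i] = (c * rl + (b - c) * rr) / b
    scale = max(1.0, float(np.abs(y).max()))
    # A continuous piecewise-linear curve makes the junction point fit both
    # lines, tying two breakpoints at zero RMSE; the junction is the larger.
    best = totals.min()
    tied = np.flatnonzero(totals <= best + 1e-10 * scale)
    best_c = int(cs[tied[-1]])
    collinear = _line_rmse(x, y) <= 1e-10 * scale
    return best_c - 1, float(best), collinear


def _line_rmse(x: np.ndarray, y: np.ndarray) -> float:
    A = np.column_stack([x, np.ones_like(x)])
    resid = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
    return float(np.sqrt(np.mean(resid ** 2)))


def lmethod_knee(g: EvaluationGraph, initial_cutoff: int = 20) -> int:
    """L-method knee of the evaluation graph.

    Two least-squares lines are fitted over every admissible breakpoint
    within a window of the first ``initial_cutoff`` points; the knee
    minimizes the size-weighted RMSE.  If the knee falls outside the
    middle third of the window, the window is grown by 10 points and the
    search repeats, stopping when the knee is roughly centred or the
    window is exhausted.  A perfectly linear (collinear) graph has no
    knee: the smallest candidate k is returned with a warning.
    """
    x = np.asarray(g.k_values, dtype=float)
    y = np.asarray(g.eval, dtype=float)
    if len(x) < 5:
        raise ValidationError("evaluation graph needs at least 5 points")
    if not np.all(np.isfinite(y)):
        raise ValidationError("evaluation graph contains non-finite values")
    b = min(initial_cutoff, len(x))
    while True:
        ci, _, collinear = _two_line_break(x[:b], y[:b])
        if collinear:
            warnings.warn(
                "evaluation graph is collinear within tolerance; no knee "
                "exists - returning the smallest candidate k", stacklevel=2)
            return int(x[1])
        if b / 3.0 <= ci + 1 <= 2.0 * b / 3.0:
            break
        nb = min(b + 10, len(x))
        if nb == b:
            break
        b = nb
    return int(x[ci])


def _order_categories_by_leaves(dend: Dendrogram, raw: np.ndarray) -> np.ndarray:
    """Relabel cut_tree output so category ids follow dendrogram leaf order."""
    order = leaves_list(dend.linkage)
    mapping: dict[int, int] = {}
    for leaf in order:
        c = raw[leaf]
        if c not in mapping:
            mapping[c] = len(mapping)
    return np.array([mapping[c] for c in raw])


def cut_and_label(dend: Dendrogram, k: int, photos: pd.DataFrame,
                  top_n: int = 10) -> ClusterModel:
    """Cut the tree at k clusters and label each by its top keywords.

    Category ids (0..k-1) follow dendrogram leaf order, so adjacent ids
    are adjacent clusters in the tree.  Labels carry the ``top_n`` most
    frequent keywords (ties broken lexicographically); the name is the
    hyphenated top three.
    """
    n = dend.n_leaves
    if not 2 <= k <= n:
        raise ValidationError(f"k must lie in [2, {n}], got {k}")
    raw = _cut_labels(dend, [k])[:, 0]
    cats = _order_categories_by_leaves(dend, raw)
    assignments = pd.Series(cats, index=pd.Index(dend.leaf_ids, name="photo_id"),
                            name="category")
    sets = _keyword_sets(photos).reindex(dend.leaf_ids)
    labels: dict[int, dict] = {}
    for c in range(k):
        counts: dict[str, int] = {}
        for s in sets[cats == c]:
            for kw in s:
                counts[kw] = counts.get(kw, 0) + 1
        top = sorted(counts, key=lambda kw: (-counts[kw], kw))[:top_n]
        labels[c] = {"name": "-".join(top[:3]), "top_keywords": top}
    return ClusterModel(dend, k, assignments, labels)


def aggregate_categories(model: ClusterModel,
                         merge_map: dict[int, int]) -> ClusterModel:
    """Coarsen categories through a merge map (e.g. several nature-like
    clusters into one NATURE category).  Unmapped categories keep their
    id; labels of merged categories pool their top keywords."""
    unknown = set(merge_map) - set(model.labels)
    if unknown:
        raise ValidationError(f"merge_map keys are not categories: {sorted(unknown)}")
    full_map = {c: merge_map.get(c, c) for c in model.labels}
    bad_targets = set(full_map.values()) - set(model.labels)
    if bad_targets:
        raise ValidationError(
            f"merge targets are not existing categories: {sorted(bad_targets)}")
    labels: dict[int, dict] = {}
    for c in sorted(model.labels):
        t = full_map[c]
        if t not in labels:
            labels[t] = {"name": model.labels[t]["name"], "top_keywords": []}
        for kw in model.labels[c]["top_keywords"]:
            if kw not in labels[t]["top_keywords"]:
                labels[t]["top_keywords"].append(kw)
    return replace(model, labels=labels, aggregation=full_map)
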