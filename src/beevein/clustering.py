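"""Adaptive hierarchical clustering of wing feature vectors.

Samples agglomerate under Ward linkage on Euclidean distances.  Instead of
cutting the dendrogram at a fixed height or a preset cluster count, each
merge is scored by its inconsistency coefficient

    inconsistency = (h - h_bar) / sigma_h

where ``h`` is the merge height and ``h_bar``, ``sigma_h`` are the mean
and (ddof-1) standard deviation of the heights in the merge's depth-limited
neighborhood (the merge itself plus its descendant merges up to ``depth``
levels, the standard depth-2 convention).  A merge whose subtree contains
any score above the threshold is broken; samples connected through
unbroken merges form the clusters.  Because the standardized coefficient
is bounded near the square root of its neighborhood size, a raw-height
cut is provided as well and is the default for the end-to-end search
(published threshold sweeps in the tens live on the height scale).  The
threshold is selected by a k-fold grid search maximizing the average
silhouette score, with Davies-Bouldin and Calinski-Harabasz indices as
tie-breakers, followed by a refinement pass around the best coarse value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from sklearn.metrics import (
    adjusted_rand_score,
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .features import FEATURE_NAMES

__all__ = [
    "ward_linkage",
    "inconsistency",
    "adaptive_cut",
    "cluster_quality",
    "optimize_threshold",
    "profile_clusters",
    "standardize",
    "cluster_features",
    "DEFAULT_GRID",
    "ClusterResult",
]


def standardize(features: np.ndarray) -> np.ndarray:
    """Z-score each feature column (zero-variance columns pass through
    centered).  The 45 features mix scales from ~1e-3 densities to
    node counts in the tens; Ward on raw Euclidean distances would be
    dominated by the large-scale columns."""
    x = np.asarray(features, dtype=np.float64)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def ward_linkage(features: np.ndarray) -> np.ndarray:
    """Ward-linkage merge table on Euclidean distances.

    Returns the standard (n-1) x 4 linkage matrix: child indices, merge
    height, merged size.  Heights follow the Lance-Williams Ward
    recurrence and are monotone non-decreasing.
    """
    x = np.asarray(features, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    return linkage(x, method="ward")


@dataclass(frozen=True)
class InconsistencyRecord:
    mean: float
    std: float
    count: int
    coefficient: float


def inconsistency(linkage_matrix: np.ndarray, depth: int = 2) -> list[InconsistencyRecord]:
    """Per-merge inconsistency coefficients.

    The neighborhood of merge i is itself plus descendant merges up to
    ``depth`` levels below; the coefficient is (h - mean)/std with ddof-1
    std, defined as 0 when the neighborhood has fewer than 2 merges or
    zero spread."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    z = np.asarray(linkage_matrix, dtype=np.float64)
    n = len(z) + 1

    def neighborhood(i: int, d: int) -> list[float]:
        heights = [z[i, 2]]
        if d > 1:
            for child in (int(z[i, 0]), int(z[i, 1])):
                if child >= n:
                    heights.extend(neighborhood(child - n, d - 1))
        return heights

    records = []
    for i in range(len(z)):
        h = neighborhood(i, depth)
        if len(h) < 2:
            records.append(InconsistencyRecord(z[i, 2], 0.0, len(h), 0.0))
            continue
        mean = float(np.mean(h))
        std = float(np.std(h, ddof=1))
        coeff = 0.0 if std == 0.0 else (z[i, 2] - mean) / std
        records.append(InconsistencyRecord(mean, std, len(h), float(coeff)))
    return records


def adaptive_cut(
    linkage_matrix: np.ndarray,
    records: list[InconsistencyRecord] | None = None,
    threshold: float = 1.15,
    depth: int = 2,
    criterion: str = "inconsistency",
) -> np.ndarray:
    """Cut the dendrogram adaptively: a merge is broken iff its score (or
    any score in its subtree) exceeds the threshold; samples connected
    through unbroken merges share a label, renumbered 0..k-1 by first
    occurrence in sample order.

    ``criterion="inconsistency"`` scores each merge by its standardized
    inconsistency coefficient; ``criterion="height"`` scores it by its raw
    linkage height (subtree propagation is then vacuous since Ward heights
    are monotone).  Published threshold sweeps in the tens only make sense
    on the height scale; the coefficient scale tops out near the square
    root of the neighborhood size."""
    z = np.asarray(linkage_matrix, dtype=np.float64)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if criterion not in ("inconsistency", "height"):
        raise ValueError(f"unknown cut criterion: {criterion!r}")
    n = len(z) + 1

    if criterion == "height":
        scores = z[:, 2]
    else:
        if records is None:
            records = inconsistency(z, depth=depth)
        scores = np.array([r.coefficient for r in records])

    subtree_max = np.empty(len(z))
    for i in range(len(z)):
        m = scores[i]
        for child in (int(z[i, 0]), int(z[i, 1])):
            if child >= n:
                m = max(m, subtree_max[child - n])
        subtree_max[i] = m

    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    cluster_of_merge: dict[int, int] = {}
    for i in range(len(z)):
        if subtree_max[i] > threshold:
            continue
        a, b = int(z[i, 0]), int(z[i, 1])
        ra = find(a) if a < n else find(cluster_of_merge[a - n])
        rb = find(b) if b < n else find(cluster_of_merge[b - n])
        parent[max(ra, rb)] = min(ra, rb)
        cluster_of_merge[i] = min(ra, rb)

    labels = np.empty(n, dtype=int)
    seen: dict[int, int] = {}
    for i in range(n):
        root = find(i)
        labels[i] = seen.setdefault(root, len(seen))
    return labels


def cluster_quality(features: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """Silhouette, Davies-Bouldin index and Calinski-Harabasz score
    (Euclidean throughout).  Undefined for fewer than 2 clusters or an
    all-singleton labeling."""
    x = np.asarray(features, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    labels = np.asarray(labels)
    k = len(np.unique(labels))
    if k < 2:
        raise ValueError("quality metrics require at least 2 clusters")
    if k >= len(labels):
        raise ValueError("quality metrics undefined for all-singleton clustering")
    return (
        float(silhouette_score(x, labels)),
        float(davies_bouldin_score(x, labels)),
        float(calinski_harabasz_score(x, labels)),
    )


def optimize_threshold(
    features: np.ndarray,
    grid: "list[float] | np.ndarray",
    n_folds: int = 5,
    seed: int = 0,
    depth: int = 2,
    criterion: str = "inconsistency",
) -> tuple[float, pd.DataFrame]:
    """Inconsistency-threshold grid search with k-fold metric averaging.

    Samples are partitioned into ``n_folds`` seeded folds; each fold's
    subset is clustered independently at every grid threshold and scored
    by the three quality indices (degenerate folds contribute silhouette
    -1, DBI +inf, CH 0).  The best threshold maximizes mean silhouette,
    with ties broken by minimum DBI then maximum CH.  Returns the chosen
    threshold and the per-threshold metrics table
    (columns threshold, silhouette, dbi, ch).

    Height thresholds are specified on the full-sample scale; Ward heights
    grow like the square root of the cluster sizes, so within a fold of m
    samples the threshold is rescaled by sqrt(m/n) before cutting."""
    grid = list(grid)
    if not grid:
        raise ValueError("threshold grid must not be empty")
    x = np.asarray(features, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    n = len(x)
    if n < 2 * n_folds:
        raise ValueError("need at least 2 samples per fold")
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), n_folds)

    rows = []
    for t in grid:
        sils, dbis, chs = [], [], []
        for fold in folds:
            xf = x[fold]
            z = ward_linkage(xf)
            t_fold = t * np.sqrt(len(xf) / n) if criterion == "height" else t
            labels = adaptive_cut(z, threshold=t_fold, depth=depth, criterion=criterion)
            k = len(np.unique(labels))
            if k < 2 or k >= len(labels):
                sils.append(-1.0)
                dbis.append(np.inf)
                chs.append(0.0)
                continue
            s, d, c = cluster_quality(xf, labels)
            sils.append(s)
            dbis.append(d)
            chs.append(c)
        rows.append(
            {
                "threshold": t,
                "silhouette": float(np.mean(sils)),
                "dbi": float(np.mean(dbis)),
                "ch": float(np.mean(chs)),
            }
        )
    table = pd.DataFrame(rows)
    if np.all(table["silhouette"] == -1.0):
        raise ValueError("every threshold in the grid was degenerate")
    best = sorted(
        range(len(table)),
        key=lambda i: (-table["silhouette"][i], table["dbi"][i], -table["ch"][i]),
    )[0]
    return float(table["threshold"][best]), table


@dataclass
class ClusterResult:
    labels: np.ndarray
    k: int
    threshold: float
    silhouette: float
    dbi: float
    ch: float
    metrics_table: pd.DataFrame


DEFAULT_GRID: tuple[float, ...] = tuple(np.round(np.arange(1.0, 4.01, 0.25), 2))


def cluster_features(
    features: np.ndarray,
    grid: "list[float] | np.ndarray | None" = None,
    n_folds: int = 5,
    seed: int = 0,
    depth: int = 4,
    scale: bool = True,
    criterion: str = "height",
    refine: bool = True,
) -> ClusterResult:
    """End-to-end adaptive clustering: standardize, grid-search the
    inconsistency threshold with k-fold averaging, then cluster the full
    sample at the chosen threshold.

    With the default ``criterion="height"`` the grid is derived from the
    dendrogram itself — a coarse sweep over the height range followed by a
    refinement pass around the best coarse value, mirroring the published
    coarse-then-refined threshold sweep.  ``criterion="inconsistency"``
    uses the standardized coefficient with a dense fixed grid
    (:data:`DEFAULT_GRID`) instead."""
    x = np.asarray(features, dtype=np.float64)
    if scale:
        x = standardize(x)
    z = ward_linkage(x)
    if grid is None:
        if criterion == "height":
            grid = np.linspace(0.05, 0.95, 19) * z[-1, 2]
        else:
            grid = list(DEFAULT_GRID)
    best_t, table = optimize_threshold(
        x, grid, n_folds=n_folds, seed=seed, depth=depth, criterion=criterion
    )
    if refine and len(grid) > 1:
        step = float(np.median(np.diff(np.sort(np.asarray(grid, dtype=np.float64)))))
        fine = np.linspace(best_t - step, best_t + step, 9)
        fine = fine[fine > 0]
        best_t, fine_table = optimize_threshold(
            x, fine, n_folds=n_folds, seed=seed, depth=depth, criterion=criterion
        )
        table = (
            pd.concat([table, fine_table], ignore_index=True)
            .drop_duplicates(subset="threshold")
            .sort_values("threshold", ignore_index=True)
        )
    labels = adaptive_cut(z, threshold=best_t, depth=depth, criterion=criterion)
    k = len(np.unique(labels))
    if 2 <= k < len(labels):
        s, d, c = cluster_quality(x, labels)
    else:
        s, d, c = float("nan"), float("nan"), float("nan")
    return ClusterResult(labels=labels, k=k, threshold=best_t, silhouette=s, dbi=d, ch=c, metrics_table=table)


def profile_clusters(
    features: pd.DataFrame,
    labels: np.ndarray,
    manifest: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-cluster phenotype summary: size, mean and population SD of the
    intersection density and of each feature block.  When a manifest with
    ``regime_label`` is given, also returns the cluster-by-regime
    contingency table and the adjusted Rand index."""
    labels = np.asarray(labels)
    blocks = {
        "density": ["density"],
        "seg": [n for n in FEATURE_NAMES if n.startswith("seg_")],
        "cent": [n for n in FEATURE_NAMES if n.startswith("cent_")],
        "glob": [n for n in FEATURE_NAMES if n.startswith("glob_")],
    }
    rows = []
    for lab in np.unique(labels):
        sel = features.loc[labels == lab]
        row: dict = {"cluster": int(lab), "size": int(len(sel))}
        for name, cols in blocks.items():
            vals = sel[cols].to_numpy().ravel()
            row[f"{name}_mean"] = float(vals.mean())
            row[f"{name}_sd"] = float(vals.std())
        rows.append(row)
    summary = pd.DataFrame(rows)

    extras: dict = {}
    if manifest is not None and "regime_label" in manifest:
        regimes = manifest["regime_label"].to_numpy()
        extras["contingency"] = pd.crosstab(
            pd.Series(labels, name="cluster"), pd.Series(regimes, name="regime")
        )
        extras["ari"] = float(adjusted_rand_score(regimes, labels))
    return summary, extras
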