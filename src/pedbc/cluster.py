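"""Subpopulation discovery in body-composition z-space.

Pipeline: prune nearly collinear z-scored indices (lean, muscle and water
indices are interchangeable at r > 0.99, with the muscle index kept as the
representative), run Ward hierarchical clustering on the surviving features
(BMI, FMI, MMI, BNI by default) cut at k = 5, optionally confirm with
k-means, and relabel clusters into the canonical order: 1-3 ascending along
the low/mid BMI axis, 4 = high BMI with high muscle, 5 = high BMI with
average muscle (the adiposity-dominant subgroup).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ClusterResult",
    "prune_collinear",
    "WardCluster",
    "ward_cluster",
    "KMeansCluster",
    "kmeans_cluster",
    "canonical_order",
    "adjusted_rand",
]


@dataclass
class ClusterResult:
    """Labels 1..k, per-cluster centroids, and the method's audit trail."""

    labels: np.ndarray
    k: int
    centroids: pd.DataFrame  # index 1..k, columns = feature names
    method: str
    linkage: np.ndarray | None = None  # ward merge history (scipy convention)
    inertia: float | None = None  # kmeans within-cluster SS
    seed: int | None = None


def prune_collinear(
    Z: pd.DataFrame, threshold: float = 0.99, representative: str = "mmi"
) -> list[str]:
    """Drop all but one member of each near-collinear feature group.

    Features whose pairwise |Pearson r| exceeds ``threshold`` are grouped by
    transitive closure; within a group the nominated representative is kept
    when present (matched case-insensitively, with or without a ``z_``
    prefix), otherwise the first member in column order. Returns the kept
    column names in input order.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    cols = list(Z.columns)
    if len(cols) < 2:
        return cols
    corr = Z.corr().abs().to_numpy()
    # union-find over the |r| > threshold graph
    parent = list(range(len(cols)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if corr[i, j] > threshold:
                parent[find(i)] = find(j)

    def matches(name: str) -> bool:
        stem = name.lower().removeprefix("z_")
        want = representative.lower().removeprefix("z_")
        return stem == want

    groups: dict[int, list[int]] = {}
    for i in range(len(cols)):
        groups.setdefault(find(i), []).append(i)
    keep = set()
    for members in groups.values():
        rep = next((i for i in members if matches(cols[i])), members[0])
        keep.add(rep)
    return [c for i, c in enumerate(cols) if i in keep]


def _centroids(Z: pd.DataFrame, labels: np.ndarray, k: int) -> pd.DataFrame:
    rows = {c: Z[labels == c].mean(axis=0) for c in range(1, k + 1)}
    out = pd.DataFrame(rows).T
    out.index.name = "cluster"
    return out


class WardCluster(BaseEstimator, ClusterMixin):
    """Agglomerative Ward minimum-variance clustering cut at ``n_clusters``.

    Wraps scipy's Ward linkage (Lance–Williams recurrence on squared
    Euclidean distances); the dendrogram is cut below the last
    ``n_clusters - 1`` merges. Deterministic. ``linkage_`` stores the merge
    history in scipy's convention (heights are Ward merge distances).
    """

    def __init__(self, n_clusters: int = 5):
        self.n_clusters = n_clusters

    def fit(self, X, y=None):
        Z = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        if Z.isna().any().any():
            raise ValueError("ward clustering requires a complete matrix")
        if len(Z) <= self.n_clusters:
            raise ValueError(
                f"need more than n_clusters={self.n_clusters} observations, got {len(Z)}"
            )
        self.linkage_ = hierarchy.linkage(Z.to_numpy(float), method="ward")
        self.labels_ = hierarchy.fcluster(
            self.linkage_, t=self.n_clusters, criterion="maxclust"
        )
        self.feature_names_in_ = np.asarray(Z.columns)
        self.centroids_ = _centroids(Z, self.labels_, self.n_clusters)
        return self

    def result(self) -> ClusterResult:
        check_is_fitted(self, "labels_")
        return ClusterResult(
            labels=self.labels_,
            k=self.n_clusters,
            centroids=self.centroids_,
            method="ward",
            linkage=self.linkage_,
        )


def ward_cluster(Z: pd.DataFrame, k: int = 5) -> ClusterResult:
    """One-shot Ward clustering into ``k`` clusters."""
    return WardCluster(n_clusters=k).fit(Z).result()


class KMeansCluster(BaseEstimator, ClusterMixin):
    """Lloyd's k-means with k-means++ seeding and ``n_init`` restarts."""

    def __init__(self, n_clusters: int = 5, seed: int = 0, n_init: int = 10):
        self.n_clusters = n_clusters
        self.seed = seed
        self.n_init = n_init

    def fit(self, X, y=None):
        Z = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        if len(Z) <= self.n_clusters:
            raise ValueError(
                f"need more than n_clusters={self.n_clusters} observations, got {len(Z)}"
            )
        km = KMeans(
            n_clusters=self.n_clusters,
            init="k-means++",
            n_init=self.n_init,
            random_state=self.seed,
        ).fit(Z.to_numpy(float))
        self.labels_ = km.labels_ + 1
        self.inertia_ = float(km.inertia_)
        self.n_iter_ = int(km.n_iter_)
        self.centroids_ = _centroids(Z, self.labels_, self.n_clusters)
        return self

    def result(self) -> ClusterResult:
        check_is_fitted(self, "labels_")
        return ClusterResult(
            labels=self.labels_,
            k=self.n_clusters,
            centroids=self.centroids_,
            method="kmeans",
            inertia=self.inertia_,
            seed=self.seed,
        )


def kmeans_cluster(Z: pd.DataFrame, k: int = 5, seed: int = 0, n_init: int = 10) -> ClusterResult:
    """One-shot k-means clustering into ``k`` clusters."""
    return KMeansCluster(n_clusters=k, seed=seed, n_init=n_init).fit(Z).result()


def canonical_order(
    result: ClusterResult,
    bmi_col: str = "z_bmi",
    mmi_col: str = "z_mmi",
    fmi_col: str = "z_fmi",
) -> ClusterResult:
    """Relabel five clusters into the canonical body-composition order.

    The three lowest-BMI-centroid clusters become 1, 2, 3 in ascending BMI;
    of the two highest-BMI clusters the one with the higher MMI centroid
    becomes 4 (balanced high build) and the other 5 (high fat, average
    muscle). BMI ties break by ascending FMI. Idempotent.
    """
    if result.k != 5:
        raise ValueError("canonical ordering is defined for exactly 5 clusters")
    cent = result.centroids
    for col in (bmi_col, mmi_col):
        if col not in cent.columns:
            raise KeyError(f"centroids lack required column {col!r}")
    fmi = cent[fmi_col] if fmi_col in cent.columns else pd.Series(0.0, index=cent.index)
    order = sorted(
        cent.index, key=lambda c: (cent.loc[c, bmi_col], fmi.loc[c])
    )
    low3, top2 = order[:3], order[3:]
    top2 = sorted(top2, key=lambda c: -cent.loc[c, mmi_col])  # higher MMI -> 4
    mapping = {old: new for new, old in enumerate(low3 + top2, start=1)}
    labels = np.array([mapping[c] for c in result.labels])
    centroids = cent.rename(index=mapping).sort_index()
    return replace(result, labels=labels, centroids=centroids)


def adjusted_rand(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions (ARI in [-1, 1])."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    return float(adjusted_rand_score(a, b))
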