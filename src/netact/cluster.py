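"""Sample clustering on correlation distance.

Two clusterings are provided, mirroring common tumor-stratification practice:
complete-linkage hierarchical bi-clustering (for ordered-heatmap export and
visual subcluster selection) and k-means (for contingency-table evaluation
against clinical annotations).  Distance between two sample profiles is
``1 - corr`` (Pearson by default, Spearman optional), ranging over [0, 2].

For k-means, each sample vector is centered and scaled to unit norm (after
rank transformation for Spearman), which makes squared Euclidean distance
proportional to correlation distance, so standard Lloyd iterations minimize a
correlation-distance objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .activity import standardize

__all__ = [
    "correlation_distance",
    "Dendrogram",
    "hcluster_complete",
    "cut_tree",
    "bicluster",
    "KMeansResult",
    "kmeans_correlation",
    "ClusterNumberReport",
    "select_k",
    "export_newick",
]


def correlation_distance(X: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Pairwise ``1 - corr`` distance between the *columns* of X.

    Raises for constant columns (correlation undefined), naming the sample.
    """
    if method not in {"pearson", "spearman"}:
        raise ValueError(f"unknown correlation method {method!r}")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 features per sample vector")
    values = X.to_numpy(dtype=float)
    sd = values.std(axis=0)
    if (sd == 0).any():
        bad = X.columns[np.argmax(sd == 0)]
        raise ValueError(f"constant sample vector {bad!r}: correlation undefined")
    if method == "spearman":
        values = np.apply_along_axis(rankdata, 0, values)
    corr = np.corrcoef(values, rowvar=False)
    d = 1.0 - corr
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=X.columns, columns=X.columns)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over named leaves.

    ``linkage`` is a scipy linkage matrix (n-1 rows of
    ``left, right, height, size``); ``ids`` are leaf names in original order;
    ``leaf_order`` is the left-to-right display order of the tree.
    """

    ids: list[str]
    linkage: np.ndarray
    leaf_order: list[str] = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage matrix does not match leaf count")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights decrease: linkage is not monotone")
        self.leaf_order = [self.ids[i] for i in sch.leaves_list(self.linkage)]

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def merges(self) -> list[tuple[int, int, float, int]]:
        return [
            (int(l), int(r), float(h), int(s)) for l, r, h, s in self.linkage
        ]


def hcluster_complete(d: pd.DataFrame) -> Dendrogram:
    """Complete-linkage (maximum inter-cluster distance) agglomeration."""
    ids = [str(c) for c in d.columns]
    if len(ids) < 2:
        raise ValueError("need at least 2 observations to cluster")
    dm = d.to_numpy(dtype=float)
    if not np.allclose(dm, dm.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    condensed = dm[np.triu_indices(len(ids), k=1)]
    Z = sch.linkage(condensed, method="complete")
    return Dendrogram(ids=ids, linkage=Z)


def cut_tree(dend: Dendrogram, k: int) -> pd.Series:
    """Cut the dendrogram into exactly k groups (removing the k-1 highest
    merges); labels are 1..k in order of first appearance."""
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    raw = sch.cut_tree(dend.linkage, n_clusters=k)[:, 0]
    relabel: dict[int, int] = {}
    labels = []
    for value in raw:
        relabel.setdefault(int(value), len(relabel) + 1)
        labels.append(relabel[int(value)])
    return pd.Series(labels, index=dend.ids, name="cluster")


def bicluster(
    X: pd.DataFrame, method: str = "pearson", standardize_first: bool = True
) -> tuple[Dendrogram, Dendrogram, pd.DataFrame]:
    """Independent complete-linkage clustering of rows and columns.

    Feature rows are standardized to mean 0 / sd 1 first (default); both
    trees use correlation distance on the standardized data.  Returns
    (row dendrogram, column dendrogram, standardized matrix reordered by both
    leaf orders) — positive cells sit above the feature mean, negative below,
    ready for red/green heatmap export.

    Row standardization is affine per feature, so it leaves feature-feature
    correlations (the row tree) unchanged but does affect sample-sample
    correlations; with ``standardize_first=False`` the operation is exactly
    symmetric under transposition.
    """
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("bicluster needs at least a 2x2 matrix")
    if standardize_first:
        std, _ = standardize(X)
    else:
        std = X.astype(float)
    col_dend = hcluster_complete(correlation_distance(std, method=method))
    row_dend = hcluster_complete(correlation_distance(std.T, method=method))
    ordered = std.iloc[
        sch.leaves_list(row_dend.linkage), sch.leaves_list(col_dend.linkage)
    ]
    return row_dend, col_dend, ordered


def _correlation_embedding(X: pd.DataFrame, method: str) -> np.ndarray:
    """Samples x features embedding where squared Euclidean distance is
    proportional to correlation distance between sample profiles."""
    values = X.to_numpy(dtype=float).T  # samples x features
    if method == "spearman":
        values = np.apply_along_axis(rankdata, 1, values)
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    if (norms == 0).any():
        bad = X.columns[int(np.argmax(norms[:, 0] == 0))]
        raise ValueError(f"constant sample vector {bad!r}: correlation undefined")
    return centered / norms


@dataclass
class KMeansResult:
    """Best-of-restarts Lloyd clustering of samples on correlation distance."""

    assignments: pd.Series  # sample id -> cluster label in 1..k
    centroids: np.ndarray
    inertia: float
    n_restarts: int
    seed: int
    method: str

    @property
    def k(self) -> int:
        return int(self.assignments.max())


def kmeans_correlation(
    X: pd.DataFrame,
    k: int,
    n_restarts: int = 100,
    seed: int = 0,
    method: str = "pearson",
) -> KMeansResult:
    """k-means over the correlation-distance embedding of the samples.

    k-means++ seeding, best of ``n_restarts`` by inertia, deterministic given
    ``seed``.  Cluster labels are 1..k in order of first appearance along the
    sample axis.
    """
    if method not in {"pearson", "spearman"}:
        raise ValueError(f"unknown correlation method {method!r}")
    n_samples = X.shape[1]
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_samples < k:
        raise ValueError(f"cannot form {k} clusters from {n_samples} samples")
    emb = _correlation_embedding(X, method)
    km = KMeans(
        n_clusters=k,
        n_init=n_restarts,
        max_iter=300,
        random_state=seed,
        init="k-means++",
        algorithm="lloyd",
    ).fit(emb)
    relabel: dict[int, int] = {}
    labels = []
    for value in km.labels_:
        relabel.setdefault(int(value), len(relabel) + 1)
        labels.append(relabel[int(value)])
    order = sorted(relabel, key=relabel.get)
    return KMeansResult(
        assignments=pd.Series(labels, index=X.columns, name="cluster"),
        centroids=km.cluster_centers_[order],
        inertia=float(km.inertia_),
        n_restarts=n_restarts,
        seed=seed,
        method=method,
    )


@dataclass
class ClusterNumberReport:
    """Average silhouette width per candidate k; chosen_k maximizes it."""

    silhouette_by_k: dict[int, float]
    chosen_k: int


def select_k(
    X: pd.DataFrame,
    k_range: tuple[int, int] = (2, 6),
    method: str = "pearson",
    seed: int = 0,
    n_restarts: int = 100,
) -> ClusterNumberReport:
    """Choose the number of clusters by average silhouette width.

    For each k in the inclusive range, runs `kmeans_correlation` and scores
    the partition on the correlation distance matrix; ties prefer smaller k.
    """
    lo, hi = k_range
    n = X.shape[1]
    if lo < 2 or hi > n - 1 or lo > hi:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    d = correlation_distance(X, method=method).to_numpy()
    scores: dict[int, float] = {}
    for k in range(lo, hi + 1):
        result = kmeans_correlation(X, k, n_restarts=n_restarts, seed=seed, method=method)
        scores[k] = float(
            silhouette_score(d, result.assignments.to_numpy(), metric="precomputed")
        )
    chosen = max(sorted(scores), key=lambda k: scores[k])
    return ClusterNumberReport(silhouette_by_k=scores, chosen_k=chosen)


def _quote_newick(name: str) -> str:
    if any(c in name for c in " \t\n()[]{}:;,'\""):
        return "'" + name.replace("'", "''") + "'"
    return name


def export_newick(dend: Dendrogram) -> str:
    """Serialize a dendrogram as a Newick string.

    Merge heights are treated as cluster diameters: a node at height h sits at
    radius h/2, and each branch length is the parent radius minus the child
    radius (leaves at radius 0).  Two leaves merging at height 1 therefore
    yield ``(A:0.5,B:0.5);``.
    """
    n = dend.n_leaves
    Z = dend.linkage

    def radius(node: int) -> float:
        return 0.0 if node < n else float(Z[node - n, 2]) / 2.0

    def render(node: int, parent_radius: float) -> str:
        length = parent_radius - radius(node)
        if node < n:
            return f"{_quote_newick(dend.ids[node])}:{length:g}"
        left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
        r = radius(node)
        return f"({render(left, r)},{render(right, r)}):{length:g}"

    root = 2 * n - 2
    r = radius(root)
    left, right = int(Z[root - n, 0]), int(Z[root - n, 1])
    return f"({render(left, r)},{render(right, r)});"
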