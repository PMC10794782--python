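"""Shared hierarchical-clustering and silhouette primitives.

Profile clustering throughout the package is agglomerative clustering on a
precomputed cosine-distance matrix, cut to an exact number of clusters.
The silhouette here is the textbook per-sample score evaluated on the same
precomputed distance matrix, vectorized so that a scan over many values of
k reuses one distance matrix and one dendrogram.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform


def cosine_distance_matrix(x: np.ndarray) -> np.ndarray:
    """Pairwise cosine distances between rows of ``x``.

    Rows with zero norm are treated as maximally distant from every other
    row (cosine similarity 0) rather than producing NaNs; this only arises
    for degenerate inputs such as shuffled null matrices with all-zero rows.
    """
    x = np.asarray(x, dtype=float)
    norms = np.linalg.norm(x, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = x / safe[:, None]
    sim = np.clip(unit @ unit.T, -1.0, 1.0)
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    # numerical guard: distances are ≥ 0
    return np.maximum(d, 0.0)


def hierarchical_labels(
    dist: np.ndarray, k: int, method: str = "average"
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster a square distance matrix into exactly ``k`` groups.

    Returns ``(labels, linkage_matrix)`` with dense integer labels starting
    at 0. The tree is cut at the smallest depth that yields exactly k
    clusters (scipy's ``cut_tree``).
    """
    n = dist.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    z = linkage(squareform(dist, checks=False), method=method)
    labels = cut_tree(z, n_clusters=k).ravel()
    return labels.astype(int), z


def cut_many(z: np.ndarray, ks: np.ndarray) -> np.ndarray:
    """Cut one dendrogram at several cluster counts; columns follow ``ks``."""
    return cut_tree(z, n_clusters=np.asarray(ks))


def mean_silhouette(dist: np.ndarray, labels: np.ndarray) -> float:
    """Mean per-sample silhouette on a precomputed distance matrix.

    s(i) = (b_i - a_i) / max(a_i, b_i) with a_i the mean distance to the
    other members of i's cluster and b_i the smallest mean distance to any
    other cluster; members of singleton clusters score 0 by convention.
    """
    labels = np.asarray(labels)
    n = dist.shape[0]
    uniq, inv = np.unique(labels, return_inverse=True)
    k = len(uniq)
    if k < 2 or k > n - 1:
        raise ValueError("silhouette needs 2 <= n_clusters <= n_samples - 1")
    onehot = np.zeros((n, k))
    onehot[np.arange(n), inv] = 1.0
    counts = onehot.sum(axis=0)
    sums = dist @ onehot  # (n, k): total distance from each point to each cluster
    own = counts[inv]
    a = sums[np.arange(n), inv] / np.maximum(own - 1, 1)
    mean_other = sums / counts[None, :]
    mean_other[np.arange(n), inv] = np.inf
    b = mean_other.min(axis=1)
    denom = np.maximum(a, b)
    with np.errstate(invalid="ignore"):
        s = np.where(denom > 0, (b - a) / denom, 0.0)  # coincident points: 0
    s[own == 1] = 0.0
    return float(s.mean())


def silhouette_over_cuts(dist: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    """Mean silhouette for each column of a ``cut_many`` label matrix."""
    return np.array([mean_silhouette(dist, cuts[:, j]) for j in range(cuts.shape[1])])
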