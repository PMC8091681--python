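"""Embedding quality metrics: KNI, mean Silhouette, and ARI.

KNI (k-nearest-neighbor index) is the fraction of a cell's k nearest
embedded neighbors (self excluded, Euclidean distance) that carry the same
label, averaged over all cells.  Values near 1 indicate homogeneous
neighborhoods of cell types; random mixing gives the chance level
sum_c m_c (m_c - 1) / (n (n - 1)) for class sizes m_c.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score, silhouette_score

DEFAULT_K = 10


def _as_labels(labels) -> np.ndarray:
    lab = np.asarray(labels)
    if lab.ndim != 1 or lab.size == 0:
        raise ValueError("labels must be a non-empty 1-D vector")
    return lab


def kni(Y: np.ndarray, labels, k: int = DEFAULT_K) -> float:
    """k-nearest-neighbor index of an embedding against a labeling.

    Distance ties at the k-th neighbor are broken by lower cell index so the
    result is deterministic.
    """
    Y = np.asarray(Y, dtype=np.float64)
    lab = _as_labels(labels)
    n = Y.shape[0]
    if lab.size != n:
        raise ValueError(f"labels length {lab.size} != number of cells {n}")
    if not 1 <= k < n:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    D = squareform(pdist(Y))
    np.fill_diagonal(D, np.inf)
    # stable sort => ties resolved toward the lower index
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    same = lab[order] == lab[:, None]
    return float(same.mean())


def kni_chance_level(labels) -> float:
    """Chance-level KNI: sum_c m_c (m_c - 1) / (n (n - 1))."""
    lab = _as_labels(labels)
    n = lab.size
    _, counts = np.unique(lab, return_counts=True)
    return float(np.sum(counts * (counts - 1)) / (n * (n - 1)))


def silhouette_mean(Y: np.ndarray, labels) -> float:
    """Mean Silhouette score (b - a)/max(a, b) in [-1, 1], Euclidean.

    Requires at least two distinct labels; singleton clusters score 0.
    """
    Y = np.asarray(Y, dtype=np.float64)
    lab = _as_labels(labels)
    if lab.size != Y.shape[0]:
        raise ValueError("labels length must match the number of cells")
    if len(np.unique(lab)) < 2:
        raise ValueError("silhouette undefined for a single label")
    return float(silhouette_score(Y, lab, metric="euclidean"))


def ari(labels1, labels2) -> float:
    """Adjusted Rand Index between two labelings of the same cells."""
    a = _as_labels(labels1)
    b = _as_labels(labels2)
    if a.size != b.size:
        raise ValueError(f"labelings differ in length: {a.size} vs {b.size}")
    return float(adjusted_rand_score(a, b))


def evaluate_embedding(Y: np.ndarray, labels, k: int = DEFAULT_K) -> dict:
    """KNI + mean Silhouette with a per-class KNI breakdown."""
    lab = _as_labels(labels)
    overall = kni(Y, lab, k=k)
    per_class = {}
    Yf = np.asarray(Y, dtype=np.float64)
    D = squareform(pdist(Yf))
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    same = lab[order] == lab[:, None]
    for c in np.unique(lab):
        per_class[str(c)] = float(same[lab == c].mean())
    return {
        "k": k,
        "kni": overall,
        "silhouette": silhouette_mean(Yf, lab),
        "kni_per_class": per_class,
    }


__all__ = [
    "kni",
    "kni_chance_level",
    "silhouette_mean",
    "ari",
    "evaluate_embedding",
    "DEFAULT_K",
]
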