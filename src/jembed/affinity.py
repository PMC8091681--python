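"""Per-modality high-dimensional similarity structures.

The SNE branch uses perplexity-calibrated Gaussian conditionals symmetrized
into a joint distribution P (off-diagonal entries sum to 1).  The UMAP branch
uses fuzzy k-NN membership graphs: per point, the distance to the nearest
neighbor is subtracted (so the nearest neighbor always has membership 1) and
a per-point bandwidth is solved by bisection so the smoothed neighbor count
equals log2(n_neighbors); directed strengths are symmetrized with the
probabilistic t-conorm a + b - a*b.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import squareform, pdist
from sklearn.neighbors import NearestNeighbors

from .datatypes import FuzzyGraph, ModalityView

# Exact brute-force k-NN below this size; tree/ANN search above.
EXACT_KNN_MAX_N = 5000


def pairwise_sq_dists(V: ModalityView | np.ndarray) -> np.ndarray:
    """Dense squared Euclidean distance matrix (zero diagonal, symmetric)."""
    X = V.values if isinstance(V, ModalityView) else np.asarray(V, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in input")
    D = squareform(pdist(X, metric="sqeuclidean"))
    return np.maximum(D, 0.0)


def _row_entropy_bits(d: np.ndarray, beta: float) -> tuple[float, np.ndarray]:
    """Shannon entropy (bits) and probabilities of one Gaussian conditional.

    ``d`` are squared distances to the other points, ``beta = 1/(2 sigma^2)``.
    """
    logits = -d * beta
    logits -= logits.max()
    p = np.exp(logits)
    s = p.sum()
    p /= s
    pos = p > 0
    h_nats = -np.sum(p[pos] * np.log(p[pos]))
    return h_nats / np.log(2.0), p


def calibrate_conditionals(
    D: np.ndarray,
    perplexity: float,
    tol: float = 1e-6,
    max_steps: int = 100,
) -> np.ndarray:
    """Row-stochastic Gaussian conditionals p_{j|i} with per-point bandwidth.

    For every point i, sigma_i is found by binary search on
    beta_i = 1/(2 sigma_i^2) so that the conditional distribution over the
    other points has perplexity 2^H equal to the target.
    """
    D = np.asarray(D, dtype=np.float64)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("D must be square")
    if perplexity > n - 1:
        raise ValueError(
            f"perplexity must be <= n - 1 = {n - 1}, got {perplexity}"
        )
    if perplexity <= 0:
        raise ValueError("perplexity must be positive")
    target_bits = np.log2(perplexity)
    P = np.zeros((n, n))
    idx = np.arange(n)
    for i in range(n):
        d = D[i, idx != i]
        beta, lo, hi = 1.0, 0.0, np.inf
        h, p = _row_entropy_bits(d, beta)
        step = 0
        while abs(h - target_bits) > tol:
            if h > target_bits:      # distribution too flat -> sharpen
                lo = beta
                beta = beta * 2.0 if np.isinf(hi) else (lo + hi) / 2.0
            else:
                hi = beta
                beta = (lo + hi) / 2.0
            h, p = _row_entropy_bits(d, beta)
            step += 1
            if step >= max_steps:
                raise RuntimeError(
                    f"perplexity calibration did not converge for row {i} "
                    f"(target {perplexity}, reached 2^{h:.4f})"
                )
        P[i, idx != i] = p
    return P


def symmetrize_P(P_cond: np.ndarray) -> np.ndarray:
    """Joint distribution p_ij = (p_{j|i} + p_{i|j}) / (2n).

    Off-diagonal entries sum to 1; diagonal is zero.
    """
    P_cond = np.asarray(P_cond, dtype=np.float64)
    n = P_cond.shape[0]
    if not np.allclose(P_cond.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rows of the conditional matrix must sum to 1")
    P = (P_cond + P_cond.T) / (2.0 * n)
    np.fill_diagonal(P, 0.0)
    return P


def modality_P(V: ModalityView, perplexity: float = 30.0) -> np.ndarray:
    """High-dimensional joint distribution P for one modality."""
    D = pairwise_sq_dists(V)
    return symmetrize_P(calibrate_conditionals(D, perplexity))


def _knn(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """k nearest neighbors excluding self; (distances, indices), sorted."""
    algo = "brute" if X.shape[0] <= EXACT_KNN_MAX_N else "auto"
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm=algo)
    nn.fit(X)
    dist, ind = nn.kneighbors(X)
    return dist[:, 1:], ind[:, 1:]


def smooth_knn_bandwidth(
    dists: np.ndarray,
    target: float,
    n_steps: int = 64,
    tol: float = 1e-5,
) -> float:
    """Bisection for sigma_i with sum_j exp(-max(0, d_ij - rho_i)/sigma) = target.

    ``dists`` are the rho-shifted nonnegative neighbor distances of one point.
    """
    lo, hi, mid = 0.0, np.inf, 1.0
    for _ in range(n_steps):
        val = float(np.exp(-dists / mid).sum())
        if abs(val - target) < tol:
            break
        if val > target:
            hi = mid
            mid = (lo + hi) / 2.0
        else:
            lo = mid
            mid = mid * 2.0 if np.isinf(hi) else (lo + hi) / 2.0
    return mid


def fuzzy_graph(V: ModalityView | np.ndarray, n_neighbors: int = 15) -> FuzzyGraph:
    """Symmetric fuzzy k-NN membership graph of one modality."""
    X = V.values if isinstance(V, ModalityView) else np.asarray(V, dtype=np.float64)
    n = X.shape[0]
    if not 2 <= n_neighbors < n:
        raise ValueError(f"n_neighbors must be in [2, {n - 1}], got {n_neighbors}")
    dist, ind = _knn(X, n_neighbors)
    target = np.log2(n_neighbors)
    rows, cols, vals = [], [], []
    for i in range(n):
        d = dist[i]
        rho = d[0]                       # distance to nearest neighbor
        shifted = np.maximum(d - rho, 0.0)
        sigma = smooth_knn_bandwidth(shifted, target)
        strengths = np.exp(-shifted / sigma)
        rows.extend([i] * n_neighbors)
        cols.extend(ind[i].tolist())
        vals.extend(strengths.tolist())
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    # probabilistic t-conorm: a + b - a*b
    S = A + A.T - A.multiply(A.T)
    S = sp.csr_matrix(S)
    S.data = np.clip(S.data, 0.0, 1.0)
    S.setdiag(0.0)
    S.eliminate_zeros()
    return FuzzyGraph(edges=S, n_neighbors=n_neighbors)


__all__ = [
    "pairwise_sq_dists",
    "calibrate_conditionals",
    "symmetrize_P",
    "modality_P",
    "fuzzy_graph",
    "smooth_knn_bandwidth",
]
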