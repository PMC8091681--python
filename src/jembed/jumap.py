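"""Joint UMAP (j-UMAP): a convex combination of per-modality fuzzy
cross-entropies with the same entropy-regularized weight learning as j-SNE.

Per modality k a fuzzy k-NN membership graph V^(k) is built once.  For fixed
weights alpha the attractive force on an edge (i, j) is proportional to
sum_k alpha_k v_ij^(k), so the embedding subproblem is standard UMAP
stochastic gradient descent on the combined graph
V_bar = sum_k alpha_k V^(k).  For fixed point locations the per-modality
fuzzy cross-entropy losses

    CE_k = -sum_(i<j) [ v log w + (1 - v) log(1 - w) ]

(with w the low-dimensional kernel (1 + a d^(2b))^-1 and v = 0 off the
graph; a single edge with w = v contributes the binary entropy of v, the
minimum over w) feed the shared closed-form weight update.  Conventional UMAP never
evaluates its loss; here the attractive part is summed exactly over stored
edges and the non-edge part is estimated from seeded uniform non-edge
samples, with the same sample reused across modalities within an outer
iteration so that loss differences between modalities are not sampling
noise.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from umap.layouts import optimize_layout_euclidean
from umap.umap_ import find_ab_params, make_epochs_per_sample

from .affinity import fuzzy_graph
from .datatypes import (
    FuzzyGraph,
    JointConfig,
    JointResult,
    ModalityView,
    OuterIterationRecord,
    UmapKernelParams,
    check_simplex,
    entropy_objective,
)
from .jsne import update_weights

_W_CLIP = 1e-12


def fit_ab(min_dist: float = 0.1, spread: float = 1.0) -> tuple[float, float]:
    """Least-squares fit of the smooth kernel (1 + a d^(2b))^-1 to the
    piecewise target (1 below min_dist, exponential decay beyond)."""
    if not 0 <= min_dist < spread:
        raise ValueError("require 0 <= min_dist < spread")
    try:
        a, b = find_ab_params(spread, min_dist)
    except Exception as exc:  # pragma: no cover - curve fit failure
        raise RuntimeError(f"kernel curve fit failed: {exc}") from exc
    return float(a), float(b)


def combine_graphs(V_list: list[FuzzyGraph], alpha: np.ndarray) -> FuzzyGraph:
    """Weighted-sum union V_bar = sum_k alpha_k V^(k).

    Strengths stay in (0, 1] because each v <= 1 and alpha is convex.
    """
    alpha = check_simplex(alpha)
    if len(V_list) != alpha.size:
        raise ValueError("one weight per graph required")
    n = V_list[0].n_cells
    for V in V_list[1:]:
        if V.n_cells != n:
            raise ValueError("graphs must share their cell count")
    M = sp.csr_matrix((n, n))
    for a, V in zip(alpha, V_list):
        if a > 0:
            M = M + a * V.edges
    M = sp.csr_matrix(M)
    M.data = np.clip(M.data, 0.0, 1.0)
    M.eliminate_zeros()
    return FuzzyGraph(edges=M, n_neighbors=max(V.n_neighbors for V in V_list))


def _kernel_w(Y: np.ndarray, i: np.ndarray, j: np.ndarray, a: float, b: float) -> np.ndarray:
    d2 = np.sum((Y[i] - Y[j]) ** 2, axis=1)
    w = 1.0 / (1.0 + a * d2**b)
    return np.clip(w, _W_CLIP, 1.0 - _W_CLIP)


def sample_negative_pairs(
    n: int, n_samples: int, seed: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Seeded uniform sample of unordered pairs i < j (edges not excluded;
    callers reject pairs present in their own graph)."""
    rng = rng or np.random.default_rng(seed)
    i = rng.integers(0, n, size=n_samples)
    j = rng.integers(0, n, size=n_samples)
    keep = i != j
    i, j = i[keep], j[keep]
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    return np.stack([lo, hi], axis=1)


def cross_entropy_term(
    V: FuzzyGraph,
    Y: np.ndarray,
    params: UmapKernelParams,
    neg_seed: int = 0,
    neg_pairs: np.ndarray | None = None,
) -> float:
    """Fuzzy cross entropy of one modality's graph against an embedding.

    The sum over stored edges (both the v-weighted attractive part and the
    (1-v) complement) is exact; the contribution of non-edge pairs (v = 0,
    i.e. -log(1 - w)) is estimated from ``neg_sample_rate`` uniform non-edge
    samples per edge, scaled to the total number of non-edge pairs.
    Deterministic given ``neg_seed`` (or an explicit ``neg_pairs`` sample,
    which callers may share across modalities).
    """
    Y = np.asarray(Y, dtype=np.float64)
    n = V.n_cells
    if Y.shape[0] != n:
        raise ValueError("embedding and graph disagree on cell count")
    a, b = params.a, params.b
    if a is None:
        a, b = fit_ab(params.min_dist, params.spread)
    U = sp.triu(V.edges, k=1).tocoo()
    i, j, v = U.row, U.col, np.clip(U.data, 0.0, 1.0)
    w = _kernel_w(Y, i, j, a, b)
    edge_term = float(-np.sum(v * np.log(w) + (1.0 - v) * np.log(1.0 - w)))
    n_edges = len(v)
    n_pairs = n * (n - 1) // 2
    n_non_edges = n_pairs - n_edges
    rate = params.ce_neg_rate
    if n_non_edges == 0 or (rate == 0 and neg_pairs is None):
        return edge_term
    if neg_pairs is None:
        neg_pairs = sample_negative_pairs(n, rate * max(n_edges, 1), neg_seed)
    edge_keys = set((i * n + j).tolist())
    keys = neg_pairs[:, 0] * n + neg_pairs[:, 1]
    mask = np.fromiter((k not in edge_keys for k in keys.tolist()), bool, len(keys))
    kept = neg_pairs[mask]
    if len(kept) == 0:
        return edge_term
    w_neg = _kernel_w(Y, kept[:, 0], kept[:, 1], a, b)
    rep = -float(np.mean(np.log(1.0 - w_neg))) * n_non_edges
    return edge_term + rep


def union_ce_losses(
    V_list: list[FuzzyGraph],
    Y: np.ndarray,
    a: float,
    b: float,
    neg_pairs: np.ndarray | None = None,
) -> np.ndarray:
    """Per-modality cross entropies evaluated on the union of edge sets.

    Every modality is scored on the same set of pairs: the union of all
    modalities' stored edges (exact, with v_k = 0 where modality k lacks the
    edge) plus an optional shared non-edge background sample scaled to the
    number of pairs outside the union.  Because the background pairs carry
    v_k = 0 for every modality, they shift all losses by the same amount and
    cancel in the softmax weight update; modality differences come entirely
    from pairs on which their fuzzy graphs disagree.  Returned losses are
    means per union edge.
    """
    n = V_list[0].n_cells
    union = sp.triu(sum(V.edges for V in V_list), k=1).tocoo()
    i, j = union.row, union.col
    n_union = len(i)
    w = _kernel_w(Y, i, j, a, b)
    background = 0.0
    if neg_pairs is not None and len(neg_pairs):
        union_keys = set((i * n + j).tolist())
        keys = neg_pairs[:, 0] * n + neg_pairs[:, 1]
        mask = np.fromiter(
            (k not in union_keys for k in keys.tolist()), bool, len(keys)
        )
        kept = neg_pairs[mask]
        if len(kept):
            w_neg = _kernel_w(Y, kept[:, 0], kept[:, 1], a, b)
            n_non = n * (n - 1) // 2 - n_union
            background = -float(np.mean(np.log(1.0 - w_neg))) * n_non
    losses = np.empty(len(V_list))
    for k, V in enumerate(V_list):
        v = np.clip(np.asarray(V.edges[i, j]).ravel(), 0.0, 1.0)
        ce = float(-np.sum(v * np.log(w) + (1.0 - v) * np.log(1.0 - w)))
        losses[k] = (ce + background) / max(n_union, 1)
    return losses


def _spectral_init(
    graph: sp.csr_matrix, dim: int, seed: int, data: np.ndarray
) -> np.ndarray:
    """Spectral layout of the combined graph, scaled to UMAP's conventional
    extent; falls back to a seeded Gaussian when the graph is disconnected."""
    rng = np.random.default_rng(seed)
    n_comp, _ = connected_components(graph, directed=False)
    if n_comp > 1:
        return rng.normal(scale=10.0, size=(graph.shape[0], dim))
    from umap.spectral import spectral_layout

    Y = spectral_layout(data, graph, dim, np.random.RandomState(seed))
    expansion = 10.0 / max(np.abs(Y).max(), 1e-12)
    return Y * expansion + rng.normal(scale=1e-4, size=Y.shape)


def _sgd_epoch_layout(
    Y: np.ndarray,
    graph: sp.csr_matrix,
    n_epochs: int,
    a: float,
    b: float,
    neg_sample_rate: int,
    rng_state: np.ndarray,
    initial_alpha: float = 1.0,
) -> np.ndarray:
    """One call of UMAP's edge-sampling SGD on the combined graph."""
    g = graph.copy().tocoo()
    # standard UMAP pruning: edges too weak to be sampled even once
    cutoff = g.data.max() / float(n_epochs)
    g.data[g.data < cutoff] = 0.0
    g = sp.coo_matrix(g)
    g.eliminate_zeros()
    epochs_per_sample = make_epochs_per_sample(g.data, n_epochs)
    head = g.row.astype(np.int32)
    tail = g.col.astype(np.int32)
    Y32 = np.ascontiguousarray(Y, dtype=np.float32)
    Y32 = optimize_layout_euclidean(
        Y32,
        Y32,
        head,
        tail,
        n_epochs,
        graph.shape[0],
        epochs_per_sample,
        a,
        b,
        rng_state,
        gamma=1.0,
        initial_alpha=initial_alpha,
        negative_sample_rate=neg_sample_rate,
        parallel=False,
        verbose=False,
        move_other=True,
    )
    return np.asarray(Y32, dtype=np.float64)


def run_jumap(
    views: list[ModalityView],
    config: JointConfig | None = None,
    kernel: UmapKernelParams | None = None,
    V_list: list[FuzzyGraph] | None = None,
) -> JointResult:
    """Alternating optimization of the j-UMAP objective.

    Per-modality fuzzy graphs are built once (they do not depend on alpha).
    Each outer iteration combines them with the current weights, runs
    edge-sampling SGD (spectral initialization on the first iteration, warm
    start afterwards), evaluates the per-modality cross entropies on a
    shared negative sample, and updates alpha with the common closed form.
    """
    config = config or JointConfig(lambda_reg=1.0)
    kernel = kernel or UmapKernelParams()
    if not views:
        raise ValueError("need at least one modality view")
    n = views[0].n_cells
    if n < 4:
        raise ValueError("need at least 4 cells to embed")
    for v in views:
        if v.n_cells != n:
            raise ValueError(
                f"modality {v.modality_name!r} has {v.n_cells} cells, expected {n}"
            )
    if V_list is None:
        V_list = [fuzzy_graph(v, min(config.n_neighbors, n - 1)) for v in views]
    a, b = kernel.a, kernel.b
    if a is None:
        a, b = fit_ab(kernel.min_dist, kernel.spread)
    K = len(V_list)
    alpha = np.full(K, 1.0 / K)
    seed_stream = np.random.RandomState(config.seed % (2**31))
    history: list[OuterIterationRecord] = []
    Y = None
    max_edges = max(sp.triu(V.edges, k=1).nnz for V in V_list)
    n_edges = [max(sp.triu(V.edges, k=1).nnz, 1) for V in V_list]
    # one fixed non-edge sample, shared across modalities and outer
    # iterations: per-modality loss differences and their changes over the
    # alternation are then never sampling noise
    neg_seed = int(seed_stream.randint(0, 2**31 - 1))
    neg_pairs = sample_negative_pairs(n, kernel.ce_neg_rate * max_edges, neg_seed)
    for t in range(config.max_outer_iter):
        V_bar = combine_graphs(V_list, alpha)
        if Y is None:
            if config.init == "gaussian":
                Y = np.random.default_rng(config.seed).normal(
                    scale=10.0, size=(n, config.n_components_embed)
                )
            else:
                Y = _spectral_init(
                    V_bar.edges, config.n_components_embed, config.seed,
                    views[0].values,
                )
            n_epochs = kernel.n_epochs_first
        else:
            n_epochs = kernel.n_epochs_later
        rng_state = seed_stream.randint(-(2**31) + 1, 2**31 - 1, 3).astype(np.int64)
        # annealed SGD learning rate across outer iterations: alternating
        # minimization over (Y, alpha) needs diminishing inner stochasticity
        # for the weight trajectory to settle
        initial_alpha = 0.5**t
        Y = _sgd_epoch_layout(
            Y, V_bar.edges, n_epochs, a, b, kernel.neg_sample_rate, rng_state,
            initial_alpha=initial_alpha,
        )
        # weight-update losses: mean CE per union edge, every modality scored
        # on the same pair set (see union_ce_losses) — raw per-graph CE sums
        # are dominated by a modality-independent geometric background and
        # grow with data size, so they neither discriminate informative from
        # noisy modalities nor let a single lambda transfer across data sets
        losses = union_ce_losses(V_list, Y, a, b, neg_pairs=neg_pairs)
        if config.fixed_uniform_weights:
            alpha_new = np.full(K, 1.0 / K)
        else:
            alpha_new = update_weights(losses, config.lambda_reg)
        history.append(
            OuterIterationRecord(
                iteration=t,
                losses=losses,
                alpha=alpha_new.copy(),
                objective=entropy_objective(losses, alpha_new, config.lambda_reg),
            )
        )
        delta = float(np.max(np.abs(alpha_new - alpha)))
        alpha = alpha_new
        if delta < config.alpha_tol:
            break
    return JointResult(
        embedding=Y,
        weights=alpha,
        history=history,
        modality_names=[v.modality_name for v in views],
        cell_ids=views[0].cell_ids,
    )


__all__ = [
    "fit_ab",
    "combine_graphs",
    "cross_entropy_term",
    "sample_negative_pairs",
    "run_jumap",
]
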