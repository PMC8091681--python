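"""Joint t-SNE (j-SNE): a convex combination of per-modality KL divergences
with entropy-regularized, learned modality weights.

The objective over an embedding Y and simplex weights alpha is

    C(Y, alpha) = sum_k alpha_k KL(P^(k) || Q(Y)) + lambda * sum_k alpha_k log alpha_k

where P^(k) is the perplexity-calibrated joint distribution of modality k and
Q the Student-t similarity distribution of the embedding.  Because every KL
term shares the same Q, for fixed alpha the embedding subproblem is exactly
t-SNE on the convex combination P_bar = sum_k alpha_k P^(k):

    sum_k alpha_k KL(P^(k)||Q) = -sum_{ij} P_bar_ij log q_ij + const(Y).

For fixed Y the weight subproblem  min_alpha sum_k alpha_k L_k
+ lambda sum_k alpha_k log alpha_k  on the simplex has the closed-form
solution alpha_k proportional to exp(-L_k / lambda); lambda -> 0 selects the
single most informative modality, lambda -> inf gives uniform weights.  The
two subproblems alternate, each exactly minimized, so the total objective is
non-increasing across updates.
"""

from __future__ import annotations

import numpy as np

from .affinity import modality_P, pairwise_sq_dists
from .datatypes import (
    JointConfig,
    JointResult,
    ModalityView,
    OuterIterationRecord,
    check_simplex,
    entropy_objective,
)

EPS = 1e-12  # floor inside logs, matching reference t-SNE practice


def aggregate_P(P_list: list[np.ndarray], alpha: np.ndarray) -> np.ndarray:
    """Convex combination P_bar = sum_k alpha_k P^(k)."""
    alpha = check_simplex(alpha)
    if len(P_list) != alpha.size:
        raise ValueError("one weight per affinity matrix required")
    n = P_list[0].shape[0]
    for P in P_list:
        if P.shape != (n, n):
            raise ValueError("affinity matrices must share their shape")
    out = np.zeros((n, n))
    for a, P in zip(alpha, P_list):
        out += a * P
    return out


def _student_t_weights(Y: np.ndarray) -> np.ndarray:
    """Unnormalized Student-t kernel (1 + ||y_i - y_j||^2)^-1, zero diagonal."""
    W = 1.0 / (1.0 + pairwise_sq_dists(np.asarray(Y, dtype=np.float64)))
    np.fill_diagonal(W, 0.0)
    return W


def low_dim_Q(Y: np.ndarray) -> np.ndarray:
    """Embedding similarity distribution Q, normalized over off-diagonal pairs."""
    W = _student_t_weights(Y)
    return W / W.sum()


def kl_term(P: np.ndarray, Q: np.ndarray) -> float:
    """KL(P || Q) over off-diagonal pairs, with 0 * log 0 = 0."""
    P = np.asarray(P, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    if P.shape != Q.shape:
        raise ValueError("shape mismatch between P and Q")
    mask = P > 0
    if np.any(Q[mask] <= 0):
        raise ValueError("Q is zero where P has mass; KL undefined")
    return float(np.sum(P[mask] * np.log(P[mask] / Q[mask])))


def jsne_gradient(P_bar: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Gradient of sum_k alpha_k KL(P^(k)||Q) w.r.t. Y, via P_bar.

    The t-SNE form: dC/dy_i = 4 sum_j (pbar_ij - q_ij) w_ij (y_i - y_j)
    with w_ij the unnormalized Student-t kernel.
    """
    Y = np.asarray(Y, dtype=np.float64)
    W = _student_t_weights(Y)
    Q = W / W.sum()
    M = (P_bar - Q) * W
    # sum_j M_ij (y_i - y_j) = (diag(M 1) - M) Y
    return 4.0 * ((np.diag(M.sum(axis=1)) - M) @ Y)


def update_weights(losses: np.ndarray, lambda_reg: float) -> np.ndarray:
    """Exact minimizer of sum_k alpha_k L_k + lambda sum_k alpha_k log alpha_k
    on the simplex: alpha_k proportional to exp(-L_k / lambda).

    ``lambda_reg = 0`` returns the one-hot vertex at the smallest loss
    (first index on ties) — the analytic limit.
    """
    L = np.asarray(losses, dtype=np.float64)
    if L.ndim != 1 or L.size == 0:
        raise ValueError("losses must be a non-empty vector")
    if not np.all(np.isfinite(L)):
        raise ValueError("losses must be finite")
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be nonnegative")
    if lambda_reg == 0:
        alpha = np.zeros_like(L)
        alpha[int(np.argmin(L))] = 1.0
        return alpha
    logits = -(L - L.min()) / lambda_reg
    alpha = np.exp(logits)
    return alpha / alpha.sum()


def _init_embedding(views: list[ModalityView], config: JointConfig) -> np.ndarray:
    n = views[0].n_cells
    d = config.n_components_embed
    rng = np.random.default_rng(config.seed)
    if config.init == "pca":
        from sklearn.decomposition import PCA

        X = np.concatenate([v.values for v in views], axis=1)
        ncomp = min(d, X.shape[1], n - 1)
        Y = PCA(n_components=ncomp, svd_solver="full").fit_transform(X)
        if ncomp < d:
            Y = np.pad(Y, ((0, 0), (0, d - ncomp)))
        # shrink to the usual small-scale start so early exaggeration can act
        return Y / max(Y[:, 0].std(), EPS) * 1e-4
    return rng.normal(scale=1e-4, size=(n, d))


def gradient_descent(
    P: np.ndarray,
    Y0: np.ndarray,
    n_iter: int,
    learning_rate: float = 200.0,
    early_exaggeration: float | None = None,
    exaggeration_iters: int = 0,
) -> np.ndarray:
    """Reference exact O(n^2) t-SNE gradient descent with momentum and gains.

    Momentum 0.5 for the first 250 steps then 0.8; adaptive per-coordinate
    gains as in the original t-SNE implementation.  If requested, P is
    multiplied by ``early_exaggeration`` for the first ``exaggeration_iters``
    steps.
    """
    Y = np.array(Y0, dtype=np.float64, copy=True)
    vel = np.zeros_like(Y)
    gains = np.ones_like(Y)
    for it in range(n_iter):
        exagg = early_exaggeration if it < exaggeration_iters else None
        grad = jsne_gradient(P * exagg if exagg else P, Y)
        momentum = 0.5 if it < 250 else 0.8
        inc = np.sign(grad) != np.sign(vel)
        gains = np.where(inc, gains + 0.2, gains * 0.8)
        gains = np.maximum(gains, 0.01)
        vel = momentum * vel - learning_rate * gains * grad
        Y += vel
    return Y - Y.mean(axis=0)


def tsne_embed(
    P: np.ndarray,
    config: JointConfig,
    Y0: np.ndarray | None = None,
) -> np.ndarray:
    """Plain (single-distribution) t-SNE on a precomputed P — the K=1 case."""
    if Y0 is None:
        n = P.shape[0]
        rng = np.random.default_rng(config.seed)
        Y0 = rng.normal(scale=1e-4, size=(n, config.n_components_embed))
    return gradient_descent(
        P,
        Y0,
        n_iter=config.inner_iters_first,
        learning_rate=config.learning_rate,
        early_exaggeration=config.early_exaggeration,
        exaggeration_iters=min(250, config.inner_iters_first // 2),
    )


def run_jsne(
    views: list[ModalityView],
    config: JointConfig | None = None,
    P_list: list[np.ndarray] | None = None,
) -> JointResult:
    """Alternating optimization of the j-SNE objective.

    Per outer iteration: (a) build P_bar from the current weights and run
    t-SNE gradient descent — a full schedule with early exaggeration on the
    first outer iteration, shorter warm-started refinement afterwards;
    (b) evaluate L_k = KL(P^(k)||Q(Y)) and update alpha in closed form.
    Stops when max|delta alpha| < ``alpha_tol`` or after ``max_outer_iter``
    iterations.  Fully deterministic for a fixed seed.

    ``P_list`` may supply precomputed affinity matrices (then ``views`` is
    only used for shape validation and may contain the same views).
    """
    config = config or JointConfig()
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
    if P_list is None:
        P_list = [modality_P(v, config.perplexity) for v in views]
    K = len(P_list)
    alpha = np.full(K, 1.0 / K)
    Y = _init_embedding(views, config)
    history: list[OuterIterationRecord] = []
    for t in range(config.max_outer_iter):
        P_bar = aggregate_P(P_list, alpha)
        if t == 0:
            Y = gradient_descent(
                P_bar,
                Y,
                n_iter=config.inner_iters_first,
                learning_rate=config.learning_rate,
                early_exaggeration=config.early_exaggeration,
                exaggeration_iters=min(250, config.inner_iters_first // 2),
            )
        else:
            Y = gradient_descent(
                P_bar, Y, n_iter=config.inner_iters_later,
                learning_rate=config.learning_rate,
            )
        Q = low_dim_Q(Y)
        losses = np.array([kl_term(P, Q) for P in P_list])
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
    "aggregate_P",
    "low_dim_Q",
    "kl_term",
    "jsne_gradient",
    "update_weights",
    "gradient_descent",
    "tsne_embed",
    "run_jsne",
]
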