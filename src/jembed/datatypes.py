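"""Shared containers for multimodal embedding runs.

A *modality* is one molecular layer measured per cell (mRNA counts, ADT
surface-protein counts, chromatin accessibility, ...) over a shared, ordered
set of cells.  Raw data enter as :class:`CountMatrix`, are preprocessed into
:class:`ModalityView` objects, and the joint optimizers return a
:class:`JointResult` holding the embedding, the learned modality weights
``alpha`` (a point on the probability simplex) and the per-outer-iteration
trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.sparse as sp

SIMPLEX_ATOL = 1e-10


def check_simplex(alpha: np.ndarray, atol: float = SIMPLEX_ATOL) -> np.ndarray:
    """Validate that ``alpha`` lies on the probability simplex.

    Returns the array as float64.  Raises ``ValueError`` otherwise.
    """
    alpha = np.asarray(alpha, dtype=np.float64)
    if alpha.ndim != 1 or alpha.size == 0:
        raise ValueError("alpha must be a non-empty 1-D vector")
    if np.any(alpha < -atol):
        raise ValueError(f"alpha has negative entries: {alpha}")
    if abs(alpha.sum() - 1.0) > max(atol, 1e-8 * alpha.size):
        raise ValueError(f"alpha must sum to 1, got {alpha.sum()!r}")
    return np.clip(alpha, 0.0, None)


@dataclass
class CountMatrix:
    """Raw cells x features nonnegative integer counts for one modality."""

    values: np.ndarray
    cell_ids: list[str]
    feature_ids: list[str]
    modality_name: str = "modality"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("counts must be a 2-D cells x features matrix")
        if np.any(self.values < 0):
            raise ValueError(f"negative counts in modality {self.modality_name!r}")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.allclose(self.values, np.round(self.values)):
                raise ValueError(
                    f"non-integer counts in modality {self.modality_name!r}"
                )
            self.values = np.round(self.values).astype(np.int64)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("cell_ids length does not match row count")
        if len(self.feature_ids) != self.values.shape[1]:
            raise ValueError("feature_ids length does not match column count")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids must be unique")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class ModalityView:
    """Processed real-valued view of one modality (post log / PCA).

    ``transform_log`` records the preprocessing steps applied, for
    provenance.
    """

    values: np.ndarray
    modality_name: str = "modality"
    cell_ids: list[str] | None = None
    transform_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("view values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(
                f"non-finite values in view of modality {self.modality_name!r}"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


@dataclass
class FuzzyGraph:
    """Sparse symmetric fuzzy k-NN membership graph (UMAP branch).

    Stored strengths lie in (0, 1]; the diagonal is empty.
    """

    edges: sp.csr_matrix
    n_neighbors: int

    def __post_init__(self) -> None:
        self.edges = sp.csr_matrix(self.edges)
        if self.edges.shape[0] != self.edges.shape[1]:
            raise ValueError("fuzzy graph must be square")
        if self.edges.nnz:
            d = self.edges.data
            if np.any(d <= 0) or np.any(d > 1.0 + 1e-12):
                raise ValueError("membership strengths must lie in (0, 1]")
        if np.any(self.edges.diagonal() != 0):
            raise ValueError("fuzzy graph diagonal must be empty")

    @property
    def n_cells(self) -> int:
        return self.edges.shape[0]


@dataclass
class JointConfig:
    """Settings shared by the j-SNE and j-UMAP alternating optimizers.

    ``lambda_reg`` is the entropy-regularization strength on the modality
    weights: large values pull ``alpha`` toward uniform, ``lambda_reg = 0``
    selects the single most informative modality.  The embedding subproblem
    runs ``inner_iters_first`` gradient steps on the first outer iteration
    (with early exaggeration for the t-SNE branch) and ``inner_iters_later``
    warm-started steps thereafter.
    """

    lambda_reg: float = 3.0
    max_outer_iter: int = 10
    perplexity: float = 30.0
    n_neighbors: int = 15
    n_components_embed: int = 2
    inner_iters_first: int = 500
    inner_iters_later: int = 100
    early_exaggeration: float = 12.0
    learning_rate: float = 200.0
    seed: int = 0
    alpha_tol: float = 1e-3
    init: str = "gaussian"
    fixed_uniform_weights: bool = False

    def __post_init__(self) -> None:
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be nonnegative")
        if self.max_outer_iter < 1:
            raise ValueError("max_outer_iter must be >= 1")
        if self.init not in {"gaussian", "pca", "spectral"}:
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class UmapKernelParams:
    """Low-dimensional kernel and SGD settings for the UMAP branch.

    The embedded-space similarity is ``w_ij = (1 + a * d^(2b))^-1`` with
    ``(a, b)`` fitted from ``min_dist`` / ``spread``.
    """

    a: float | None = None
    b: float | None = None
    min_dist: float = 0.1
    spread: float = 1.0
    n_epochs_first: int = 200
    n_epochs_later: int = 50
    neg_sample_rate: int = 5
    ce_neg_rate: int = 50

    def __post_init__(self) -> None:
        if (self.a is None) != (self.b is None):
            raise ValueError("provide both a and b, or neither")
        if self.a is not None and (self.a <= 0 or self.b <= 0):
            raise ValueError("kernel parameters a, b must be positive")


@dataclass
class OuterIterationRecord:
    """One outer iteration of the alternating scheme."""

    iteration: int
    losses: np.ndarray          # per-modality divergence L_k at current Y
    alpha: np.ndarray           # weights after the convex update
    objective: float            # C = sum_k alpha_k L_k + lambda sum_k alpha_k log alpha_k

    def to_dict(self) -> dict:
        return {
            "iteration": self.iteration,
            "losses": [float(x) for x in self.losses],
            "alpha": [float(x) for x in self.alpha],
            "objective": float(self.objective),
        }


@dataclass
class JointResult:
    """Outcome of a joint embedding run."""

    embedding: np.ndarray
    weights: np.ndarray
    history: list[OuterIterationRecord]
    modality_names: list[str] = field(default_factory=list)
    cell_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.weights = check_simplex(self.weights)
        for rec in self.history:
            check_simplex(rec.alpha)


def entropy_objective(losses: Sequence[float], alpha: np.ndarray, lambda_reg: float) -> float:
    """Total objective C = sum_k alpha_k L_k + lambda * sum_k alpha_k log alpha_k.

    Uses the convention 0 * log 0 = 0.
    """
    alpha = np.asarray(alpha, dtype=np.float64)
    losses = np.asarray(losses, dtype=np.float64)
    pos = alpha > 0
    ent = float(np.sum(alpha[pos] * np.log(alpha[pos])))
    return float(alpha @ losses) + lambda_reg * ent


__all__ = [
    "CountMatrix",
    "ModalityView",
    "FuzzyGraph",
    "JointConfig",
    "UmapKernelParams",
    "OuterIterationRecord",
    "JointResult",
    "check_simplex",
    "entropy_objective",
    "replace",
]
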