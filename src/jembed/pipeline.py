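"""High-level entry points: counts in, joint embedding out, plus the
conventional single-view and concatenation baselines used for comparison."""

from __future__ import annotations

import numpy as np

from .datatypes import (
    CountMatrix,
    JointConfig,
    JointResult,
    ModalityView,
    UmapKernelParams,
)
from .preprocess import frobenius_concat, pca_project, prepare_views
from .jsne import run_jsne
from .jumap import run_jumap

DEFAULT_LAMBDA = {"jsne": 3.0, "jumap": 1.0}


def default_config(method: str, **overrides) -> JointConfig:
    """Method-specific defaults; notably lambda = 3 for j-SNE, 1 for j-UMAP."""
    if method not in DEFAULT_LAMBDA:
        raise ValueError(f"method must be one of {sorted(DEFAULT_LAMBDA)}")
    overrides.setdefault("lambda_reg", DEFAULT_LAMBDA[method])
    return JointConfig(**overrides)


def embed_views(
    views: list[ModalityView],
    method: str = "jsne",
    config: JointConfig | None = None,
    kernel: UmapKernelParams | None = None,
) -> JointResult:
    config = config or default_config(method)
    if method == "jsne":
        return run_jsne(views, config)
    if method == "jumap":
        return run_jumap(views, config, kernel)
    raise ValueError(f"unknown method {method!r}")


def embed_counts(
    modalities: list[CountMatrix],
    method: str = "jsne",
    config: JointConfig | None = None,
    kernel: UmapKernelParams | None = None,
    n_components: int = 20,
) -> JointResult:
    """Full pipeline: log-normalize + PCA each modality, then run the joint
    optimizer."""
    views = prepare_views(modalities, n_components=n_components)
    return embed_views(views, method=method, config=config, kernel=kernel)


def concat_baseline_embedding(
    modalities: list[CountMatrix],
    method: str = "jsne",
    normalize: bool = True,
    config: JointConfig | None = None,
    kernel: UmapKernelParams | None = None,
    n_components: int = 20,
) -> JointResult:
    """Conventional t-SNE/UMAP on the (optionally Frobenius-normalized)
    feature-wise concatenation of the count matrices, reduced by PCA —
    the single-view baseline for multimodal data."""
    view = frobenius_concat(modalities, normalize=normalize)
    ncomp = min(n_components, view.values.shape[1], view.n_cells - 1)
    view = pca_project(view, ncomp)
    config = config or default_config(method)
    return embed_views([view], method=method, config=config, kernel=kernel)


def unimodal_embedding(
    view: ModalityView,
    method: str = "jsne",
    config: JointConfig | None = None,
    kernel: UmapKernelParams | None = None,
) -> JointResult:
    """Plain t-SNE/UMAP of a single modality (the K=1 joint run)."""
    return embed_views([view], method=method, config=config, kernel=kernel)


def views_from_sim(modalities: dict, n_components: int = 20) -> list[ModalityView]:
    """Preprocess a simulated modality dict (CountMatrix entries get
    log-normalize + PCA, ModalityView entries pass through)."""
    views: list[ModalityView] = []
    for m in modalities.values():
        if isinstance(m, ModalityView):
            views.append(m)
        else:
            views.extend(prepare_views([m], n_components=n_components))
    return views


__all__ = [
    "default_config",
    "embed_views",
    "embed_counts",
    "concat_baseline_embedding",
    "unimodal_embedding",
    "views_from_sim",
    "DEFAULT_LAMBDA",
]
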