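"""Count-matrix preprocessing: library-size normalization, log1p, PCA,
and the concatenation baselines.

The embeddings consume :class:`~jembed.datatypes.ModalityView` objects.  The
standard route is ``log_normalize`` (scale every cell to the median total
count, then log1p) followed by ``pca_project`` to 20 or 50 components.  ADT
panels with fewer antibodies than the requested component count may skip PCA.
"""

from __future__ import annotations

import numpy as np
from sklearn.decomposition import PCA

from .datatypes import CountMatrix, ModalityView


def log_normalize(X: CountMatrix) -> ModalityView:
    """Scale each cell to the median total count, then apply log1p.

    Raises ``ValueError`` if any cell has zero total counts (the scale
    factor is undefined for it), naming the offending cell ids.
    """
    counts = X.values.astype(np.float64)
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 cells to normalize")
    totals = counts.sum(axis=1)
    zero = totals == 0
    if np.any(zero):
        bad = [X.cell_ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(
            f"cells with all-zero counts in modality {X.modality_name!r}: {bad}"
        )
    target = float(np.median(totals))
    scaled = counts * (target / totals)[:, None]
    return ModalityView(
        values=np.log1p(scaled),
        modality_name=X.modality_name,
        cell_ids=list(X.cell_ids),
        transform_log=[f"median_library_scale(target={target:g})", "log1p"],
    )


def pca_project(V: ModalityView, n_components: int = 20) -> ModalityView:
    """Project a view onto its leading principal components.

    Columns are PC scores of the centered input, ordered by decreasing
    explained variance.  ``n_components`` must not exceed
    ``min(n_cells - 1, n_features)``.
    """
    n, p = V.values.shape
    bound = min(n - 1, p)
    if not 1 <= n_components <= bound:
        raise ValueError(
            f"n_components={n_components} out of range; must be in [1, {bound}] "
            f"(min(n_cells - 1, n_features) for a {n} x {p} view)"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(V.values)
    return ModalityView(
        values=scores,
        modality_name=V.modality_name,
        cell_ids=V.cell_ids,
        transform_log=V.transform_log + [f"pca(n_components={n_components})"],
    )


def frobenius_concat(X_list: list[CountMatrix], normalize: bool = True) -> ModalityView:
    """Feature-wise concatenation of count matrices, the baseline input for
    conventional t-SNE/UMAP on multimodal data.

    With ``normalize`` each block is divided by its own Frobenius norm so no
    single modality dominates by scale; without it raw values are stacked.
    """
    if not X_list:
        raise ValueError("need at least one count matrix")
    n = X_list[0].n_cells
    for X in X_list[1:]:
        if X.n_cells != n:
            raise ValueError(
                f"cell count mismatch: {X.modality_name!r} has {X.n_cells} cells, "
                f"{X_list[0].modality_name!r} has {n}"
            )
    blocks = []
    steps = []
    for X in X_list:
        vals = X.values.astype(np.float64)
        if normalize:
            norm = float(np.linalg.norm(vals))
            if norm == 0:
                raise ValueError(f"modality {X.modality_name!r} is all zeros")
            vals = vals / norm
            steps.append(f"{X.modality_name}/frobenius({norm:g})")
        else:
            steps.append(X.modality_name)
        blocks.append(vals)
    return ModalityView(
        values=np.concatenate(blocks, axis=1),
        modality_name="concat",
        cell_ids=list(X_list[0].cell_ids),
        transform_log=[("normalized_concat: " if normalize else "concat: ") + "+".join(steps)],
    )


def prepare_views(
    modalities: list[CountMatrix],
    n_components: int = 20,
    skip_pca_if_small: bool = True,
) -> list[ModalityView]:
    """Standard preprocessing pipeline: log-normalize each modality, then
    PCA to ``n_components``.

    Small feature panels (e.g. 10-50 antibody ADT modalities) are kept at
    full dimension when ``skip_pca_if_small`` and the feature count is at
    most ``n_components`` — reducing a 13-antibody panel to 20 PCs is
    ill-posed.
    """
    views = []
    for X in modalities:
        v = log_normalize(X)
        if X.n_features > n_components or not skip_pca_if_small:
            ncomp = min(n_components, min(X.n_cells - 1, X.n_features))
            v = pca_project(v, ncomp)
        views.append(v)
    return views


__all__ = ["log_normalize", "pca_project", "frobenius_concat", "prepare_views"]
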