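"""Synthetic multimodal single-cell data with CITE-seq-like structure.

The generator follows the hierarchical gamma-Poisson scheme popularized by
Splatter for grouped scRNA-seq counts and applies the same machinery with a
separate parameter block to ADT (surface protein) counts — ADT panels are
small, less sparse, and more dispersed than RNA, and their features are
curated markers so a larger fraction is differentially expressed between
cell types.  A third "noise" modality is produced by duplicating a modality
and randomly permuting expression vectors within a random subset of cells,
which destroys the cell-to-measurement link for those cells while preserving
every marginal feature distribution.

Generative model per modality (all draws from one seeded generator):

1. baseline feature means  mu_f ~ Gamma(mean_shape, 1/mean_rate);
   with probability outlier_prob a feature becomes an expression outlier,
   its mean replaced by median(mu) * outlier_scale * LogNormal(0, 0.5);
2. per group g and feature f, a DE factor 2^N(0, de_logfc_scale) applied
   with probability de_prob (otherwise 1);
3. per cell c, library size L_c ~ LogNormal(libsize_mu, libsize_sigma);
   the expected count lambda_cf = L_c * group-normalized mean share;
4. counts ~ Poisson(Gamma(1/dispersion, lambda * dispersion)) — i.e.
   negative binomial with Var = mu + dispersion * mu^2;
5. optional logistic dropout: a count is zeroed with probability
   expit(dropout_shape * (dropout_mid - log1p(lambda))) (disabled when
   dropout_shape <= 0).

The default parameter values are documented stand-ins chosen to yield
sparse, overdispersed counts at desk scale; they are not estimates from any
real data set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

from .datatypes import CountMatrix, ModalityView


@dataclass
class ModalityParams:
    """Negative-binomial generator block for one modality."""

    n_features: int = 500
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    libsize_mu: float = 9.5          # natural-log scale
    libsize_sigma: float = 0.35
    dispersion: float = 0.2
    dropout_mid: float = 1.0         # on log1p(expected count)
    dropout_shape: float = 1.0       # <= 0 disables dropout
    outlier_prob: float = 0.05
    outlier_scale: float = 4.0
    de_prob: float = 0.1
    de_logfc_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mean_shape", "mean_rate", "de_logfc_scale", "outlier_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.de_prob <= 1 or not 0 <= self.outlier_prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")


def default_adt_params() -> ModalityParams:
    """ADT defaults: small curated marker panel, shallower but denser
    libraries, higher dispersion, weak dropout, most features DE."""
    return ModalityParams(
        n_features=30,
        mean_shape=1.5,
        mean_rate=0.5,
        libsize_mu=7.0,
        libsize_sigma=0.3,
        dispersion=0.4,
        dropout_mid=0.5,
        dropout_shape=0.5,
        outlier_prob=0.05,
        outlier_scale=3.0,
        de_prob=0.5,
        de_logfc_scale=2.0,
    )


@dataclass
class SimConfig:
    """Configuration of a joint RNA + ADT simulation."""

    n_cells: int = 500
    n_groups: int = 5
    group_probs: Sequence[float] | None = None
    rna: ModalityParams = field(default_factory=ModalityParams)
    adt: ModalityParams = field(default_factory=default_adt_params)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_probs is None:
            self.group_probs = tuple([1.0 / self.n_groups] * self.n_groups)
        probs = np.asarray(self.group_probs, dtype=np.float64)
        if probs.size != self.n_groups or np.any(probs < 0) or abs(probs.sum() - 1) > 1e-8:
            raise ValueError("group_probs must be a simplex vector of length n_groups")
        self.group_probs = tuple(float(p) for p in probs)

    @property
    def n_genes(self) -> int:
        return self.rna.n_features

    @property
    def n_adt(self) -> int:
        return self.adt.n_features


@dataclass
class SimResult:
    """A simulated multimodal data set with ground-truth group labels."""

    modalities: dict[str, CountMatrix | ModalityView]
    labels: np.ndarray
    params_used: SimConfig | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        for name, m in self.modalities.items():
            if m.n_cells != self.labels.size:
                raise ValueError(f"modality {name!r} does not match label length")


def _simulate_counts(
    rng: np.random.Generator,
    groups: np.ndarray,
    n_groups: int,
    p: ModalityParams,
    prefix: str,
    name: str,
) -> CountMatrix:
    n = groups.size
    mu = rng.gamma(p.mean_shape, 1.0 / p.mean_rate, size=p.n_features)
    out_mask = rng.random(p.n_features) < p.outlier_prob
    n_out = int(out_mask.sum())
    if n_out:
        mu[out_mask] = (
            np.median(mu) * p.outlier_scale * rng.lognormal(0.0, 0.5, size=n_out)
        )
    de_mask = rng.random((n_groups, p.n_features)) < p.de_prob
    logfc = rng.normal(0.0, p.de_logfc_scale, size=(n_groups, p.n_features))
    factors = np.where(de_mask, 2.0**logfc, 1.0)
    group_means = mu[None, :] * factors                      # (G, F)
    shares = group_means / group_means.sum(axis=1, keepdims=True)
    lib = rng.lognormal(p.libsize_mu, p.libsize_sigma, size=n)
    lam = lib[:, None] * shares[groups]                      # (n, F)
    if p.dispersion > 0:
        shape = 1.0 / p.dispersion
        lam_cell = rng.gamma(shape, lam * p.dispersion)
    else:
        lam_cell = lam
    counts = rng.poisson(lam_cell)
    if p.dropout_shape > 0:
        p_drop = expit(p.dropout_shape * (p.dropout_mid - np.log1p(lam)))
        counts = np.where(rng.random(counts.shape) < p_drop, 0, counts)
    return CountMatrix(
        values=counts.astype(np.int64),
        cell_ids=[f"cell{c}" for c in range(n)],
        feature_ids=[f"{prefix}{f}" for f in range(p.n_features)],
        modality_name=name,
    )


def simulate_multimodal(config: SimConfig | None = None) -> SimResult:
    """Draw joint RNA + ADT count matrices with shared group labels."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    groups = rng.choice(config.n_groups, size=config.n_cells, p=config.group_probs)
    rna = _simulate_counts(rng, groups, config.n_groups, config.rna, "gene", "RNA")
    adt = _simulate_counts(rng, groups, config.n_groups, config.adt, "adt", "ADT")
    labels = np.array([f"group{g}" for g in groups])
    return SimResult(
        modalities={"RNA": rna, "ADT": adt}, labels=labels, params_used=config
    )


def make_shuffled_modality(
    X: CountMatrix, fraction: float, seed: int = 0
) -> CountMatrix:
    """Noise modality: duplicate X and permute expression vectors within a
    random floor(fraction * n)-cell subset (rows stay a permutation of the
    originals; cells outside the subset are untouched)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    values = X.values.copy()
    m = int(np.floor(fraction * X.n_cells))
    if m >= 2:
        subset = rng.choice(X.n_cells, size=m, replace=False)
        perm = rng.permutation(m)
        values[subset] = values[subset[perm]]
    return CountMatrix(
        values=values,
        cell_ids=list(X.cell_ids),
        feature_ids=list(X.feature_ids),
        modality_name=f"{X.modality_name}_shuffled",
    )


def toy_two_view_scenario(n_cells: int = 200, seed: int = 0) -> SimResult:
    """Four true cell types, two modalities that each confound one pair.

    Modality A places groups 1 and 2 on a shared center (indistinguishable,
    e.g. identical surface-protein profiles) while groups 3 and 4 are well
    separated; modality B confounds groups 3 and 4 instead.  Only a joint
    embedding can resolve all four groups.  Views are returned directly
    (already real-valued); preprocessing is not needed.
    """
    if n_cells < 40 or n_cells % 4 != 0:
        raise ValueError("n_cells must be >= 40 and divisible by 4")
    rng = np.random.default_rng(seed)
    dim, sep = 10, 10.0
    per = n_cells // 4
    labels = np.repeat([f"type{i}" for i in range(1, 5)], per)
    centers_a = np.zeros((4, dim))
    centers_a[2, 0] = sep
    centers_a[3, 0] = -sep
    centers_b = np.zeros((4, dim))
    centers_b[0, 1] = sep
    centers_b[1, 1] = -sep
    g = np.repeat(np.arange(4), per)
    A = centers_a[g] + rng.normal(size=(n_cells, dim))
    B = centers_b[g] + rng.normal(size=(n_cells, dim))
    cell_ids = [f"cell{i}" for i in range(n_cells)]
    return SimResult(
        modalities={
            "modality_A": ModalityView(A, "modality_A", cell_ids, ["toy blobs"]),
            "modality_B": ModalityView(B, "modality_B", cell_ids, ["toy blobs"]),
        },
        labels=labels,
    )


def three_modality_dataset(
    n_cells: int = 500,
    shuffle_fraction: float = 0.4,
    seed: int = 0,
    config: SimConfig | None = None,
) -> SimResult:
    """RNA + ADT + shuffled-RNA noise modality — the weight-learning setup."""
    config = replace(config or SimConfig(), n_cells=n_cells, seed=seed)
    sim = simulate_multimodal(config)
    noisy = make_shuffled_modality(sim.modalities["RNA"], shuffle_fraction, seed=seed + 1)
    sim.modalities["RNA_shuffled"] = noisy
    return sim


def scaling_suite(
    n_cells_list: Sequence[int],
    n_modalities: int = 2,
    seed: int = 0,
    config: SimConfig | None = None,
) -> list[SimResult]:
    """Runtime-scaling inputs: RNA + ADT, optionally plus shuffled copies of
    both at fraction 0.4 (the 4-modality setup)."""
    if n_modalities not in (2, 4):
        raise ValueError("n_modalities must be 2 or 4")
    out = []
    for n in n_cells_list:
        cfg = replace(config or SimConfig(), n_cells=int(n), seed=seed)
        sim = simulate_multimodal(cfg)
        if n_modalities == 4:
            sim.modalities["RNA_shuffled"] = make_shuffled_modality(
                sim.modalities["RNA"], 0.4, seed=seed + 1
            )
            sim.modalities["ADT_shuffled"] = make_shuffled_modality(
                sim.modalities["ADT"], 0.4, seed=seed + 2
            )
        out.append(sim)
    return out


#: Named desk-scale presets patterned on "1k / 5k cells, reduced gene count"
#: style variations; the sizes are this package's own choices.
PRESETS: dict[str, SimConfig] = {
    "N1k": SimConfig(n_cells=1000),
    "N5k": SimConfig(n_cells=5000),
    "N1kD300": SimConfig(n_cells=1000, rna=ModalityParams(n_features=300)),
    "N5kD300": SimConfig(n_cells=5000, rna=ModalityParams(n_features=300)),
    "N1kUneven": SimConfig(
        n_cells=1000, group_probs=(0.4, 0.3, 0.15, 0.1, 0.05)
    ),
}


__all__ = [
    "ModalityParams",
    "default_adt_params",
    "SimConfig",
    "SimResult",
    "simulate_multimodal",
    "make_shuffled_modality",
    "toy_two_view_scenario",
    "three_modality_dataset",
    "scaling_suite",
    "PRESETS",
]
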