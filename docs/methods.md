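# Methods

## Model

Given K modalities measured in the same n cells, each preprocessed into a
real-valued view, `jembed` learns a shared low-dimensional embedding Y and
simplex-constrained modality weights α by minimizing

    C(Y, α) = Σₖ αₖ Lₖ(Y) + λ Σₖ αₖ log αₖ,     αₖ ≥ 0, Σₖ αₖ = 1,

with the convention 0·log 0 = 0. For the SNE branch Lₖ = KL(P⁽ᵏ⁾‖Q), where
P⁽ᵏ⁾ is the perplexity-calibrated, symmetrized Gaussian joint distribution of
modality k (perplexity default 30; symmetrization p_ij = (p_{j|i}+p_{i|j})/2n)
and Q the Student-t distribution of the embedding. For the UMAP branch Lₖ is
a fuzzy cross entropy between modality k's k-NN membership graph V⁽ᵏ⁾
(n_neighbors default 15; bandwidths solved so the smoothed neighbor count is
log2(n_neighbors); probabilistic t-conorm symmetrization) and the embedded
kernel w = (1 + a d^{2b})⁻¹ with (a, b) fitted from min_dist = 0.1,
spread = 1.0.

The entropy regularizer makes the weight subproblem strictly convex with the
closed form αₖ ∝ exp(−Lₖ/λ); λ = 0 is handled as the analytic one-hot limit
at the smallest loss (first index on ties). λ controls how aggressively
uninformative modalities are suppressed: defaults λ = 3 (j-SNE) and
λ = 1 (j-UMAP).

## Alternating optimization

Weights start uniform. Each outer iteration (at most `max_outer_iter = 10`):

1. **Embedding step.** j-SNE: exact O(n²) t-SNE gradient descent on
   P̄ = Σₖ αₖ P⁽ᵏ⁾ — momentum 0.5→0.8, adaptive per-coordinate gains,
   learning rate 200; the first outer iteration runs `inner_iters_first = 500`
   steps with 12× early exaggeration on its first half, later iterations
   warm-start from the current Y for `inner_iters_later = 100` plain steps.
   j-UMAP: edge-sampling stochastic gradient descent on V̄ = Σₖ αₖ V⁽ᵏ⁾
   (epochs per edge proportional to combined strength; negative sample rate
   5), 200 epochs on the first outer iteration and 50 thereafter.
2. **Weight step.** Evaluate each modality's divergence at the current Y and
   set α to the closed-form minimizer. The update is exact, so the total
   objective C is non-increasing across every weight step by construction.

The loop stops early when max|Δα| < `alpha_tol = 1e-3`. Initialization:
j-SNE from a seeded Gaussian (σ = 1e-4; PCA initialization available);
j-UMAP from the spectral layout of V̄ (seeded Gaussian fallback when the
graph is disconnected).

Two j-UMAP-specific choices stabilize the alternation against SGD noise:

* the SGD initial learning rate is annealed geometrically (0.5^t at outer
  iteration t) — alternating minimization with a stochastic inner solver
  needs diminishing inner stochasticity for the weight trajectory to settle
  within the iteration budget;
* the non-edge sample used by the loss estimator (below) is drawn once per
  run and reused across modalities and outer iterations, so that neither
  per-modality loss differences nor their changes over the alternation are
  sampling noise.

## Cross-entropy evaluation for the weight step

Conventional UMAP never evaluates its loss, so the weight step needs an
explicit estimator. `cross_entropy_term` computes, for one graph,
−Σ_{i<j} [v log w + (1−v) log(1−w)] exactly over stored edges plus a
seeded uniform non-edge sample (50 per edge by default) scaled to the number
of non-edge pairs; w is clipped to [1e-12, 1−1e-12]. A single edge with
w = v contributes the binary entropy of v, the minimum over w.

For the weight update the per-graph sums are unsuitable: they grow with data
size (so one λ could not transfer across data sets and the softmax saturates
to one-hot on any sizeable input) and they are dominated by a
modality-independent geometric background from non-edge pairs, which swamps
the part that distinguishes informative from noisy modalities. `run_jumap`
therefore scores every modality on the *union* of all modalities' edge sets
(v_k = 0 where modality k lacks an edge) plus the shared background sample,
normalized per union edge. Background pairs carry v = 0 for every modality,
so they shift all losses equally and cancel in the softmax; modality
differences come entirely from pairs on which the fuzzy graphs disagree.
Consistent with the smaller CE differences this produces, j-UMAP's weight
adjustments are systematically smaller in magnitude than j-SNE's.

## Preprocessing

Counts are scaled per cell to the median total count, log1p-transformed, and
reduced to 20 (default) or 50 principal components; every step is recorded
in the view's `transform_log`. Small feature panels (ADT antibody panels
with fewer features than the requested component count) skip PCA — reducing
a 13-antibody panel to 20 components is ill-posed. No highly-variable-gene
selection, clipping or batch correction is performed. Cells are aligned
across modalities by id against the first modality's order.

The concatenation baseline stacks count matrices feature-wise, optionally
dividing each block by its Frobenius norm so no modality dominates by scale,
then applies PCA and a conventional (single-view) embedding.

## Synthetic data

`simulate_multimodal` draws grouped RNA and ADT counts from a hierarchical
gamma–Poisson model in the style of Splatter: feature means ~ Gamma
(shape 0.6, rate 0.3 for RNA), expression outliers with probability 0.05,
per-group differential-expression factors 2^N(0, σ_DE) applied to a fraction
of features, cell library sizes ~ LogNormal, negative-binomial counts via a
gamma–Poisson mixture (Var = μ + φμ²), and logistic dropout on the expected
count. ADT uses a separate parameter block: a small curated panel (30
features), shallower but denser libraries (log-libsize 7.0 vs 9.5), higher
dispersion (0.4 vs 0.2), weak dropout, and strong group structure
(de_prob 0.5, σ_DE = 2) — surface-marker panels are selected to discriminate
cell types, with bimodal 4–10× differences between positive and negative
populations. All default values are stand-ins chosen once to produce sparse,
overdispersed, realistically informative counts at desk scale; they are not
estimates from any real data set.

The noise modality duplicates a count matrix and permutes expression vectors
among a uniformly chosen ⌊fraction·n⌋-cell subset (rows are permuted within
the subset only, so the row multiset is preserved). The toy scenario draws
four equal cell types in two 10-dimensional Gaussian views with unit noise
and separation 10, arranged so each view collapses one pair of types onto a
shared center — each modality alone can resolve only three clusters.

What the generator does *not* emulate: batch effects, mean–variance trends
(BCV), differentiation paths, ambient contamination, and the empirical
parameter values of real CITE-seq panels. Passing tests therefore
demonstrate the optimization behaves as designed under controlled
conditions, not performance on any particular real data set.

## Numerical choices

* Perplexity calibration: per-row binary search on the precision to 1e-6
  bits, error after 100 steps. Equidistant rows admit the maximal-entropy
  target (perplexity = n−1) exactly.
* Probabilities are floored at 1e-12 inside logarithms; KL uses 0·log 0 = 0
  and raises if Q vanishes where P has mass.
* KNI breaks distance ties at the k-th neighbor toward the lower cell index;
  Silhouette uses Euclidean distance in the embedding; both metrics take the
  embedding as-is (they are invariant to rigid motions).
* Exact brute-force k-NN is used up to 5,000 cells, tree-based search above.
* Determinism: every stochastic component (initialization, SGD, negative
  sampling, simulators) is driven by the run seed; identical configuration
  and seed reproduce results bit-identically, and each CLI run writes a
  manifest (config, seed, input checksums, loss/weight trace) sufficient to
  re-run it.

## Problem sizes

Tests and the acceptance script run the method end to end at desk scale,
chosen as this package's own study conditions: the toy scenario at n = 200
(5 seeds in the test suite, 3 in the acceptance script), the three-modality
noise study at n = 500 with shuffle fractions {0, 0.2, 0.4, 0.8, 1.0}
(3 seeds; 2 seeds and fractions {0.4, 0.8} in the acceptance script), and
oracle checks on 10–100-point instances. Larger runs change none of the
qualitative conclusions but are not exercised routinely.

## Known limitations

* The j-SNE embedding step is the exact O(n²) reference path; no Barnes-Hut
  or interpolation acceleration is included, so runs beyond ~5,000 cells are
  slow.
* The CE-per-union-edge loss for the j-UMAP weight step is this package's
  documented estimator; other choices (exact all-pairs CE, per-graph sums)
  change the weight scale and hence the effective meaning of λ.
* Silhouette comparisons on data where modalities fully confound cluster
  pairs can favor embeddings that merge those clusters (merged cells score
  ≈ 0, never negative); KNI does not share this artifact and is the primary
  comparison metric here.
* Embeddings are 2-D by default; higher `n_components_embed` is supported
  for j-SNE/j-UMAP but spectral initialization quality degrades on
  disconnected graphs (Gaussian fallback).
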