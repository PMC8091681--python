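# jembed — joint t-SNE / UMAP embeddings of multimodal single-cell omics

Emerging single-cell technologies (CITE-seq, REAP-seq, SNARE-seq, ...) measure
several molecular layers — mRNA, surface proteins (ADT), chromatin
accessibility — in the *same* cells. t-SNE and UMAP are usually applied to one
modality at a time, and the resulting maps must be reconciled by eye: cell
types indistinguishable in one modality may be cleanly separated in another.

`jembed` implements **j-SNE** and **j-UMAP**, generalizations of t-SNE and
UMAP that embed all modalities into a single two-dimensional map while
*learning how informative each modality is*. For modalities k = 1..K with
high-dimensional similarity structures P⁽ᵏ⁾, the j-SNE objective over the
embedding 𝓔 and simplex weights α is

    C(𝓔) = Σₖ αₖ · KL(P⁽ᵏ⁾ ‖ Q)  +  λ Σₖ αₖ log αₖ ,

where Q is the Student-t similarity distribution of the embedding and λ ≥ 0
penalizes non-uniform weights. j-UMAP is the analog with per-modality fuzzy
k-NN graphs V⁽ᵏ⁾ and cross-entropy losses in place of KL divergences. The
objective is minimized by alternating optimization:

* **embedding step** — with α fixed, all divergence terms share one Q, so the
  subproblem is exactly t-SNE on the convex combination P̄ = Σₖ αₖ P⁽ᵏ⁾
  (respectively UMAP stochastic gradient descent on V̄ = Σₖ αₖ V⁽ᵏ⁾);
* **weight step** — with the embedding fixed, the entropy-regularized weight
  subproblem has the closed-form solution αₖ ∝ exp(−Lₖ/λ), where Lₖ is
  modality k's divergence. λ → ∞ gives uniform weights; λ = 0 selects the
  single most informative modality.

Noisy or redundant modalities receive small weights automatically; defaults
are λ = 3 for j-SNE and λ = 1 for j-UMAP, with at most 10 outer iterations.

The package also ships the evaluation metrics used to quantify embeddings
(**KNI** — the fraction of each cell's k nearest embedded neighbors sharing
its cell type, plus mean Silhouette and ARI), conventional-embedding
baselines (single modality, Frobenius-normalized or raw concatenation, frozen
uniform weights), and a Splatter-style gamma–Poisson simulator of grouped
RNA + ADT counts with a "shuffled" noise modality for controlled experiments.

## Worked example

Simulate 300 cells with five cell types measured as RNA counts, ADT counts,
and a noise modality (RNA duplicated, expression vectors permuted among 80%
of cells), then embed jointly with j-SNE and evaluate:

```bash
jembed simulate --preset cite3 --n 300 --seed 0 --shuffle-fraction 0.8 --out sim/
jembed embed --method jsne \
    --modality sim/RNA.csv --modality sim/ADT.csv --modality sim/RNA_shuffled.csv \
    --seed 0 --out run/
jembed metrics --embedding run/embedding.csv --labels sim/labels.csv
```

The embed step logs one line per outer iteration (per-modality KL losses and
the updated weights):

```
outer 0: losses=1.6337,1.6535,2.5503 alpha=0.3663,0.3639,0.2699
outer 1: losses=1.2262,1.1116,2.3613 alpha=0.3671,0.3814,0.2515
outer 2: losses=1.2237,1.0846,2.4028 alpha=0.3673,0.3847,0.2479
outer 3: losses=1.2237,1.0797,2.4103 alpha=0.3673,0.3854,0.2473
```

The shuffled modality's KL divergence stays high (≈2.4 vs ≈1.1–1.2), so its
weight is pushed below uniform (0.247 vs 1/3) while RNA and ADT share the
remainder — the optimizer has identified the noise channel from the data
alone. The metrics step prints

```json
{
  "k": 10,
  "kni": 0.9867,
  "silhouette": 0.5897,
  "kni_per_class": {"group0": 0.981, "group1": 0.984, "group2": 0.994,
                    "group3": 0.977, "group4": 0.994}
}
```

i.e. 98.7% of every cell's 10 nearest embedded neighbors are of its own cell
type, despite one of the three input modalities being mostly noise. All
outputs come with a `manifest.json` (config, seed, input checksums, loss and
weight trace) from which the run can be reproduced bit-identically.

The same workflow is available from Python:

```python
from jembed import three_modality_dataset, embed_counts, default_config, kni

sim = three_modality_dataset(n_cells=300, shuffle_fraction=0.8, seed=0)
result = embed_counts(list(sim.modalities.values()), method="jsne",
                      config=default_config("jsne", seed=0))
print(dict(zip(result.modality_names, result.weights.round(3))))
print(kni(result.embedding, sim.labels))
```

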