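# ddikit

Multimodal graph-attention modelling of drug–drug interactions (DDIs).

## The problem

Predicting whether two drugs interact is a binary classification task over
drug pairs, but the evidence is scattered across heterogeneous sources:
chemical substructure fingerprints, adverse-effect profiles, expression
signatures, therapeutic-class annotations, and co-prescription statistics.
`ddikit` is a library for researchers who want to fuse such per-drug
feature *modalities* into a relational drug graph, learn drug embeddings
over it with attention, and score drug pairs — with every loss term and
attention map open to inspection.

## The model

For drugs with features `X = [x_1ᵀ, …, x_Nᵀ]ᵀ` split into M modality
blocks:

1. **Similarity fusion.** Each block yields a kernel similarity matrix
   `S⁽ᵐ⁾` (cosine, Gaussian with median-distance bandwidth, or Jaccard);
   the fused similarity is the convex combination
   `S = Σₘ λₘ S⁽ᵐ⁾` with trainable simplex weights `λ = softmax(logits)`.
2. **Relational graph.** Edges are `S_ij > ε` (strict threshold) or
   k-nearest-neighbour selection, union-symmetrized.
3. **Attention propagation.** K layers of
   `h_i ← σ(Σ_j α_ij W h_j)` with
   `α_ij = softmax_j LeakyReLU(aᵀ[W h_i ‖ W h_j])`, residual connections
   to the projected input, row normalization `h_i / (‖h_i‖₂ + ε)`, and a
   multi-hop combination `Z = Σₖ γₖ H⁽ᵏ⁾`.
4. **Pair head.** Per-modality embeddings of the two drugs are aligned by
   top-k–masked, scaled dot-product cross-attention; the symmetrized
   logistic MLP over `[z_i ‖ z_j ‖ z_i⊙z_j ‖ pooled]` outputs the
   interaction probability.
5. **Joint objective.** A triplet contrastive loss, a similarity-
   preservation loss `Σ (S_ij − cos(z_i, z_j))²`, supervised
   cross-entropy on drug classes, plus knowledge-alignment regularizers:
   context co-membership alignment `Σ_p ω_p·2tr(ZᵀL_pZ)`, Laplacian
   smoothness `tr(ZᵀL_GZ)` on the unified topology
   `G = ΣₘS⁽ᵐ⁾ + Σ_pR_p`, a KL calibration of `σ(z_iᵀz_j)` against
   row-normalized co-prescription probabilities (confidence-weighted by
   `min(1, ln(1+O_ij))`), Gaussian-kernel MMD across per-modality
   embedding distributions, a margin ranking loss, and an entropy
   confidence regularizer.

Training is pure NumPy on a small built-in reverse-mode autodiff tape
(`ddikit.autodiff`), with Adam, cosine annealing, stratified 80/10/10
pair splits and early stopping.

Because the four public benchmark corpora this line of work evaluates on
are not redistributable, the package ships a synthetic cohort generator
(`ddikit.synthetic`) that plants a controllable version of the same
structure: clustered drugs, exactly one informative modality, contexts
correlated with clusters, Poisson co-prescriptions elevated within
clusters, and flip-noise pair labels.

## Worked example

```python
import numpy as np
from ddikit import generate_cohort, train, TrainConfig

cohort = generate_cohort(n_drugs=100, n_modalities=4, n_clusters=4,
                         noise_sd=1.0, flip_prob=0.05, seed=1)
result = train(cohort, TrainConfig.small_synthetic(seed=1, max_epochs=30,
                                                   early_stop_patience=10))
print(result.metrics.as_dict())
print(np.round(result.fusion_weights, 3))
```

prints

```
{'accuracy': 0.883..., 'recall': 0.933..., 'f1': 0.889...,
 'roc_auc': 0.920..., 'pr_auc': 0.919..., 'n_pairs': 240}
[0.269 0.244 0.244 0.244]
```

The held-out ROC-AUC of 0.92 says the pair head ranks interacting above
non-interacting pairs far better than chance despite 5 % label noise, and
the fusion weights concentrate on modality 0 — the model identified the
planted informative modality without being told which one it is.  The
`examples/` directory has one narrative script per capability (cohort
generation, graph building, training, ablations, attention maps,
molecular encoding).

## Command line

```bash
ddikit simulate --n-drugs 200 --seed 1 --out-dir cohort/
ddikit build-graph --cohort-dir cohort/ --knn-k 10 --out graph/
ddikit train --cohort-dir cohort/ --preset small --out run/
ddikit evaluate --predictions run/test_predictions.tsv
ddikit predict --model run/model.npz --cohort-dir cohort/ \
       --pairs cohort/pairs.tsv --attention --out pred/
```

Every command writes a `manifest.json` (config, input digests, seed) so
runs can be reproduced exactly.

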