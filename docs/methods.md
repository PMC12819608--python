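# Methods

This note documents the model, its defaults, the synthetic study
conditions, numerical choices, and known limitations.  Notation follows
the README: N drugs, M feature modalities, embeddings `Z ∈ R^{N×d}`.

## Model and assumptions

DDIs are treated as an *undirected* binary relation: pair files store
unordered pairs, the scoring head is symmetrized exactly
(`score(i,j) = (s_ij + s_ji)/2`), and all graph structures are symmetric.
The model assumes that interaction propensity correlates with multimodal
similarity — drugs similar under at least one informative modality are
more likely to interact — and that knowledge structures (shared
therapeutic contexts, co-prescription frequencies) carry complementary
signal worth aligning the embedding geometry to.

The encoder input is the concatenated feature matrix projected linearly
to the hidden dimension; that projected state is also the residual base
of every attention layer (the raw feature dimension generally differs
from the hidden dimension, so a residual on raw features would be
dimensionally inconsistent).  Isolated graph nodes receive a self-loop so
the neighbourhood softmax is always defined.  Multi-head attention
averages heads.  Layer states are row-normalized (`h/(‖h‖+ε)`,
ε = 1e-8), and the final multi-hop combination is normalized the same
way, so embeddings live near the unit sphere and inner products act as
cosines.

**Per-modality embeddings.** The distribution-alignment (MMD) term and
the pair head's cross-attention tokens need one embedding per modality.
These are produced by re-encoding the feature matrix with all other
modality blocks zeroed, through the *shared* encoder.  This is one
defensible reading of "embedding subsets derived from each modality";
alternatives (separate encoders, column-sliced projections) exist, and no
claim is made that this choice is unique.

**Pair head tokens.** When molecular atom graphs are not supplied, the M
per-modality embeddings of a drug serve as its substructure token set for
cross-attention.  With `top_k` (default 8) at least M, the pre-masking is
inactive at the default M = 4; it engages for atom-level states, where a
drug can have tens of tokens.  The ablation that disables multimodal
fusion also replaces this head by plain mean-concatenation, which is what
makes it a genuine ablation of the alignment machinery.

**Molecular encoder.** Atom graphs (random toys, or RDKit-parsed SMILES)
are encoded by three attention layers whose messages concatenate bond
embeddings, followed by global attention pooling.  It is exposed as a
feature extractor — its output can be concatenated to the tabular
features — but it is not trained jointly by default; how precomputed
multimodal features and structure-derived embeddings should combine is
genuinely open, and the package does not pretend to settle it.

## Objective

The optimized loss is

    L = L_ctr + λ₁·L_sim + λ₂·L_sup                (embedding objective)
      + α₁L_ctx + α₂L_lap + α₃L_co + α₄L_mmd + α₅L_rank + α₆L_ent
      + w_pair·BCE(pair scores)

`ddikit.losses` implements every term as its printed double-sum / trace
formula (these exact values are what the unit tests pin down); the
training wrapper divides each term by its term count so that the default
weights — λ₁ = λ₂ = 1, α₁..α₆ = 0.1, w_pair = 1 — keep the terms on
comparable scales regardless of N and batch size.  The weights are
configuration, not claims: they were chosen so no term dominates on the
synthetic cohort and are recorded in `TrainConfig`.

Notable term-level choices:

* **Contrastive triplet** (`ln(1+e^{z·z⁻}) − ln σ(z·z⁺)`): both terms are
  the same softplus function algebraically; inner products are clamped to
  ±30 before exponentials.  Positives are labelled interacting pairs;
  negatives are uniform non-interacting partners, re-mined every epoch.
* **Similarity preservation** exists in two printed forms; the cosine
  reconstruction form `Σ(S_ij − cos z_i z_j)²` is the default (mode flag
  `sqdist` gives the graph-weighted squared-distance form).  This is the
  term through which the fusion weights λ receive gradient, since the
  graph edges themselves are discrete.
* **Context alignment**: the ordered double sum equals **2**·tr(ZᵀLZ),
  not tr(ZᵀLZ); the factor-2 reconciliation is applied and verified by a
  dedicated identity test.
* **Co-prescription calibration** compares a row-normalized probability
  table against sigmoid inner products, which are not a normalized
  distribution — the sum is therefore *not* guaranteed non-negative.  The
  tests assert finiteness and the zero-at-match property only, and the
  natural logarithm is used throughout.  Pairs with zero probability
  contribute exactly 0; sigmoids are clamped to [1e-12, 1−1e-12].
* **MMD** uses the biased estimator (diagonal terms kept), which is
  non-negative and exactly zero for identical samples; the Gaussian
  bandwidth defaults to the median pairwise distance of the pooled
  samples.
* **Entropy regularizer** uses the convention 0·ln 0 = 0 via probability
  clamping at 1e-12.

The two printed objectives (embedding and alignment) are minimized
*jointly* in a single step; no alternation schedule is used because none
is specified anywhere, and joint optimisation keeps every gradient path
(including λ's) active throughout.

## Training protocol

Adam (lr 1e-3, weight decay 1e-5), cosine annealing to zero, dropout 0.1
on attention weights, mini-batch 128, at most 150 epochs with early
stopping on the validation pair loss (patience 15) and best-epoch
parameter restoration.  Pair splits are 80/10/10, label-stratified, with
an optional drug-wise (cold-start) mode that holds out whole drugs.
Fusion weights are optimized as unconstrained logits under a softmax, so
the simplex constraint holds at every step; the relational graph is
rebuilt from the current fused similarity every `graph_refresh` epochs
(default 1).

**Compact preset.** `TrainConfig.small_synthetic()` is the configuration
used for the package's own end-to-end experiments on ~200-drug synthetic
cohorts: hidden dim 32, 2 heads, 2 layers, lr 3e-3, 60 epochs, one
full-batch-style step per epoch on a 2 048-pair subsample (with up to
2 000 mined triplets).  These are problem sizes matched to the synthetic
cohorts, chosen so the whole experiment grid (full model, three
ablations, robustness fractions, five seeds each) runs in minutes on one
CPU; the `TrainConfig` defaults above remain the reference protocol.

**Supervision labels.** The per-drug classification head uses each drug's
first context annotation (its therapeutic-class stand-in) as the class
label — observed data, not the latent cluster assignment, although in the
synthetic cohort the two coincide by construction.

## Synthetic study conditions

`generate_cohort` defaults (chosen once; `DEFAULT_COHORT_PARAMS` is the
condition used in the acceptance experiments): 200 drugs, 4 modalities of
32 features each, 4 balanced clusters, informative-modality noise sd 1.0
against unit-variance centroids, label flip probability 0.05,
within/between co-prescription Poisson rates 5.0/1.0, one random extra
context per drug from a pool of 3.

What the generator emulates: multimodal blocks with exactly one
cluster-separable modality, knowledge structures correlated with the
latent clusters, and noisy pair labels with balanced classes (negatives
subsampled 1:1 — real corpora rarely publish their class ratio).  What it
does **not** emulate: real marginal distributions of fingerprints,
adverse-event or expression data, heavy-tailed degree distributions,
modality-specific missingness, or any real pharmacology.  Passing the
end-to-end tests therefore demonstrates that the machinery recovers
planted structure under controlled noise — not clinical performance.
With 5 % symmetric label flips the achievable ROC-AUC is itself capped
(≈ 0.95 for a perfect cluster oracle), which is why observed AUCs
around 0.95 should be read as near-ceiling.

## Numerical choices

* Strict inequality in the edge threshold; the diagonal is excluded from
  adjacency even though the raw indicator would set self-loops
  (self-loops are added only inside encoder layers, for isolated nodes).
* kNN ties break toward the lower drug index (stable sort);
  symmetrization by union.
* Degree-normalization of context matrices passes zero-degree rows
  through unchanged (their rows are all-zero anyway).
* The unified topology's degree includes the diagonal similarity
  contribution (the row sum runs over all columns), unlike the
  zero-diagonal adjacency convention; both are deliberate and tested.
* All matrices are dense float64; the intended scale is N ≲ 5 000.
* Gradient clamps (`clip`) carry the true subgradient (zero outside the
  range); stability offsets (1e-300 inside square roots) keep gradients
  finite at exactly-zero rows without changing values.
* The autodiff tape is a minimal reverse-mode engine over NumPy arrays,
  property-tested against central finite differences for every primitive
  and every loss.

## Known limitations

* Graph construction is discrete, so λ learns only through the
  similarity-preservation term, not through the edge set; with very few
  epochs the weights move little (the recovery check asks only that the
  argmax lands on the informative modality).
* The co-prescription KL term is a calibration pressure, not a proper
  divergence (see above).
* Embeddings are constrained near the unit sphere, which bounds
  `σ(z_iᵀz_j)` away from 0 and 1; the pair MLP head, not the raw inner
  product, carries the final calibration.
* Dense similarity matrices make memory quadratic in N.
* The ablation gaps on the synthetic default are small because the task
  is near its noise ceiling; ordering, not magnitude, is the tested
  property.
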