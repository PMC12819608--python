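"""Loss terms for the joint contrastive–supervised objective and the
knowledge-alignment regularization suite.

Every function computes the printed double-sum / trace formula exactly
(so closed-form hand values hold); normalization by term counts, when
desired for optimisation, is the caller's responsibility.  All functions
are generic over plain arrays and :class:`~ddikit.autodiff.Tensor`.

A note on signs: the co-prescription KL calibration compares a
row-normalized probability table against sigmoid inner products, which do
not form a normalized distribution; the resulting sum is therefore not
guaranteed non-negative (it is zero when the sigmoids match the table on
every active pair, and finite always).  Every other term is >= 0 by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import value

__all__ = [
    "LossWeights", "TripletBatch",
    "softplus", "contrastive_triplet", "similarity_preserving",
    "supervised_ce", "embedding_objective",
    "context_alignment", "context_contrastive", "laplacian_smoothness",
    "coprescription_kl", "mmd_alignment", "margin_ranking",
    "entropy_regularizer", "alignment_objective",
]

CLAMP = 30.0          # inner products clamped to +-30 before exp/log
PROB_EPS = 1e-12      # probability clamping inside log terms


@dataclass(frozen=True)
class LossWeights:
    """Trade-off weights of the joint objective.

    ``embedding`` = (lambda1, lambda2) weighting the similarity-preserving
    and supervised terms; ``alignment`` = (alpha1..alpha6) weighting the
    context, Laplacian, co-prescription, MMD, ranking and entropy terms.
    """

    embedding: tuple = (1.0, 1.0)
    alignment: tuple = (0.1, 0.1, 0.1, 0.1, 0.1, 0.1)
    contrastive_margin: float = 1.0       # tau, context-contrastive margin
    ranking_margin: float = 1.0           # delta, margin ranking
    mmd_bandwidth: object = "median"

    def __post_init__(self):
        all_w = (*self.embedding, *self.alignment)
        if any((not np.isfinite(w)) or w < 0 for w in all_w):
            raise ValueError("loss weights must be finite and >= 0")
        if self.contrastive_margin < 0 or self.ranking_margin < 0:
            raise ValueError("margins must be >= 0")


@dataclass(frozen=True)
class TripletBatch:
    """Index triples (anchor, positive, negative)."""

    anchors: np.ndarray
    positives: np.ndarray
    negatives: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.anchors, dtype=int)
        p = np.asarray(self.positives, dtype=int)
        n = np.asarray(self.negatives, dtype=int)
        if not (len(a) == len(p) == len(n)):
            raise ValueError("triplet index arrays must share a length")
        if ((a == p) | (a == n) | (p == n)).any():
            raise ValueError("index collision inside a triple")
        object.__setattr__(self, "anchors", a)
        object.__setattr__(self, "positives", p)
        object.__setattr__(self, "negatives", n)

    def __len__(self):
        return len(self.anchors)


def softplus(x):
    """ln(1 + exp(x)) with the argument clamped to +-30 for stability.

    Algebraically softplus(x) = -ln sigmoid(-x), so both terms of the
    triplet contrastive loss reduce to this one function.
    """
    return ad.log(ad.add(1.0, ad.exp(ad.clip(x, -CLAMP, CLAMP))))


def contrastive_triplet(z, batch: TripletBatch):
    """sum_i [ ln(1 + exp(z_i.z_neg)) - ln sigmoid(z_i.z_pos) ].

    At all-zero embeddings each anchor contributes 2 ln 2.
    """
    if len(batch) == 0:
        warnings.warn("empty triplet batch; contrastive loss is 0")
        return np.float64(0.0) if not isinstance(z, ad.Tensor) else ad.mul(0.0, ad.asum(z))
    za = ad.take(z, batch.anchors)
    zp = ad.take(z, batch.positives)
    zn = ad.take(z, batch.negatives)
    s_pos = ad.asum(ad.mul(za, zp), axis=1)
    s_neg = ad.asum(ad.mul(za, zn), axis=1)
    # -ln sigmoid(x) = softplus(-x)
    return ad.asum(ad.add(softplus(s_neg), softplus(ad.neg(s_pos))))


def _cosine_matrix(z):
    """Row-cosine matrix with zero rows mapped to cosine 0 (flagged)."""
    zd = value(z)
    norms = np.linalg.norm(zd, axis=1)
    if (norms == 0).any():
        warnings.warn("zero embedding rows: their cosine is defined as 0")
    # sqrt offset keeps gradients finite; exact zeros give cosine 0 anyway
    inv = ad.div(1.0, ad.add(ad.sqrt(ad.add(
        ad.asum(ad.mul(z, z), axis=1, keepdims=True), 1e-300)), 0.0))
    zn = ad.mul(z, inv)
    return ad.matmul(zn, ad.transpose(zn))


def similarity_preserving(z, fused: np.ndarray, mode: str = "cosine"):
    """Similarity-preservation over all ordered pairs i != j.

    ``sqdist``: sum_ij S_ij ||z_i - z_j||^2 (graph-weighted smoothness);
    ``cosine``: sum_ij (S_ij - cos(z_i, z_j))^2 (reconstruction form).
    """
    n = value(fused).shape[0]
    off = 1.0 - np.eye(n)
    if mode == "sqdist":
        sq = ad.asum(ad.mul(z, z), axis=1, keepdims=True)
        d2 = ad.add(ad.add(sq, ad.transpose(sq)),
                    ad.mul(-2.0, ad.matmul(z, ad.transpose(z))))
        return ad.asum(ad.mul(ad.mul(fused, off), d2))
    if mode == "cosine":
        diff = ad.sub(fused, _cosine_matrix(z))
        return ad.asum(ad.mul(off, ad.mul(diff, diff)))
    raise ValueError(f"unknown mode {mode!r}")


def _softmax_rows(logits):
    shift = value(logits).max(axis=-1, keepdims=True)  # constant shift
    e = ad.exp(ad.sub(logits, shift))
    return ad.div(e, ad.asum(e, axis=-1, keepdims=True))


def supervised_ce(z, class_weight, labels):
    """Mean cross-entropy of the linear softmax head yhat = softmax(W_c z).

    ``class_weight`` is the (C, d) matrix W_c; ``labels`` are integer class
    ids in [0, C).
    """
    y = np.asarray(labels, dtype=int)
    c = value(class_weight).shape[0]
    if (y < 0).any() or (y >= c).any():
        raise ValueError(f"labels must lie in [0, {c})")
    yhat = _softmax_rows(ad.matmul(z, ad.transpose(class_weight)))
    onehot = np.eye(c)[y]
    picked = ad.asum(ad.mul(yhat, onehot), axis=1)
    return ad.neg(ad.amean(ad.log(ad.clip(picked, PROB_EPS, 1.0))))


def embedding_objective(l_ctr, l_sim, l_sup, weights: LossWeights):
    """L_ctr + lambda1 L_sim + lambda2 L_sup."""
    lam1, lam2 = weights.embedding
    return ad.add(l_ctr, ad.add(ad.mul(lam1, l_sim), ad.mul(lam2, l_sup)))


# ---------------------------------------------------------------------
# knowledge-alignment suite
# ---------------------------------------------------------------------

def context_alignment(z, context):
    """sum_p w_p sum_ij R_p(i,j) ||z_i - z_j||^2, via 2 tr(Z^T L_p Z).

    The trace identity tr(Z^T L Z) = 1/2 sum_ij R_ij ||z_i - z_j||^2 means
    the printed double sum over *ordered* pairs equals twice the trace.
    """
    total = None
    for w, lap in zip(context.context_weights, context.context_laplacians):
        term = ad.mul(2.0 * float(w), ad.asum(ad.mul(z, ad.matmul(lap, z))))
        total = term if total is None else ad.add(total, term)
    return total


def _pairwise_sq_dists(z):
    sq = ad.asum(ad.mul(z, z), axis=1, keepdims=True)
    d2 = ad.add(ad.add(sq, ad.transpose(sq)),
                ad.mul(-2.0, ad.matmul(z, ad.transpose(z))))
    return ad.relu(d2)  # clip tiny negative rounding


def context_contrastive(z, context, margin: float):
    """Context-aware contrastive alignment with a margin on non-members.

    sum_p w_p sum_{i != j} [ R_p d_ij^2 + (1 - R_p) max(0, tau - d_ij)^2 ].
    """
    n = value(z).shape[0]
    off = 1.0 - np.eye(n)
    d2 = _pairwise_sq_dists(z)
    dist = ad.sqrt(ad.add(d2, 1e-300))
    hinge = ad.relu(ad.sub(margin, dist))
    hinge2 = ad.mul(hinge, hinge)
    total = None
    for w, r in zip(context.context_weights, context.comembership):
        inside = ad.mul(r * off, d2)
        outside = ad.mul((1.0 - r) * off, hinge2)
        term = ad.mul(float(w), ad.asum(ad.add(inside, outside)))
        total = term if total is None else ad.add(total, term)
    return total


def laplacian_smoothness(z, topology):
    """tr(Z^T L_G Z) = 1/2 sum_ij G_ij ||z_i - z_j||^2 (zero-diagonal G)."""
    return ad.asum(ad.mul(z, ad.matmul(topology.laplacian, z)))


def coprescription_kl(z, data, weighted: bool = True):
    """KL-style calibration of sigmoid(z_i . z_j) to co-prescription
    probabilities; terms with P_co = 0 contribute 0.

    With ``weighted`` the confidence rho_ij = min(1, ln(1 + O_ij)) damps
    rare co-occurrences.
    """
    p = data.probabilities
    active = (p > 0).astype(np.float64)
    logp = np.where(p > 0, np.log(np.maximum(p, PROB_EPS)), 0.0)
    sig = ad.clip(ad.sigmoid(ad.matmul(z, ad.transpose(z))),
                  PROB_EPS, 1.0 - PROB_EPS)
    per_pair = ad.mul(active * p, ad.sub(logp, ad.log(sig)))
    if weighted:
        per_pair = ad.mul(data.confidence, per_pair)
    return ad.asum(per_pair)


def _gaussian_kernel(x, y, bandwidth: float):
    sqx = ad.asum(ad.mul(x, x), axis=1, keepdims=True)
    sqy = ad.asum(ad.mul(y, y), axis=1, keepdims=True)
    d2 = ad.add(ad.add(sqx, ad.transpose(sqy)),
                ad.mul(-2.0, ad.matmul(x, ad.transpose(y))))
    d2 = ad.relu(d2)  # clip rounding so k(x, x) = 1 exactly
    return ad.exp(ad.div(ad.neg(d2), 2.0 * bandwidth ** 2))


def median_bandwidth(samples: list) -> float:
    """Median pairwise distance of the pooled sample set."""
    pooled = np.concatenate([value(s) for s in samples], axis=0)
    sq = np.sum(pooled * pooled, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * pooled @ pooled.T, 0.0)
    iu = np.triu_indices(len(pooled), k=1)
    med = float(np.median(np.sqrt(d2[iu])))
    return med if med > 0 else 1.0


def mmd_alignment(embeddings: list, bandwidth="median"):
    """Sum over unordered modality pairs of the biased-estimator squared
    maximum mean discrepancy with a Gaussian kernel.

    The biased estimator keeps the x = x' diagonal terms, guaranteeing a
    non-negative value and exact zero for identical samples.
    """
    if len(embeddings) < 2:
        warnings.warn("single modality: MMD alignment is 0")
        return np.float64(0.0)
    bw = (median_bandwidth(embeddings) if bandwidth == "median"
          else float(bandwidth))
    total = None
    for m in range(len(embeddings) - 1):
        for n in range(m + 1, len(embeddings)):
            x, y = embeddings[m], embeddings[n]
            kxx = ad.amean(_gaussian_kernel(x, x, bw))
            kyy = ad.amean(_gaussian_kernel(y, y, bw))
            kxy = ad.amean(_gaussian_kernel(x, y, bw))
            term = ad.add(ad.add(kxx, kyy), ad.mul(-2.0, kxy))
            total = term if total is None else ad.add(total, term)
    return total


def margin_ranking(z, batch: TripletBatch, margin: float):
    """sum_{(i,j,k)} max(0, delta + ||z_i - z_j||^2 - ||z_i - z_k||^2),
    with j compatible and k incompatible with anchor i."""
    za = ad.take(z, batch.anchors)
    zp = ad.take(z, batch.positives)
    zn = ad.take(z, batch.negatives)
    dp = ad.asum(ad.mul(ad.sub(za, zp), ad.sub(za, zp)), axis=1)
    dn = ad.asum(ad.mul(ad.sub(za, zn), ad.sub(za, zn)), axis=1)
    return ad.asum(ad.relu(ad.add(margin, ad.sub(dp, dn))))


def entropy_regularizer(yhat):
    """-sum_i sum_c yhat_ic ln yhat_ic with 0 ln 0 := 0.

    Uniform predictions over C classes give N ln C; one-hot rows give 0.
    """
    clamped = ad.clip(yhat, PROB_EPS, 1.0)
    return ad.neg(ad.asum(ad.mul(yhat, ad.log(clamped))))


def alignment_objective(components, weights: LossWeights):
    """alpha1 L_ctx + alpha2 L_lap + alpha3 L_co + alpha4 L_mmd
    + alpha5 L_rank + alpha6 L_ent.

    ``components`` is the tuple (L_ctx, L_lap, L_co, L_mmd, L_rank, L_ent).
    """
    if len(components) != 6:
        raise ValueError("expected 6 components (ctx, lap, co, mmd, rank, ent)")
    total = None
    for a, comp in zip(weights.alignment, components):
        term = ad.mul(float(a), comp)
        total = term if total is None else ad.add(total, term)
    return total
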