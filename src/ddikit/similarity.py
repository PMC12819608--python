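"""Per-modality similarity kernels, convex fusion, and relational graphs.

The inter-drug graph is built in three stages: a modality-specific kernel
turns each feature block into a symmetric similarity matrix S^(m); the
matrices are fused by a convex combination with simplex weights lambda;
the fused similarity is sparsified (threshold or k-nearest-neighbour) into
a binary adjacency from which degree and Laplacian matrices follow.

Knowledge structures live here too: binary context co-membership matrices
R_p (one per pharmacological context, e.g. therapeutic class), the unified
topology G = sum_m S^(m) + sum_p R_p, and co-prescription statistics
(row-normalized conditional probabilities and a log-damped confidence).

All matrices are dense float64; the intended scale is a few thousand drugs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DrugFeatureSet", "SimilarityStack", "RelationalGraph",
    "KnowledgeContext", "CoPrescriptionData", "UnifiedTopology",
    "modality_similarity", "build_similarity_stack", "fuse_similarities",
    "threshold_adjacency", "knn_sparsify", "context_comembership",
    "unified_topology", "coprescription_probabilities",
]


@dataclass(frozen=True)
class DrugFeatureSet:
    """Concatenated multimodal feature matrix with per-modality slices."""

    features: np.ndarray          # (N, F)
    modality_slices: list         # list[slice] partitioning the columns
    drug_ids: list

    def __post_init__(self):
        if self.features.shape[0] != len(self.drug_ids):
            raise ValueError("row count must match number of drug ids")
        total = sum(s.stop - s.start for s in self.modality_slices)
        if total != self.features.shape[1]:
            raise ValueError("modality slices must partition the columns")
        if np.isnan(self.features).any():
            raise ValueError("features contain missing values")

    def block(self, m: int) -> np.ndarray:
        return self.features[:, self.modality_slices[m]]


@dataclass
class SimilarityStack:
    """Per-modality similarity matrices and their convex fusion."""

    matrices: list                 # list of (N, N) symmetric arrays
    kernel_kinds: list             # per-modality kernel tag
    fusion_weights: np.ndarray     # simplex vector, length M
    fused: np.ndarray = None

    def __post_init__(self):
        w = np.asarray(self.fusion_weights, dtype=np.float64)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("fusion weights must be non-negative and sum to 1")
        self.fusion_weights = w
        if self.fused is None:
            self.fused = fuse_similarities(self.matrices, w)

    @property
    def n_modalities(self) -> int:
        return len(self.matrices)


@dataclass(frozen=True)
class RelationalGraph:
    """Binary drug graph with degree and Laplacian matrices attached."""

    adjacency: np.ndarray
    epsilon: float | None = None
    knn_k: int | None = None
    degree: np.ndarray = None
    laplacian: np.ndarray = None
    normalized_laplacian: np.ndarray = None
    isolated_nodes: np.ndarray = None

    def __post_init__(self):
        a = self.adjacency
        deg = a.sum(axis=1)
        iso = np.flatnonzero(deg == 0)
        d_inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1)), 0.0)
        norm_l = np.eye(len(a)) - d_inv_sqrt[:, None] * a * d_inv_sqrt[None, :]
        object.__setattr__(self, "degree", deg)
        object.__setattr__(self, "laplacian", np.diag(deg) - a)
        object.__setattr__(self, "normalized_laplacian", norm_l)
        object.__setattr__(self, "isolated_nodes", iso)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass(frozen=True)
class KnowledgeContext:
    """Context co-membership matrices R_p with weights, Laplacians and
    symmetric normalizations (zero-degree rows passed through unchanged)."""

    comembership: list                 # list of (N, N) binary arrays
    context_ids: list
    context_weights: np.ndarray = None
    normalized: list = None
    context_laplacians: list = None

    def __post_init__(self):
        if self.context_weights is None:
            object.__setattr__(self, "context_weights",
                               np.ones(len(self.comembership)))
        w = np.asarray(self.context_weights, dtype=np.float64)
        if (w < 0).any() or not np.isfinite(w).all():
            raise ValueError("context weights must be finite and >= 0")
        object.__setattr__(self, "context_weights", w)
        norms, laps = [], []
        for r in self.comembership:
            deg = r.sum(axis=1)
            laps.append(np.diag(deg) - r)
            scale = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1)), 1.0)
            norms.append(scale[:, None] * r * scale[None, :])
        object.__setattr__(self, "normalized", norms)
        object.__setattr__(self, "context_laplacians", laps)

    @property
    def n_contexts(self) -> int:
        return len(self.comembership)


@dataclass(frozen=True)
class CoPrescriptionData:
    """Co-prescription counts O with row-normalized probabilities P_co and
    confidence weights rho_ij = min(1, ln(1 + O_ij))."""

    counts: np.ndarray
    probabilities: np.ndarray = None
    confidence: np.ndarray = None

    def __post_init__(self):
        o = np.asarray(self.counts, dtype=np.float64).copy()
        if (o < 0).any():
            raise ValueError("co-prescription counts must be non-negative")
        np.fill_diagonal(o, 0.0)
        rowsum = o.sum(axis=1)
        if (rowsum == 0).any():
            warnings.warn("co-prescription matrix has all-zero rows; their "
                          "probability rows are set to zero")
        p = np.divide(o, rowsum[:, None], out=np.zeros_like(o),
                      where=rowsum[:, None] > 0)
        object.__setattr__(self, "counts", o)
        object.__setattr__(self, "probabilities", p)
        object.__setattr__(self, "confidence", np.minimum(1.0, np.log1p(o)))


@dataclass(frozen=True)
class UnifiedTopology:
    """G = sum_m S^(m) + sum_p R_p with its degree and Laplacian.

    Degrees include the diagonal contribution of the similarity matrices
    (the row sum runs over every column), unlike the zero-diagonal
    convention used for the binary adjacency A.
    """

    matrix: np.ndarray
    degree: np.ndarray = None
    laplacian: np.ndarray = None

    def __post_init__(self):
        deg = self.matrix.sum(axis=1)
        object.__setattr__(self, "degree", deg)
        object.__setattr__(self, "laplacian", np.diag(deg) - self.matrix)


# ---------------------------------------------------------------------
# kernels and fusion
# ---------------------------------------------------------------------

def modality_similarity(features: np.ndarray, kernel: str = "cosine") -> np.ndarray:
    """Pairwise similarity for one modality block.

    Kernels: ``cosine`` (zero rows get similarity 0 to everything, with a
    warning), ``gaussian`` exp(-||xi-xj||^2 / (2 sigma^2)) with the median
    pairwise distance as bandwidth, ``jaccard`` for binary blocks.
    """
    x = np.asarray(features, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    n = x.shape[0]
    if kernel == "cosine":
        norms = np.linalg.norm(x, axis=1)
        zero = norms == 0
        if zero.any():
            warnings.warn("cosine kernel: zero-vector rows get similarity 0")
        safe = np.where(zero, 1.0, norms)
        s = (x / safe[:, None]) @ (x / safe[:, None]).T
        s[zero, :] = 0.0
        s[:, zero] = 0.0
        np.fill_diagonal(s, np.where(zero, 0.0, 1.0))
    elif kernel == "gaussian":
        sq = np.sum(x * x, axis=1)
        d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * x @ x.T, 0.0)
        iu = np.triu_indices(n, k=1)
        bandwidth = float(np.median(np.sqrt(d2[iu])))
        if bandwidth == 0:
            bandwidth = 1.0
        s = np.exp(-d2 / (2.0 * bandwidth ** 2))
        np.fill_diagonal(s, 1.0)
    elif kernel == "jaccard":
        if not np.isin(x, (0.0, 1.0)).all():
            raise ValueError("jaccard kernel requires a binary matrix")
        inter = x @ x.T
        sizes = x.sum(axis=1)
        union = sizes[:, None] + sizes[None, :] - inter
        s = np.divide(inter, union, out=np.zeros_like(inter),
                      where=union > 0)
        np.fill_diagonal(s, 1.0)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return 0.5 * (s + s.T)  # enforce exact symmetry


def build_similarity_stack(feature_set: DrugFeatureSet, kernels=None,
                           weights=None) -> SimilarityStack:
    """Kernel each modality block and fuse (uniform weights by default)."""
    m = len(feature_set.modality_slices)
    if kernels is None:
        kernels = ["cosine"] * m
    if weights is None:
        weights = np.full(m, 1.0 / m)
    mats = [modality_similarity(feature_set.block(i), kernels[i])
            for i in range(m)]
    return SimilarityStack(matrices=mats, kernel_kinds=list(kernels),
                           fusion_weights=np.asarray(weights, float))


def fuse_similarities(matrices, weights) -> np.ndarray:
    """Convex combination sum_m lambda_m S^(m) (elementwise)."""
    w = np.asarray(weights, dtype=np.float64)
    if len(w) != len(matrices):
        raise ValueError("one weight per modality required")
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("weights must be a simplex vector (>=0, sum 1)")
    fused = np.zeros_like(np.asarray(matrices[0], dtype=np.float64))
    for wm, s in zip(w, matrices):
        fused = fused + wm * np.asarray(s, dtype=np.float64)
    return fused


# ---------------------------------------------------------------------
# sparsification
# ---------------------------------------------------------------------

def threshold_adjacency(fused: np.ndarray, epsilon: float) -> RelationalGraph:
    """A_ij = 1 iff i != j and fused_ij > epsilon (strict)."""
    f = np.asarray(fused, dtype=np.float64)
    if not np.allclose(f, f.T):
        raise ValueError("fused similarity must be symmetric")
    a = (f > epsilon).astype(np.float64)
    np.fill_diagonal(a, 0.0)
    g = RelationalGraph(adjacency=a, epsilon=float(epsilon))
    if len(g.isolated_nodes):
        warnings.warn(f"thresholded graph has {len(g.isolated_nodes)} "
                      "isolated node(s)")
    return g


def knn_sparsify(fused: np.ndarray, k: int) -> RelationalGraph:
    """Keep each node's k most similar neighbours; union-symmetrized.

    Ties are broken toward the lower drug index (stable sort on -sim).
    """
    f = np.asarray(fused, dtype=np.float64)
    n = f.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError("k must lie in [1, N-1]")
    a = np.zeros((n, n))
    for i in range(n):
        sims = f[i].copy()
        sims[i] = -np.inf
        order = np.argsort(-sims, kind="stable")
        a[i, order[:k]] = 1.0
    a = np.maximum(a, a.T)  # edge kept if either endpoint selected it
    return RelationalGraph(adjacency=a, knn_k=int(k))


# ---------------------------------------------------------------------
# knowledge structures
# ---------------------------------------------------------------------

def context_comembership(assignments, n_drugs: int | None = None,
                         weights=None) -> KnowledgeContext:
    """Binary co-membership matrices from per-drug context annotations.

    ``assignments`` is a sequence (one entry per drug, index = drug) of
    iterables of context ids.  R_p(i, j) = 1 iff i != j and both drugs
    carry context p.
    """
    sets = [set(a) for a in assignments]
    if n_drugs is None:
        n_drugs = len(sets)
    if len(sets) != n_drugs:
        raise ValueError("one context set per drug required")
    ctx_ids = sorted({c for s in sets for c in s})
    if not ctx_ids:
        raise ValueError("at least one context required")
    mats = []
    for c in ctx_ids:
        member = np.array([c in s for s in sets], dtype=np.float64)
        r = np.outer(member, member)
        np.fill_diagonal(r, 0.0)
        mats.append(r)
    return KnowledgeContext(comembership=mats, context_ids=ctx_ids,
                            context_weights=weights)


def unified_topology(stack: SimilarityStack,
                     context: KnowledgeContext | None = None) -> UnifiedTopology:
    """G = sum_m S^(m) + sum_p R_p (unweighted sums, as defined)."""
    g = np.zeros_like(stack.matrices[0])
    for s in stack.matrices:
        if s.shape != g.shape:
            raise ValueError("similarity matrices must share a shape")
        g = g + s
    if context is not None:
        for r in context.comembership:
            if r.shape != g.shape:
                raise ValueError("context matrices must match drug count")
            g = g + r
    return UnifiedTopology(matrix=g)


def coprescription_probabilities(counts: np.ndarray) -> CoPrescriptionData:
    """Row-normalize co-prescription counts into conditional probabilities."""
    return CoPrescriptionData(counts=np.asarray(counts, dtype=np.float64))
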