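"""Graph encoders: inter-drug attention propagation, molecular encoding,
and the pairwise cross-attention head.

The inter-drug encoder stacks attention layers over the relational drug
graph: each layer transforms neighbour states, weighs them with softmax
attention coefficients computed from a shared attention vector, applies a
residual connection to the (projected) input state, and row-normalizes to
unit scale.  A multi-hop aggregation sums the per-layer states with
trainable scalar weights so the final embedding mixes local and wider
neighbourhood context.

All inter-drug functions are generic over plain ``numpy`` arrays and
:class:`~ddikit.autodiff.Tensor`: the same code is the trainable forward
pass and the reference evaluation path.  The molecular (intra-drug)
encoder operates on plain arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import value

__all__ = [
    "EncoderParams", "EmbeddingState", "PairRepresentation",
    "MolecularEncoderParams", "CrossAttentionParams", "PairHeadParams",
    "mean_aggregate_layer", "attention_coefficients", "gat_layer",
    "multi_hop_aggregate", "forward_encoder", "encode_molecule",
    "global_attention_pool", "cross_attention_pair", "pair_score",
]


def _activate(x, tag: str, slope: float = 0.2):
    if tag == "relu":
        return ad.relu(x)
    if tag == "leaky_relu":
        return ad.leaky_relu(x, slope)
    if tag == "identity":
        return x
    raise ValueError(f"unknown activation {tag!r}")


def _with_self_loops(adjacency: np.ndarray) -> np.ndarray:
    """Insert a self-loop at isolated nodes so softmax rows are defined."""
    a = np.asarray(value(adjacency), dtype=np.float64).copy()
    np.fill_diagonal(a, 0.0)
    deg = a.sum(axis=1)
    iso = deg == 0
    if iso.any():
        a[np.flatnonzero(iso), np.flatnonzero(iso)] = 1.0
    return a


# ---------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------

@dataclass
class EncoderParams:
    """Weights of the inter-drug attention encoder.

    ``layer_transforms[k][h]`` is the (d_in, d) transform of head h at
    layer k; ``attention_vectors[k][h]`` the matching shared attention
    vector of length 2d.  ``hop_weights`` are the multi-hop scalars
    gamma_k (initialized 1/K, unconstrained).
    """

    layer_transforms: list
    attention_vectors: list
    hop_weights: object            # (K,) array or Tensor
    n_layers: int
    hidden_dim: int
    n_heads: int = 1
    leaky_slope: float = 0.2
    stability_eps: float = 1e-8

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("need at least one layer")
        if self.stability_eps <= 0:
            raise ValueError("stability_eps must be positive")
        for k, heads in enumerate(self.attention_vectors):
            for a in heads:
                if value(a).size != 2 * self.hidden_dim:
                    raise ValueError(
                        f"attention vector at layer {k} must have length "
                        f"2*hidden_dim={2 * self.hidden_dim}")

    @staticmethod
    def initialize(d_in: int, hidden_dim: int, n_layers: int,
                   n_heads: int = 1, seed: int = 0,
                   leaky_slope: float = 0.2,
                   stability_eps: float = 1e-8) -> "EncoderParams":
        rng = np.random.default_rng(seed)
        transforms, vectors = [], []
        for k in range(n_layers):
            din = d_in if k == 0 else hidden_dim
            sw = np.sqrt(2.0 / (din + hidden_dim))
            transforms.append([rng.normal(0, sw, size=(din, hidden_dim))
                               for _ in range(n_heads)])
            vectors.append([rng.normal(0, 0.1, size=(2 * hidden_dim,))
                            for _ in range(n_heads)])
        return EncoderParams(
            layer_transforms=transforms, attention_vectors=vectors,
            hop_weights=np.full(n_layers, 1.0 / n_layers),
            n_layers=n_layers, hidden_dim=hidden_dim, n_heads=n_heads,
            leaky_slope=leaky_slope, stability_eps=stability_eps)


@dataclass
class EmbeddingState:
    """Per-layer states, multi-hop combination and final embeddings."""

    layer_states: list             # H^(0..K)
    multi_hop: object              # Z_multi
    final: object                  # Z, row-normalized
    attention_maps: list = field(default_factory=list)  # per-layer (N, N)


@dataclass
class PairRepresentation:
    """Cross-attention alignment of two drugs' substructure states."""

    drug_pair: tuple
    node_states_i: object
    node_states_j: object
    cross_attention_weights: np.ndarray    # i-nodes x j-nodes, masked rows
    cross_attention_weights_ji: np.ndarray
    pooled: object                         # length-2d pair vector
    score: float | None = None


@dataclass
class CrossAttentionParams:
    """Per-head query/key/value projections for pair cross-attention."""

    wq: list
    wk: list
    wv: list

    @property
    def n_heads(self) -> int:
        return len(self.wq)

    @staticmethod
    def initialize(d: int, n_heads: int = 1, seed: int = 0,
                   symmetric: bool = False) -> "CrossAttentionParams":
        rng = np.random.default_rng(seed)
        sw = np.sqrt(1.0 / d)
        wq = [rng.normal(0, sw, size=(d, d)) for _ in range(n_heads)]
        wk = ([np.array(w) for w in wq] if symmetric
              else [rng.normal(0, sw, size=(d, d)) for _ in range(n_heads)])
        wv = [rng.normal(0, sw, size=(d, d)) for _ in range(n_heads)]
        return CrossAttentionParams(wq=wq, wk=wk, wv=wv)


@dataclass
class PairHeadParams:
    """Logistic MLP scoring head over pair features."""

    w1: object
    b1: object
    w2: object
    b2: object

    @staticmethod
    def initialize(feat_dim: int, hidden: int, seed: int = 0) -> "PairHeadParams":
        rng = np.random.default_rng(seed)
        sw = np.sqrt(2.0 / (feat_dim + hidden))
        return PairHeadParams(
            w1=rng.normal(0, sw, size=(feat_dim, hidden)),
            b1=np.zeros(hidden),
            w2=rng.normal(0, np.sqrt(1.0 / hidden), size=(hidden, 1)),
            b2=np.zeros(1))


# ---------------------------------------------------------------------
# inter-drug layers
# ---------------------------------------------------------------------

def mean_aggregate_layer(state, adjacency, transform, activation: str = "relu"):
    """h_i <- act( (1/|N(i)|) sum_{j in N(i)} W h_j ).

    Isolated nodes fall back to a self-loop, so the layer is defined on
    any graph.
    """
    a = _with_self_loops(adjacency)
    if a.shape[0] != value(state).shape[0]:
        raise ValueError("graph and state row counts must match")
    deg = a.sum(axis=1, keepdims=True)
    msg = ad.div(ad.matmul(a, ad.matmul(state, transform)), deg)
    return _activate(msg, activation)


def attention_coefficients(state, adjacency, transform, attn_vector,
                           leaky_slope: float = 0.2):
    """Softmax attention over each node's neighbourhood.

    alpha_ij = softmax_{j in N(i)} LeakyReLU( a^T [W h_i || W h_j] ),
    returned as an (N, N) matrix that is zero off-edges and whose rows sum
    to 1 over the neighbourhood (self-loops inserted at isolated nodes).
    """
    if not np.isfinite(value(state)).all():
        bad = np.flatnonzero(~np.isfinite(value(state)).all(axis=1))
        raise FloatingPointError(f"non-finite node state at index {bad[0]}")
    a_eff = _with_self_loops(adjacency)
    wh = ad.matmul(state, transform)
    d = value(transform).shape[1]
    a2d = ad.reshape(attn_vector, (-1, 1))
    a_src = ad.take(a2d, np.arange(d))
    a_dst = ad.take(a2d, np.arange(d, 2 * d))
    f_src = ad.matmul(wh, a_src)                 # (N, 1)
    f_dst = ad.matmul(wh, a_dst)                 # (N, 1)
    logits = ad.leaky_relu(ad.add(f_src, ad.transpose(f_dst)), leaky_slope)
    return ad.masked_softmax(logits, a_eff, axis=1)


def gat_layer(state, adjacency, params: EncoderParams, layer: int,
              h0=None, activation: str = "relu", residual: bool = True,
              dropout_p: float = 0.0, rng=None):
    """One attention propagation layer.

    Per head: h_i <- act( sum_j alpha_ij W h_j ); heads are averaged;
    then the residual h_i <- h_i + h0_i (requires matching dims) and the
    row normalization h_i <- h_i / (||h_i||_2 + eps).

    Returns ``(next_state, attention)`` where ``attention`` is the
    head-averaged (N, N) coefficient matrix as a plain array.
    """
    outs, alphas = [], []
    for h in range(params.n_heads):
        w = params.layer_transforms[layer][h]
        a = params.attention_vectors[layer][h]
        alpha = attention_coefficients(state, adjacency, w, a,
                                       params.leaky_slope)
        alpha = ad.dropout(alpha, dropout_p, rng)
        outs.append(ad.matmul(alpha, ad.matmul(state, w)))
        alphas.append(value(alpha))
    out = outs[0]
    for o in outs[1:]:
        out = ad.add(out, o)
    out = ad.div(out, float(params.n_heads))
    out = _activate(out, activation)
    if residual:
        if h0 is None:
            raise ValueError("residual connection requires the base state h0")
        if value(h0).shape != value(out).shape:
            raise ValueError(
                "residual requires h0 projected to the layer dimension "
                f"(got {value(h0).shape} vs {value(out).shape})")
        out = ad.add(out, h0)
    out = _row_normalize(out, params.stability_eps)
    return out, np.mean(alphas, axis=0)


def _row_normalize(h, eps: float):
    """h_i / (||h_i||_2 + eps); the tiny inner offset keeps the gradient
    of sqrt finite at exactly-zero rows."""
    norm = ad.sqrt(ad.add(ad.asum(ad.mul(h, h), axis=1, keepdims=True),
                          1e-300))
    return ad.div(h, ad.add(norm, eps))


def multi_hop_aggregate(states, hop_weights):
    """Z_multi = sum_k gamma_k H^(k) over layer states H^(1..K)."""
    shapes = {value(s).shape for s in states}
    if len(shapes) != 1:
        raise ValueError("all layer states must share a shape")
    if isinstance(hop_weights, ad.Tensor):
        g2d = ad.reshape(hop_weights, (-1, 1))
        if value(g2d).shape[0] != len(states):
            raise ValueError("one hop weight per layer state required")
        out = ad.mul(ad.take(g2d, [0]), states[0])
        for k in range(1, len(states)):
            out = ad.add(out, ad.mul(ad.take(g2d, [k]), states[k]))
        return out
    gw = np.asarray(hop_weights, dtype=np.float64).ravel()
    if gw.size != len(states):
        raise ValueError("one hop weight per layer state required")
    out = ad.mul(float(gw[0]), states[0])
    for k in range(1, len(states)):
        out = ad.add(out, ad.mul(float(gw[k]), states[k]))
    return out


def forward_encoder(h0, adjacency, params: EncoderParams,
                    activation: str = "relu", residual: bool = True,
                    dropout_p: float = 0.0, rng=None,
                    attention: bool = True) -> EmbeddingState:
    """Run the full K-layer encoder from a (projected) input state h0.

    With ``attention=False`` the layers degrade to plain mean
    aggregation (no attention coefficients, residuals or normalization),
    and the final state is the last layer's output.
    """
    states = [h0]
    maps = []
    state = h0
    if attention:
        for k in range(params.n_layers):
            state, alpha = gat_layer(state, adjacency, params, k, h0=h0,
                                     activation=activation, residual=residual,
                                     dropout_p=dropout_p, rng=rng)
            states.append(state)
            maps.append(alpha)
        multi = multi_hop_aggregate(states[1:], params.hop_weights)
        final = _row_normalize(multi, params.stability_eps)
    else:
        for k in range(params.n_layers):
            # first head's transform doubles as the mean-aggregation weight
            state = mean_aggregate_layer(state, adjacency,
                                         params.layer_transforms[k][0],
                                         activation)
            states.append(state)
        multi = states[-1]
        final = _row_normalize(multi, params.stability_eps)
    return EmbeddingState(layer_states=states, multi_hop=multi,
                          final=final, attention_maps=maps)


# ---------------------------------------------------------------------
# molecular (intra-drug) encoder
# ---------------------------------------------------------------------

@dataclass
class MolecularEncoderParams:
    """Embedding tables and layer weights of the atom-graph encoder."""

    atom_type_emb: np.ndarray
    degree_emb: np.ndarray
    aromatic_emb: np.ndarray
    charge_emb: np.ndarray
    bond_emb: np.ndarray                  # (n_bond_types, bond_dim)
    layer_self: list                      # per layer (d, d)
    layer_msg: list                       # per layer (d + bond_dim, d)
    attn_src: list                        # per layer (d,)
    attn_dst: list                        # per layer (d,)
    pool_vector: np.ndarray               # (d,)
    leaky_slope: float = 0.2
    stability_eps: float = 1e-8

    @property
    def n_layers(self) -> int:
        return len(self.layer_self)

    @property
    def dim(self) -> int:
        return self.atom_type_emb.shape[1]

    @staticmethod
    def initialize(d: int = 16, bond_dim: int = 4, n_layers: int = 3,
                   n_atom_types: int = 6, n_degree: int = 4,
                   n_charge: int = 3, n_bond_types: int = 3,
                   seed: int = 0) -> "MolecularEncoderParams":
        rng = np.random.default_rng(seed)
        emb = lambda n, k: rng.normal(0, 1.0 / np.sqrt(k), size=(n, k))
        return MolecularEncoderParams(
            atom_type_emb=emb(n_atom_types, d),
            degree_emb=emb(n_degree, d),
            aromatic_emb=emb(2, d),
            charge_emb=emb(n_charge, d),
            bond_emb=emb(n_bond_types, bond_dim),
            layer_self=[emb(d, d) * np.sqrt(d) * np.sqrt(2.0 / (2 * d))
                        for _ in range(n_layers)],
            layer_msg=[rng.normal(0, np.sqrt(2.0 / (d + bond_dim + d)),
                                  size=(d + bond_dim, d))
                       for _ in range(n_layers)],
            attn_src=[rng.normal(0, 0.1, size=d) for _ in range(n_layers)],
            attn_dst=[rng.normal(0, 0.1, size=d) for _ in range(n_layers)],
            pool_vector=rng.normal(0, 0.1, size=d))


def global_attention_pool(states: np.ndarray, pool_vector: np.ndarray) -> np.ndarray:
    """Softmax attention pooling over node states (permutation-invariant)."""
    h = np.asarray(states, dtype=np.float64)
    scores = h @ np.asarray(pool_vector, dtype=np.float64)
    scores = scores - scores.max()
    w = np.exp(scores)
    w = w / w.sum()
    return w @ h


def encode_molecule(toy, params: MolecularEncoderParams) -> np.ndarray:
    """Encode an atom/bond graph into a fixed-length drug vector.

    Three attention layers over the molecular graph (bond embeddings are
    concatenated to neighbour messages), followed by global attention
    pooling of the atom states.
    """
    n = toy.n_atoms
    if n == 0:
        raise ValueError("empty molecular graph")
    d = params.dim
    h = np.zeros((n, d))
    for i, (t, deg, arom, chg) in enumerate(toy.atom_labels):
        h[i] = (params.atom_type_emb[t] + params.degree_emb[deg]
                + params.aromatic_emb[arom] + params.charge_emb[chg])
    adj = toy.adjacency()
    bond_type = np.zeros((n, n), dtype=int)
    for u, v, b in toy.bond_list:
        bond_type[u, v] = bond_type[v, u] = b
    h0 = h
    for k in range(params.n_layers):
        # messages m_ij = [h_j || e_ij] W_msg, per directed edge
        hj = np.broadcast_to(h[None, :, :], (n, n, d))
        eij = params.bond_emb[bond_type]                   # (n, n, bond_dim)
        msg = np.concatenate([hj, np.broadcast_to(eij, (n, n, eij.shape[-1]))],
                             axis=2) @ params.layer_msg[k]  # (n, n, d)
        f_src = (h @ params.layer_self[k]) @ params.attn_src[k]   # (n,)
        f_dst = msg @ params.attn_dst[k]                          # (n, n)
        logits = f_src[:, None] + f_dst
        logits = np.where(logits > 0, logits, params.leaky_slope * logits)
        a_eff = _with_self_loops(adj)
        shift = np.max(np.where(a_eff > 0, logits, -np.inf), axis=1,
                       keepdims=True)
        e = np.exp(logits - shift) * a_eff
        alpha = e / e.sum(axis=1, keepdims=True)
        out = np.einsum("ij,ijd->id", alpha, msg)
        out = np.maximum(out, 0.0)
        if out.shape == h0.shape:
            out = out + h0
        norm = np.linalg.norm(out, axis=1, keepdims=True)
        h = out / (norm + params.stability_eps)
    return global_attention_pool(h, params.pool_vector)


# ---------------------------------------------------------------------
# pairwise cross-attention head
# ---------------------------------------------------------------------

def _topk_mask(cosine: np.ndarray, k: int) -> np.ndarray:
    """Binary mask keeping each row's k most similar columns (ties to the
    lower column index)."""
    ni, nj = cosine.shape
    if k > nj:
        warnings.warn(f"top_k={k} exceeds {nj} candidate nodes; clamped")
        k = nj
    mask = np.zeros_like(cosine)
    order = np.argsort(-cosine, axis=1, kind="stable")
    rows = np.repeat(np.arange(ni), k)
    mask[rows, order[:, :k].ravel()] = 1.0
    return mask


def _cosine_table(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(a, axis=1, keepdims=True)
    nb = np.linalg.norm(b, axis=1, keepdims=True)
    na = np.where(na == 0, 1.0, na)
    nb = np.where(nb == 0, 1.0, nb)
    return (a / na) @ (b / nb).T


def _attend(states_q, states_kv, mask: np.ndarray,
            params: CrossAttentionParams):
    dk = value(params.wk[0]).shape[1]
    outs = []
    alpha_avg = None
    for h in range(params.n_heads):
        q = ad.matmul(states_q, params.wq[h])
        k = ad.matmul(states_kv, params.wk[h])
        v = ad.matmul(states_kv, params.wv[h])
        logits = ad.div(ad.matmul(q, ad.transpose(k)), float(np.sqrt(dk)))
        alpha = ad.masked_softmax(logits, mask, axis=1)
        outs.append(ad.matmul(alpha, v))
        alpha_avg = (value(alpha) if alpha_avg is None
                     else alpha_avg + value(alpha))
    out = outs[0]
    for o in outs[1:]:
        out = ad.add(out, o)
    out = ad.div(out, float(params.n_heads))
    return out, alpha_avg / params.n_heads


def cross_attention_pair(states_i, states_j, top_k: int,
                         params: CrossAttentionParams,
                         drug_pair=("i", "j")) -> PairRepresentation:
    """Align two drugs' substructure states by masked cross-attention.

    For each node of drug i, cosine similarity to drug j's nodes selects
    the top_k candidates; scaled dot-product attention (multi-head,
    averaged) is computed over the retained set, and symmetrically with
    the roles swapped.  The pooled pair vector concatenates the
    mean-pooled attended states of both directions.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    si, sj = value(states_i), value(states_j)
    if si.size == 0 or sj.size == 0:
        raise ValueError("empty substructure state matrix")
    cos_ij = _cosine_table(si, sj)
    mask_ij = _topk_mask(cos_ij, top_k)
    mask_ji = _topk_mask(cos_ij.T, top_k)
    att_i, alpha_ij = _attend(states_i, states_j, mask_ij, params)
    att_j, alpha_ji = _attend(states_j, states_i, mask_ji, params)
    pooled = ad.concatenate([ad.amean(att_i, axis=0, keepdims=True),
                             ad.amean(att_j, axis=0, keepdims=True)], axis=1)
    pooled = ad.reshape(pooled, (-1,))
    return PairRepresentation(
        drug_pair=tuple(drug_pair), node_states_i=states_i,
        node_states_j=states_j, cross_attention_weights=alpha_ij,
        cross_attention_weights_ji=alpha_ji, pooled=pooled)


def candidate_prefilter(embeddings: np.ndarray, k: int) -> np.ndarray:
    """Nearest-neighbour pre-filter for large-scale pair screening.

    Returns, per drug, the indices of its k most cosine-similar other
    drugs (ties toward the lower index); candidate pairs from this list
    can then go through the full cross-attention scoring.
    """
    z = np.asarray(value(embeddings), dtype=np.float64)
    n = z.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError("k must lie in [1, N-1]")
    cos = _cosine_table(z, z)
    np.fill_diagonal(cos, -np.inf)
    order = np.argsort(-cos, axis=1, kind="stable")
    return order[:, :k]


def pair_score(z_i, z_j, pooled, head: PairHeadParams):
    """Symmetrized logistic MLP score for a drug pair.

    score = logistic(MLP([z_i || z_j || z_i * z_j || pooled])), averaged
    with the role-swapped evaluation so score(i, j) = score(j, i) exactly.
    ``pooled`` may be None when no substructure states are available.
    """
    def one_dir(za, zb, pool):
        feats = [ad.reshape(za, (1, -1)), ad.reshape(zb, (1, -1)),
                 ad.reshape(ad.mul(za, zb), (1, -1))]
        if pool is not None:
            feats.append(ad.reshape(pool, (1, -1)))
        x = ad.concatenate(feats, axis=1)
        hidden = ad.relu(ad.add(ad.matmul(x, head.w1), head.b1))
        out = ad.add(ad.matmul(hidden, head.w2), head.b2)
        return ad.sigmoid(out)

    pooled_swapped = None
    if pooled is not None:
        p = value(pooled)
        half = p.size // 2
        pooled_swapped = ad.concatenate(
            [ad.take(ad.reshape(pooled, (-1, 1)), np.arange(half, p.size)),
             ad.take(ad.reshape(pooled, (-1, 1)), np.arange(half))], axis=0)
        pooled_swapped = ad.reshape(pooled_swapped, (-1,))
    s_ij = one_dir(z_i, z_j, pooled)
    s_ji = one_dir(z_j, z_i, pooled_swapped)
    return ad.reshape(ad.div(ad.add(s_ij, s_ji), 2.0), ())
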