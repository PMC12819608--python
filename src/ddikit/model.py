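"""The joint interaction model: multimodal fusion, graph attention
encoding, per-modality embeddings, and the pairwise scoring head.

The model holds every trainable parameter as a :class:`~ddikit.autodiff.Tensor`
and assembles the joint objective

    L = [ L_ctr + lambda1 L_sim + lambda2 L_sup ]
      + [ a1 L_ctx + a2 L_lap + a3 L_co + a4 L_mmd + a5 L_rank + a6 L_ent ]
      + w_pair * BCE(pair scores, pair labels)

where the bracketed groups are the embedding objective and the
knowledge-alignment suite.  Each component is normalized by its term
count before weighting so the default weights keep terms on comparable
scales (the un-normalized printed formulas live in :mod:`ddikit.losses`).

Fusion weights lambda are parameterized by a softmax over unconstrained
logits, so the simplex constraint holds at every optimisation step; the
relational graph is rebuilt from the current fused similarity at a
configurable epoch interval (its edges are discrete and carry no
gradient — lambda learns through the similarity-preservation term).

Per-modality embeddings Z^(m) (used by the distribution-alignment term
and as the token set of the cross-attention pair head) are obtained by
encoding the feature matrix with all other modality blocks zeroed,
through the shared encoder.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import autodiff as ad
from . import losses as L
from .autodiff import value
from .encoders import (CrossAttentionParams, EncoderParams, PairHeadParams,
                       forward_encoder, _topk_mask, _cosine_table)
from .losses import LossWeights, TripletBatch
from .similarity import (KnowledgeContext, CoPrescriptionData,
                         UnifiedTopology, knn_sparsify, threshold_adjacency)

__all__ = ["InteractionModel"]


class InteractionModel:
    """Trainable drug-pair interaction model over a multimodal cohort.

    Parameters
    ----------
    features : (N, F) array
        Concatenated multimodal feature matrix.
    modality_slices : list of slice
        Column blocks, one per modality.
    sim_matrices : list of (N, N) arrays
        Per-modality similarity matrices S^(m).
    context : KnowledgeContext
    coprescription : CoPrescriptionData
    topology : UnifiedTopology
    class_labels : (N,) int array
        Per-drug class (therapeutic-context) labels for the supervised term.
    """

    def __init__(self, features, modality_slices, sim_matrices,
                 context: KnowledgeContext,
                 coprescription: CoPrescriptionData,
                 topology: UnifiedTopology,
                 class_labels, n_classes: int | None = None,
                 hidden_dim: int = 256, n_heads: int = 8, n_layers: int = 3,
                 dropout: float = 0.1, top_k: int = 8,
                 knn_k: int | None = 10, epsilon: float | None = None,
                 sim_mode: str = "cosine",
                 loss_weights: LossWeights = LossWeights(),
                 pair_loss_weight: float = 1.0,
                 seed: int = 0,
                 disable_multimodal_fusion: bool = False,
                 disable_attention_propagation: bool = False,
                 disable_contrastive: bool = False):
        self.x = np.asarray(features, dtype=np.float64)
        self.slices = list(modality_slices)
        self.sims = [np.asarray(s, dtype=np.float64) for s in sim_matrices]
        self.context = context
        self.coprescription = coprescription
        self.topology = topology
        self.y = np.asarray(class_labels, dtype=int)
        self.n_classes = (int(self.y.max()) + 1 if n_classes is None
                          else int(n_classes))
        self.n_drugs, self.n_features = self.x.shape
        self.n_modalities = len(self.slices)
        self.hidden_dim = hidden_dim
        self.dropout = dropout
        self.top_k = top_k
        self.knn_k = knn_k
        self.epsilon = epsilon
        self.sim_mode = sim_mode
        self.weights = loss_weights
        self.pair_loss_weight = pair_loss_weight
        self.no_msi = disable_multimodal_fusion
        self.no_gbap = disable_attention_propagation
        self.no_cmrg = disable_contrastive
        self.seed = seed

        rng = np.random.default_rng(seed)
        d = hidden_dim
        sw_in = np.sqrt(2.0 / (self.n_features + d))
        self.params: dict[str, ad.Tensor] = {
            "fusion_logits": ad.parameter(np.zeros(self.n_modalities)),
            "w_in": ad.parameter(rng.normal(0, sw_in,
                                            size=(self.n_features, d))),
            "hop_weights": ad.parameter(np.full(n_layers, 1.0 / n_layers)),
            "w_class": ad.parameter(rng.normal(0, np.sqrt(1.0 / d),
                                               size=(self.n_classes, d))),
        }
        self.encoder = EncoderParams(
            layer_transforms=[[ad.parameter(rng.normal(0, np.sqrt(1.0 / d),
                                                       size=(d, d)))
                               for _ in range(n_heads)]
                              for _ in range(n_layers)],
            attention_vectors=[[ad.parameter(rng.normal(0, 0.1,
                                                        size=(2 * d,)))
                                for _ in range(n_heads)]
                               for _ in range(n_layers)],
            hop_weights=self.params["hop_weights"],
            n_layers=n_layers, hidden_dim=d, n_heads=n_heads)
        for k in range(n_layers):
            for h in range(n_heads):
                self.params[f"gat{k}h{h}_w"] = self.encoder.layer_transforms[k][h]
                self.params[f"gat{k}h{h}_a"] = self.encoder.attention_vectors[k][h]
        sw = np.sqrt(1.0 / d)
        self.cross = CrossAttentionParams(
            wq=[ad.parameter(rng.normal(0, sw, size=(d, d)))
                for _ in range(n_heads)],
            wk=[ad.parameter(rng.normal(0, sw, size=(d, d)))
                for _ in range(n_heads)],
            wv=[ad.parameter(rng.normal(0, sw, size=(d, d)))
                for _ in range(n_heads)])
        for h in range(n_heads):
            self.params[f"cross_wq{h}"] = self.cross.wq[h]
            self.params[f"cross_wk{h}"] = self.cross.wk[h]
            self.params[f"cross_wv{h}"] = self.cross.wv[h]
        feat_dim = 3 * d + 2 * d   # [z_i || z_j || z_i*z_j || pooled]
        sw1 = np.sqrt(2.0 / (feat_dim + d))
        self.pair_head = PairHeadParams(
            w1=ad.parameter(rng.normal(0, sw1, size=(feat_dim, d))),
            b1=ad.parameter(np.zeros(d)),
            w2=ad.parameter(rng.normal(0, np.sqrt(1.0 / d), size=(d, 1))),
            b2=ad.parameter(np.zeros(1)))
        self.params["pair_w1"] = self.pair_head.w1
        self.params["pair_b1"] = self.pair_head.b1
        self.params["pair_w2"] = self.pair_head.w2
        self.params["pair_b2"] = self.pair_head.b2

        self._adjacency = None
        self._cache_version = 0
        self._cache: dict = {}
        self.refresh_graph()

    # -- parameters ------------------------------------------------------

    def trainable_params(self) -> dict[str, ad.Tensor]:
        out = dict(self.params)
        if self.no_msi:
            out.pop("fusion_logits")        # lambda frozen uniform
            for h in range(self.cross.n_heads):
                out.pop(f"cross_wq{h}")     # attention head replaced by
                out.pop(f"cross_wk{h}")     # plain concatenation
                out.pop(f"cross_wv{h}")
        return out

    def invalidate_cache(self):
        """Embedding cache is keyed on a version bumped at each update."""
        self._cache_version += 1
        self._cache.clear()

    # -- fusion and graph -------------------------------------------------

    def fusion_weights(self):
        """Simplex weights lambda (Tensor unless fusion is frozen)."""
        if self.no_msi:
            return np.full(self.n_modalities, 1.0 / self.n_modalities)
        logits = self.params["fusion_logits"]
        shift = value(logits).max()
        e = ad.exp(ad.sub(logits, shift))
        return ad.div(e, ad.asum(e))

    def fused_similarity(self):
        """Convex fusion of the per-modality similarities (traceable)."""
        lam = self.fusion_weights()
        if isinstance(lam, ad.Tensor):
            lam2 = ad.reshape(lam, (-1, 1))
            fused = ad.mul(ad.take(lam2, [0]), self.sims[0])
            for m in range(1, self.n_modalities):
                fused = ad.add(fused, ad.mul(ad.take(lam2, [m]), self.sims[m]))
            return fused
        return sum(w * s for w, s in zip(lam, self.sims))

    def refresh_graph(self):
        """Rebuild the relational graph from the current fused similarity."""
        fused = value(self.fused_similarity())
        if self.epsilon is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                graph = threshold_adjacency(fused, self.epsilon)
        else:
            k = self.knn_k if self.knn_k is not None else 10
            graph = knn_sparsify(fused, min(k, self.n_drugs - 1))
        self._adjacency = graph.adjacency
        self.invalidate_cache()
        return graph

    # -- encoding ----------------------------------------------------------

    def encode(self, rng=None, train: bool = False):
        """Encode the cohort: full embeddings plus per-modality embeddings.

        Returns a dict with the full :class:`EmbeddingState` under
        ``"state"``, the final embedding matrix under ``"z"`` and the list
        of per-modality finals under ``"z_mod"``.
        """
        if not train and self._cache_version in self._cache:
            return self._cache[self._cache_version]
        dropout_p = self.dropout if train else 0.0
        h0 = ad.matmul(self.x, self.params["w_in"])
        state = forward_encoder(h0, self._adjacency, self.encoder,
                                dropout_p=dropout_p, rng=rng,
                                attention=not self.no_gbap)
        z_mod = []
        for sl in self.slices:
            xm = np.zeros_like(self.x)
            xm[:, sl] = self.x[:, sl]
            h0m = ad.matmul(xm, self.params["w_in"])
            st = forward_encoder(h0m, self._adjacency, self.encoder,
                                 dropout_p=dropout_p, rng=rng,
                                 attention=not self.no_gbap)
            z_mod.append(st.final)
        out = {"state": state, "z": state.final, "z_mod": z_mod}
        if not train:
            self._cache[self._cache_version] = out
        return out

    # -- pair head ---------------------------------------------------------

    def _modality_tokens(self, z_mod, idx):
        """(B, M, d) token stacks for the drugs in ``idx``."""
        parts = []
        for zm in z_mod:
            t = ad.take(zm, idx)                       # (B, d)
            parts.append(ad.reshape(t, (len(idx), 1, self.hidden_dim)))
        return ad.concatenate(parts, axis=1)

    def pair_scores(self, pairs, encoded):
        """Symmetrized interaction probabilities for an array of pairs.

        ``pairs`` is an (B, 2) integer array of drug indices.  The pooled
        pair context comes from cross-attention over each drug's modality
        tokens (or their plain mean concatenation when multimodal fusion
        is disabled).
        """
        pairs = np.asarray(pairs, dtype=int)
        i_idx, j_idx = pairs[:, 0], pairs[:, 1]
        z = encoded["z"]
        zi, zj = ad.take(z, i_idx), ad.take(z, j_idx)
        ti = self._modality_tokens(encoded["z_mod"], i_idx)
        tj = self._modality_tokens(encoded["z_mod"], j_idx)
        if self.no_msi:
            pool_i = ad.amean(ti, axis=1)
            pool_j = ad.amean(tj, axis=1)
        else:
            pool_i = self._cross_attend(ti, tj)
            pool_j = self._cross_attend(tj, ti)

        def one_dir(za, zb, pa, pb):
            x = ad.concatenate([za, zb, ad.mul(za, zb), pa, pb], axis=1)
            hidden = ad.relu(ad.add(ad.matmul(x, self.pair_head.w1),
                                    self.pair_head.b1))
            out = ad.add(ad.matmul(hidden, self.pair_head.w2),
                         self.pair_head.b2)
            return ad.sigmoid(ad.reshape(out, (-1,)))

        s_ij = one_dir(zi, zj, pool_i, pool_j)
        s_ji = one_dir(zj, zi, pool_j, pool_i)
        return ad.div(ad.add(s_ij, s_ji), 2.0)

    def _cross_attend(self, tq, tkv):
        """Batched masked cross-attention over modality tokens -> (B, d)."""
        b, m, d = value(tq).shape
        k_eff = min(self.top_k, m)
        if k_eff >= m:
            mask = np.ones((b, m, m))
        else:
            tq_d, tkv_d = value(tq), value(tkv)
            nq = tq_d / np.maximum(np.linalg.norm(tq_d, axis=2,
                                                  keepdims=True), 1e-300)
            nk = tkv_d / np.maximum(np.linalg.norm(tkv_d, axis=2,
                                                   keepdims=True), 1e-300)
            cos = np.einsum("bmd,bnd->bmn", nq, nk)
            order = np.argsort(-cos, axis=2, kind="stable")[:, :, :k_eff]
            mask = np.zeros_like(cos)
            np.put_along_axis(mask, order, 1.0, axis=2)
        outs = None
        for h in range(self.cross.n_heads):
            q = ad.matmul(tq, self.cross.wq[h])
            kk = ad.matmul(tkv, self.cross.wk[h])
            v = ad.matmul(tkv, self.cross.wv[h])
            logits = ad.div(ad.matmul(q, ad.transpose(kk, (0, 2, 1))),
                            float(np.sqrt(d)))
            alpha = ad.masked_softmax(logits, mask, axis=2)
            att = ad.matmul(alpha, v)
            outs = att if outs is None else ad.add(outs, att)
        outs = ad.div(outs, float(self.cross.n_heads))
        return ad.amean(outs, axis=1)

    # -- objective ---------------------------------------------------------

    def objective(self, pair_idx, pair_labels, triplets: TripletBatch,
                  rank_triplets: TripletBatch, rng=None, train: bool = True):
        """Assemble the joint loss; returns (total, component dict).

        Components are normalized by term counts (see module docstring);
        the dict holds plain floats for logging.
        """
        n = self.n_drugs
        enc = self.encode(rng=rng, train=train)
        z = enc["z"]
        comps: dict[str, float] = {}

        fused = self.fused_similarity()
        l_sim = ad.div(L.similarity_preserving(z, fused, mode=self.sim_mode),
                       float(n * (n - 1)))
        l_sup = L.supervised_ce(z, self.params["w_class"], self.y)
        if self.no_cmrg or len(triplets) == 0:
            l_ctr = 0.0
        else:
            l_ctr = ad.div(L.contrastive_triplet(z, triplets),
                           float(len(triplets)))
        embedding_total = L.embedding_objective(l_ctr, l_sim, l_sup, self.weights)

        l_ctx = ad.div(L.context_alignment(z, self.context),
                       float(n * (n - 1) * self.context.n_contexts))
        l_lap = ad.div(L.laplacian_smoothness(z, self.topology), float(n * n))
        l_co = ad.div(L.coprescription_kl(z, self.coprescription), float(n))
        if self.no_cmrg:
            l_mmd, l_rank, l_ent = 0.0, 0.0, 0.0
        else:
            l_mmd = L.mmd_alignment(enc["z_mod"],
                                    bandwidth=self.weights.mmd_bandwidth)
            l_rank = (ad.div(L.margin_ranking(z, rank_triplets,
                                              self.weights.ranking_margin),
                             float(max(1, len(rank_triplets))))
                      if len(rank_triplets) else 0.0)
            yhat = _softmax_rows_t(ad.matmul(z, ad.transpose(
                self.params["w_class"])))
            l_ent = ad.div(L.entropy_regularizer(yhat), float(n))
        alignment_total = L.alignment_objective(
            (l_ctx, l_lap, l_co, l_mmd, l_rank, l_ent), self.weights)

        scores = self.pair_scores(pair_idx, enc)
        yb = np.asarray(pair_labels, dtype=np.float64)
        s = ad.clip(scores, L.PROB_EPS, 1.0 - L.PROB_EPS)
        bce = ad.neg(ad.amean(ad.add(ad.mul(yb, ad.log(s)),
                                     ad.mul(1.0 - yb, ad.log(ad.sub(1.0, s))))))
        total = ad.add(ad.add(embedding_total, alignment_total),
                       ad.mul(self.pair_loss_weight, bce))

        for name, v in [("ctr", l_ctr), ("sim", l_sim), ("sup", l_sup),
                        ("ctx", l_ctx), ("lap", l_lap), ("co", l_co),
                        ("mmd", l_mmd), ("rank", l_rank), ("ent", l_ent),
                        ("pair_bce", bce), ("total", total)]:
            comps[name] = float(value(v))
            if not np.isfinite(comps[name]):
                raise FloatingPointError(
                    f"loss component {name!r} diverged (non-finite)")
        return total, comps

    def predict_pairs(self, pairs) -> np.ndarray:
        """Interaction probabilities in [0, 1] for an (B, 2) index array."""
        enc = self.encode(train=False)
        return value(self.pair_scores(pairs, enc))

    def embeddings(self) -> np.ndarray:
        return value(self.encode(train=False)["z"])

    # -- persistence --------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: np.array(p.data) for k, p in self.params.items()}

    def load_state_dict(self, state: dict):
        for k, p in self.params.items():
            p.data = np.array(state[k], dtype=np.float64)
        self.refresh_graph()


def _softmax_rows_t(logits):
    shift = value(logits).max(axis=-1, keepdims=True)
    e = ad.exp(ad.sub(logits, shift))
    return ad.div(e, ad.asum(e, axis=-1, keepdims=True))
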