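"""Encoder layers checked against independent scalar-loop references:
mean aggregation, attention coefficients, full attention layers, multi-hop
combination, molecular pooling, cross-attention masking and pair scoring."""

import numpy as np
import pytest

from ddikit import autodiff as ad
from ddikit.autodiff import value
from ddikit.encoders import (CrossAttentionParams, EncoderParams,
                             PairHeadParams, attention_coefficients,
                             cross_attention_pair, encode_molecule,
                             forward_encoder, gat_layer,
                             global_attention_pool, mean_aggregate_layer,
                             multi_hop_aggregate, pair_score,
                             MolecularEncoderParams, _row_normalize)
from ddikit.synthetic import generate_molecular_toys

RNG = np.random.default_rng(21)


def _random_graph(n, p=0.5, ensure_edge=True):
    a = (RNG.random((n, n)) < p).astype(float)
    a = np.triu(a, 1)
    a = a + a.T
    if ensure_edge:
        a[0, 1] = a[1, 0] = 1.0
    return a


# ---------------------------------------------------------------------
# mean aggregation
# ---------------------------------------------------------------------

def test_mean_aggregation_hand_example():
    # node 0 has neighbours with states (1,0) and (0,1) -> (0.5, 0.5)
    a = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=float)
    h = np.array([[9.0, 9.0], [1.0, 0.0], [0.0, 1.0]])
    out = mean_aggregate_layer(h, a, np.eye(2), activation="identity")
    assert np.allclose(out[0], [0.5, 0.5])


def test_mean_aggregation_edgeless_self_loop_fallback():
    h = RNG.normal(size=(4, 3))
    out = mean_aggregate_layer(h, np.zeros((4, 4)), np.eye(3),
                               activation="identity")
    assert np.allclose(out, h)


def test_mean_aggregation_matches_double_loop():
    n, d = 6, 4
    a = _random_graph(n)
    h = RNG.normal(size=(n, d))
    w = RNG.normal(size=(d, d))
    out = mean_aggregate_layer(h, a, w, activation="relu")
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j] > 0] or [i]
        acc = np.zeros(d)
        for j in nbrs:
            acc += w.T @ h[j]
        expect = np.maximum(acc / len(nbrs), 0.0)
        assert np.allclose(out[i], expect, atol=1e-10)


# ---------------------------------------------------------------------
# attention coefficients
# ---------------------------------------------------------------------

def test_identical_states_give_uniform_attention():
    n, d = 5, 3
    a = _random_graph(n)
    h = np.tile(RNG.normal(size=(1, d)), (n, 1))
    w = RNG.normal(size=(d, d))
    av = RNG.normal(size=2 * d)
    alpha = attention_coefficients(h, a, w, av)
    for i in range(n):
        nbrs = a[i] > 0
        if nbrs.sum():
            assert np.allclose(alpha[i, nbrs], 1.0 / nbrs.sum(), atol=1e-12)


def test_single_neighbor_gets_full_attention():
    a = np.array([[0, 1], [1, 0]], dtype=float)
    h = RNG.normal(size=(2, 3))
    alpha = attention_coefficients(h, a, RNG.normal(size=(3, 3)),
                                   RNG.normal(size=6))
    assert alpha[0, 1] == pytest.approx(1.0)
    assert alpha[1, 0] == pytest.approx(1.0)


def test_attention_matches_scalar_softmax_loop():
    n, d = 5, 3
    a = _random_graph(n)
    h = RNG.normal(size=(n, d))
    w = RNG.normal(size=(d, d))
    av = RNG.normal(size=2 * d)
    alpha = attention_coefficients(h, a, w, av, leaky_slope=0.2)
    wh = h @ w
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j] > 0] or [i]
        logits = []
        for j in nbrs:
            cat = np.concatenate([wh[i], wh[j]])
            x = float(av @ cat)
            logits.append(x if x > 0 else 0.2 * x)
        e = np.exp(np.array(logits) - max(logits))
        expect = e / e.sum()
        assert np.allclose(alpha[i, nbrs], expect, atol=1e-10)
        assert alpha[i].sum() == pytest.approx(1.0, abs=1e-6)


def test_attention_reports_nonfinite_input():
    h = np.array([[1.0, np.nan], [0.0, 1.0]])
    with pytest.raises(FloatingPointError, match="index 0"):
        attention_coefficients(h, np.ones((2, 2)) - np.eye(2),
                               np.eye(2), np.ones(4))


# ---------------------------------------------------------------------
# full attention layer
# ---------------------------------------------------------------------

def _params(d, n_layers=1, n_heads=1, seed=0):
    return EncoderParams.initialize(d, d, n_layers, n_heads, seed=seed)


def test_row_normalization_contract():
    out = value(_row_normalize(np.array([[3.0, 4.0]]), 0.0))
    assert np.allclose(out, [[0.6, 0.8]])
    h = RNG.normal(size=(6, 4))
    norms = np.linalg.norm(value(_row_normalize(h, 1e-8)), axis=1)
    assert np.all(norms > 1 - 1e-3) and np.all(norms <= 1.0 + 1e-9)


def test_gat_layer_matches_loop_reference():
    n, d = 6, 3
    a = _random_graph(n)
    h = RNG.normal(size=(n, d))
    p = _params(d, seed=3)
    out, alpha = gat_layer(h, a, p, 0, activation="identity",
                           residual=False)
    # independent scalar reference
    w = value(p.layer_transforms[0][0])
    wh = h @ w
    alpha_ref = attention_coefficients(h, a, w,
                                       value(p.attention_vectors[0][0]))
    for i in range(n):
        acc = np.zeros(d)
        for j in range(n):
            acc += alpha_ref[i, j] * wh[j]
        expect = acc / (np.linalg.norm(acc) + p.stability_eps)
        assert np.allclose(out[i], expect, atol=1e-8)
    assert np.allclose(alpha.sum(axis=1), 1.0, atol=1e-6)


def test_gat_residual_requires_matching_dims():
    n, d = 4, 3
    a = _random_graph(n)
    h = RNG.normal(size=(n, d))
    p = _params(d)
    with pytest.raises(ValueError):
        gat_layer(h, a, p, 0, h0=RNG.normal(size=(n, d + 1)))


def test_multi_hop_examples_and_loop():
    states = [RNG.normal(size=(4, 3)) for _ in range(3)]
    assert np.allclose(multi_hop_aggregate(states, [1.0, 0.0, 0.0]),
                       states[0])
    assert np.allclose(multi_hop_aggregate(states, [0.0, 0.0, 0.0]), 0.0)
    g = RNG.normal(size=3)
    out = multi_hop_aggregate(states, g)
    expect = np.zeros((4, 3))
    for k in range(3):
        expect += g[k] * states[k]
    assert np.allclose(out, expect, atol=1e-12)
    with pytest.raises(ValueError):
        multi_hop_aggregate(states, [1.0, 2.0])


def test_forward_encoder_permutation_equivariance():
    """Relabelling drugs permutes embeddings identically."""
    n, d = 7, 4
    a = _random_graph(n)
    h = RNG.normal(size=(n, d))
    p = _params(d, n_layers=2, seed=5)
    perm = RNG.permutation(n)
    base = forward_encoder(h, a, p).final
    permuted = forward_encoder(h[perm], a[np.ix_(perm, perm)], p).final
    assert np.allclose(value(base)[perm], value(permuted), atol=1e-10)


def test_forward_pass_bit_reproducible_with_seeded_dropout():
    n, d = 6, 4
    a = _random_graph(n)
    h = RNG.normal(size=(n, d))
    p = _params(d, n_layers=2, seed=1)
    z1 = value(forward_encoder(h, a, p, dropout_p=0.2,
                               rng=np.random.default_rng(9)).final)
    z2 = value(forward_encoder(h, a, p, dropout_p=0.2,
                               rng=np.random.default_rng(9)).final)
    assert np.array_equal(z1, z2)


# ---------------------------------------------------------------------
# molecular encoder
# ---------------------------------------------------------------------

def test_pooling_single_atom_and_uniform_scores():
    h = RNG.normal(size=(1, 4))
    assert np.allclose(global_attention_pool(h, RNG.normal(size=4)), h[0])
    h = RNG.normal(size=(5, 4))
    # zero scoring vector -> uniform weights -> mean of atom states
    assert np.allclose(global_attention_pool(h, np.zeros(4)), h.mean(axis=0))


def test_molecular_encoding_is_permutation_invariant():
    toys = generate_molecular_toys(4, size_range=(5, 12), seed=8)
    params = MolecularEncoderParams.initialize(d=8, seed=2)
    rng = np.random.default_rng(0)
    for toy in toys:
        base = encode_molecule(toy, params)
        perm = rng.permutation(toy.n_atoms)
        inv = np.argsort(perm)
        relabeled = type(toy)(
            drug_id=toy.drug_id,
            atom_labels=[toy.atom_labels[perm[i]]
                         for i in range(toy.n_atoms)],
            bond_list=sorted((min(inv[u], inv[v]), max(inv[u], inv[v]), b)
                             for u, v, b in toy.bond_list))
        assert np.allclose(encode_molecule(relabeled, params), base,
                           atol=1e-6)


def test_molecular_encoding_fixed_length_and_deterministic():
    toys = generate_molecular_toys(3, size_range=(2, 20), seed=1)
    params = MolecularEncoderParams.initialize(d=8, seed=0)
    outs = [encode_molecule(t, params) for t in toys]
    assert all(o.shape == (8,) for o in outs)
    assert np.array_equal(outs[0], encode_molecule(toys[0], params))


# ---------------------------------------------------------------------
# cross-attention pair head
# ---------------------------------------------------------------------

def test_topk_at_least_n_equals_unmasked():
    hi, hj = RNG.normal(size=(3, 4)), RNG.normal(size=(5, 4))
    p = CrossAttentionParams.initialize(4, n_heads=2, seed=0)
    full = cross_attention_pair(hi, hj, top_k=5, params=p)
    with pytest.warns(UserWarning):
        clamped = cross_attention_pair(hi, hj, top_k=99, params=p)
    assert np.allclose(value(full.pooled), value(clamped.pooled))
    assert np.allclose(full.cross_attention_weights.sum(axis=1), 1.0,
                       atol=1e-6)


def test_topk_masking_matches_cosine_argmax_loop():
    hi, hj = RNG.normal(size=(3, 4)), RNG.normal(size=(2, 4))
    p = CrossAttentionParams.initialize(4, seed=1)
    rep = cross_attention_pair(hi, hj, top_k=1, params=p)
    for u in range(3):
        cos = [hi[u] @ hj[v] / (np.linalg.norm(hi[u]) * np.linalg.norm(hj[v]))
               for v in range(2)]
        keep = int(np.argmax(cos))
        assert rep.cross_attention_weights[u, keep] == pytest.approx(1.0)
        assert rep.cross_attention_weights[u, 1 - keep] == 0.0


def test_identical_states_shared_params_give_symmetric_attention():
    h = RNG.normal(size=(4, 4))
    p = CrossAttentionParams.initialize(4, seed=2, symmetric=True)
    rep = cross_attention_pair(h, h, top_k=2, params=p)
    assert np.allclose(rep.cross_attention_weights,
                       rep.cross_attention_weights_ji, atol=1e-6)


def test_candidate_prefilter_matches_brute_force_cosine():
    from ddikit.encoders import candidate_prefilter
    z = RNG.normal(size=(7, 5))
    got = candidate_prefilter(z, k=3)
    zn = z / np.linalg.norm(z, axis=1, keepdims=True)
    cos = zn @ zn.T
    for i in range(7):
        others = sorted((j for j in range(7) if j != i),
                        key=lambda j: (-cos[i, j], j))
        assert list(got[i]) == others[:3]
    with pytest.raises(ValueError):
        candidate_prefilter(z, k=7)


def test_pair_score_symmetry_and_zero_head():
    d = 4
    zi, zj = RNG.normal(size=d), RNG.normal(size=d)
    pooled = RNG.normal(size=2 * d)
    head = PairHeadParams.initialize(3 * d + 2 * d, hidden=5, seed=0)
    s_ij = float(value(pair_score(zi, zj, pooled, head)))
    s_ji = float(value(pair_score(zj, zi,
                                  np.concatenate([pooled[d:], pooled[:d]]),
                                  head)))
    assert s_ij == pytest.approx(s_ji, abs=1e-15)
    assert 0.0 < s_ij < 1.0
    zero_head = PairHeadParams(w1=np.zeros((5 * d, 3)), b1=np.zeros(3),
                               w2=np.zeros((3, 1)), b2=np.array([0.7]))
    s = float(value(pair_score(zi, zj, pooled, zero_head)))
    assert s == pytest.approx(1.0 / (1.0 + np.exp(-0.7)), abs=1e-12)


def test_pair_score_matches_loop_forward():
    d = 3
    zi, zj = RNG.normal(size=d), RNG.normal(size=d)
    pooled = RNG.normal(size=2 * d)
    head = PairHeadParams.initialize(5 * d, hidden=4, seed=5)

    def manual(za, zb, pool):
        x = np.concatenate([za, zb, za * zb, pool])
        hidden = np.maximum(x @ head.w1 + head.b1, 0.0)
        logit = float((hidden @ head.w2 + head.b2)[0])
        return 1.0 / (1.0 + np.exp(-logit))

    expect = 0.5 * (manual(zi, zj, pooled)
                    + manual(zj, zi, np.concatenate([pooled[d:], pooled[:d]])))
    got = float(value(pair_score(zi, zj, pooled, head)))
    assert got == pytest.approx(expect, abs=1e-12)
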