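"""Every loss term checked against its closed-form hand value and an
independent scalar-loop evaluation, plus structural identities (trace
forms, scale equivariance, non-negativity where guaranteed)."""

import numpy as np
import pytest

from ddikit import autodiff as ad
from ddikit.autodiff import value
from ddikit.losses import (LossWeights, TripletBatch, contrastive_triplet,
                           context_alignment, context_contrastive,
                           coprescription_kl, embedding_objective,
                           entropy_regularizer, alignment_objective,
                           laplacian_smoothness, margin_ranking,
                           mmd_alignment, similarity_preserving, softplus,
                           supervised_ce)
from ddikit.similarity import (context_comembership,
                               coprescription_probabilities,
                               unified_topology, SimilarityStack)

RNG = np.random.default_rng(33)


def _sym(n):
    m = RNG.random((n, n))
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 1.0)
    return m


# ---------------------------------------------------------------------
# contrastive triplet
# ---------------------------------------------------------------------

def test_contrastive_zero_embeddings_is_two_ln_two_per_anchor():
    z = np.zeros((6, 4))
    batch = TripletBatch(anchors=[0, 1], positives=[2, 3], negatives=[4, 5])
    val = float(value(contrastive_triplet(z, batch)))
    assert val / len(batch) == pytest.approx(2 * np.log(2), abs=1e-12)


def test_contrastive_vanishes_in_the_separated_limit():
    z = np.zeros((3, 2))
    z[0] = [20.0, 0.0]
    z[1] = [20.0, 0.0]      # positive: huge inner product
    z[2] = [-20.0, 0.0]     # negative: hugely negative inner product
    batch = TripletBatch(anchors=[0], positives=[1], negatives=[2])
    assert float(value(contrastive_triplet(z, batch))) < 1e-8


def test_contrastive_matches_scalar_loop():
    z = RNG.normal(size=(8, 3))
    batch = TripletBatch(anchors=[0, 2, 4, 6, 1],
                         positives=[1, 3, 5, 7, 6],
                         negatives=[7, 0, 2, 4, 3])
    expect = 0.0
    for a, p, n in zip(batch.anchors, batch.positives, batch.negatives):
        sp = float(np.clip(z[a] @ z[p], -30, 30))
        sn = float(np.clip(z[a] @ z[n], -30, 30))
        expect += np.log(1 + np.exp(sn)) - np.log(1 / (1 + np.exp(-sp)))
    assert float(value(contrastive_triplet(z, batch))) == pytest.approx(
        expect, abs=1e-10)


def test_empty_batch_warns_and_is_zero():
    batch = TripletBatch(anchors=[], positives=[], negatives=[])
    with pytest.warns(UserWarning):
        assert float(value(contrastive_triplet(np.ones((2, 2)), batch))) == 0


def test_triplet_batch_rejects_collisions():
    with pytest.raises(ValueError):
        TripletBatch(anchors=[0], positives=[0], negatives=[1])


def test_softplus_identity():
    x = RNG.normal(size=7)
    # softplus(x) = -ln sigmoid(-x)
    assert np.allclose(value(softplus(x)),
                       -np.log(1 / (1 + np.exp(x))), atol=1e-12)


# ---------------------------------------------------------------------
# similarity preservation
# ---------------------------------------------------------------------

def test_similarity_preserving_zero_cases():
    z = np.tile(RNG.normal(size=(1, 3)), (4, 1))
    s_unit = np.ones((4, 4))
    assert float(value(similarity_preserving(z, s_unit, "cosine"))) == \
        pytest.approx(0.0, abs=1e-18)
    assert float(value(similarity_preserving(z, _sym(4), "sqdist"))) == \
        pytest.approx(0.0, abs=1e-18)


def test_similarity_preserving_matches_loops():
    z = RNG.normal(size=(4, 3))
    s = _sym(4)
    sq, cs = 0.0, 0.0
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            sq += s[i, j] * np.sum((z[i] - z[j]) ** 2)
            cos = z[i] @ z[j] / (np.linalg.norm(z[i]) * np.linalg.norm(z[j]))
            cs += (s[i, j] - cos) ** 2
    assert float(value(similarity_preserving(z, s, "sqdist"))) == \
        pytest.approx(sq, abs=1e-10)
    assert float(value(similarity_preserving(z, s, "cosine"))) == \
        pytest.approx(cs, abs=1e-10)


# ---------------------------------------------------------------------
# supervised CE and entropy
# ---------------------------------------------------------------------

def test_uniform_predictions_give_ln_c():
    z = np.zeros((5, 3))            # zero logits -> uniform softmax
    w_c = np.zeros((2, 3))
    labels = np.array([0, 1, 0, 1, 1])
    assert float(value(supervised_ce(z, w_c, labels))) == pytest.approx(
        np.log(2), abs=1e-12)


def test_perfect_predictions_give_zero():
    w_c = np.array([[40.0, 0.0], [0.0, 40.0]])
    z = np.array([[1.0, 0.0], [0.0, 1.0]])
    labels = np.array([0, 1])
    assert float(value(supervised_ce(z, w_c, labels))) == pytest.approx(
        0.0, abs=1e-9)
    with pytest.raises(ValueError):
        supervised_ce(z, w_c, np.array([0, 2]))


def test_supervised_ce_matches_loop():
    z = RNG.normal(size=(6, 4))
    w_c = RNG.normal(size=(3, 4))
    labels = RNG.integers(0, 3, size=6)
    logits = z @ w_c.T
    expect = 0.0
    for i in range(6):
        e = np.exp(logits[i] - logits[i].max())
        p = e / e.sum()
        expect -= np.log(p[labels[i]])
    assert float(value(supervised_ce(z, w_c, labels))) == pytest.approx(
        expect / 6, abs=1e-10)


def test_entropy_regularizer_closed_forms_and_loop():
    n, c = 5, 3
    uniform = np.full((n, c), 1.0 / c)
    assert float(value(entropy_regularizer(uniform))) == pytest.approx(
        n * np.log(c), abs=1e-12)
    onehot = np.eye(c)[RNG.integers(0, c, size=n)]
    assert float(value(entropy_regularizer(onehot))) == pytest.approx(
        0.0, abs=1e-9)
    logits = RNG.normal(size=(n, c))
    y = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
    expect = -sum(y[i, k] * np.log(y[i, k]) for i in range(n)
                  for k in range(c))
    assert float(value(entropy_regularizer(y))) == pytest.approx(
        expect, abs=1e-10)


# ---------------------------------------------------------------------
# weighted totals
# ---------------------------------------------------------------------

def test_totals_are_plain_weighted_sums():
    w = LossWeights(embedding=(0.0, 0.0))
    assert float(value(embedding_objective(1.7, 5.0, 9.0, w))) == 1.7
    w2 = LossWeights(embedding=(0.5, 2.0))
    assert float(value(embedding_objective(1.0, 2.0, 3.0, w2))) == \
        pytest.approx(1.0 + 0.5 * 2.0 + 2.0 * 3.0)
    comps = tuple(RNG.random(6))
    alphas = tuple(RNG.random(6))
    got = float(value(alignment_objective(comps, LossWeights(alignment=alphas))))
    assert got == pytest.approx(sum(a * c for a, c in zip(alphas, comps)))
    assert float(value(alignment_objective((1, 2, 3, 4, 5, 6),
                                        LossWeights(alignment=(0,) * 6)))) == 0
    one_hot = LossWeights(alignment=(0, 0, 1.0, 0, 0, 0))
    assert float(value(alignment_objective(comps, one_hot))) == \
        pytest.approx(comps[2])


def test_loss_weights_validation():
    with pytest.raises(ValueError):
        LossWeights(embedding=(-1.0, 0.0))
    with pytest.raises(ValueError):
        LossWeights(contrastive_margin=-0.5)


# ---------------------------------------------------------------------
# context alignment / contrastive
# ---------------------------------------------------------------------

def test_context_alignment_hand_example_and_trace_identity():
    # 2 drugs sharing one context, z1=(0,0), z2=(1,0):
    # ordered double sum = 2 * ||z1-z2||^2 = 2
    ctx = context_comembership([["a"], ["a"]])
    z = np.array([[0.0, 0.0], [1.0, 0.0]])
    assert float(value(context_alignment(z, ctx))) == pytest.approx(2.0)
    # random instance: double-sum loop equals 2 * trace form
    ctx6 = context_comembership([["a"], ["a", "b"], ["b"], ["a"], ["c"],
                                 ["c", "b"]])
    z = RNG.normal(size=(6, 3))
    loop = 0.0
    for r in ctx6.comembership:
        for i in range(6):
            for j in range(6):
                loop += r[i, j] * np.sum((z[i] - z[j]) ** 2)
    assert float(value(context_alignment(z, ctx6))) == pytest.approx(
        loop, abs=1e-8)


def test_context_alignment_zero_when_comembers_coincide():
    ctx = context_comembership([["a"], ["a"], ["b"]])
    z = np.array([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]])
    assert float(value(context_alignment(z, ctx))) == pytest.approx(0.0)


def test_context_scale_equivariance():
    ctx = context_comembership([["a"], ["a", "b"], ["b"]],
                               weights=[1.0, 1.0])
    z = RNG.normal(size=(3, 2))
    base = float(value(context_alignment(z, ctx)))
    scaled_ctx = context_comembership([["a"], ["a", "b"], ["b"]],
                                      weights=[3.0, 3.0])
    assert float(value(context_alignment(z, scaled_ctx))) == pytest.approx(
        3.0 * base, abs=1e-10)


def test_context_contrastive_cases_and_loop():
    ctx = context_comembership([["a"], ["a"]])
    # co-members at distance 1: same as alignment double sum
    z = np.array([[0.0, 0.0], [1.0, 0.0]])
    assert float(value(context_contrastive(z, ctx, margin=1.0))) == \
        pytest.approx(2.0)
    # non-member pair at distance >= tau contributes 0
    ctx2 = context_comembership([["a"], ["b"]])
    z2 = np.array([[0.0, 0.0], [5.0, 0.0]])
    total = float(value(context_contrastive(z2, ctx2, margin=1.0)))
    assert total == pytest.approx(0.0)
    # non-member pair at distance 0 contributes tau^2 per ordered pair
    z3 = np.zeros((2, 2))
    got = float(value(context_contrastive(z3, ctx2, margin=1.0)))
    # two contexts, two ordered non-member pairs each
    assert got == pytest.approx(4.0)
    # random loop oracle
    ctx6 = context_comembership([["a"], ["a", "b"], ["b"], ["c"], ["c"],
                                 ["a"]])
    z = RNG.normal(size=(6, 2))
    tau = 1.3
    loop = 0.0
    for w, r in zip(ctx6.context_weights, ctx6.comembership):
        for i in range(6):
            for j in range(6):
                if i == j:
                    continue
                dist = np.linalg.norm(z[i] - z[j])
                loop += w * (r[i, j] * dist ** 2
                             + (1 - r[i, j]) * max(0.0, tau - dist) ** 2)
    assert float(value(context_contrastive(z, ctx6, tau))) == pytest.approx(
        loop, abs=1e-8)


# ---------------------------------------------------------------------
# Laplacian smoothness
# ---------------------------------------------------------------------

def _topology(n):
    stack = SimilarityStack(matrices=[_sym(n)], kernel_kinds=["cosine"],
                            fusion_weights=np.array([1.0]))
    return unified_topology(stack)


def test_laplacian_smoothness_cases():
    topo = _topology(3)
    z_const = np.tile([[1.0, 2.0]], (3, 1))
    assert float(value(laplacian_smoothness(z_const, topo))) == \
        pytest.approx(0.0, abs=1e-12)

    # 2-node hand example: G(1,2) = 1, z1 = (0,0), z2 = (1,0) -> 1
    from ddikit.similarity import UnifiedTopology
    g = np.array([[0.0, 1.0], [1.0, 0.0]])
    topo2 = UnifiedTopology(matrix=g)
    z = np.array([[0.0, 0.0], [1.0, 0.0]])
    assert float(value(laplacian_smoothness(z, topo2))) == pytest.approx(1.0)


def test_trace_equals_half_sum_identity():
    from ddikit.similarity import UnifiedTopology
    g = _sym(8)
    np.fill_diagonal(g, 0.0)
    topo = UnifiedTopology(matrix=g)
    z = RNG.normal(size=(8, 3))
    half_sum = 0.0
    for i in range(8):
        for j in range(8):
            half_sum += 0.5 * g[i, j] * np.sum((z[i] - z[j]) ** 2)
    assert float(value(laplacian_smoothness(z, topo))) == pytest.approx(
        half_sum, abs=1e-8)


# ---------------------------------------------------------------------
# co-prescription calibration
# ---------------------------------------------------------------------

def test_coprescription_kl_zero_at_match_and_zero_rows():
    # choose embeddings so sigmoid(z_i . z_j) equals P_co on active pairs
    o = np.array([[0, 3, 3], [3, 0, 0], [3, 0, 0]], dtype=float)
    data = coprescription_probabilities(o)
    # P_co off-diagonal entries are 0.5 or 1; pick z so sigmoid = 0.5 -> 0
    p_target = 0.5
    z = np.zeros((3, 2))            # all inner products 0, sigmoid = 0.5
    expect = 0.0
    for i in range(3):
        for j in range(3):
            p = data.probabilities[i, j]
            if p > 0:
                expect += data.confidence[i, j] * p * np.log(p / p_target)
    got = float(value(coprescription_kl(z, data, weighted=True)))
    assert got == pytest.approx(expect, abs=1e-10)
    # rows with all-zero counts contribute nothing and stay finite
    o2 = np.zeros((3, 3))
    o2[0, 1] = o2[1, 0] = 1
    with pytest.warns(UserWarning):
        d2 = coprescription_probabilities(o2)
    assert np.isfinite(float(value(coprescription_kl(z, d2)))), "finite"


def test_coprescription_kl_matches_loop():
    o = np.array([[0, 5, 1], [5, 0, 2], [1, 2, 0]], dtype=float)
    data = coprescription_probabilities(o)
    z = RNG.normal(size=(3, 2))
    for weighted in (True, False):
        expect = 0.0
        for i in range(3):
            for j in range(3):
                p = data.probabilities[i, j]
                if p == 0:
                    continue
                sig = 1 / (1 + np.exp(-(z[i] @ z[j])))
                sig = np.clip(sig, 1e-12, 1 - 1e-12)
                w = data.confidence[i, j] if weighted else 1.0
                expect += w * p * np.log(p / sig)
        got = float(value(coprescription_kl(z, data, weighted=weighted)))
        assert got == pytest.approx(expect, abs=1e-10)


# ---------------------------------------------------------------------
# MMD
# ---------------------------------------------------------------------

def test_mmd_identical_distributions_is_exactly_zero():
    z = RNG.normal(size=(6, 3))
    got = float(value(mmd_alignment([z, z.copy()], bandwidth=1.0)))
    assert got == pytest.approx(0.0, abs=1e-15)


def test_mmd_matches_three_double_loops():
    x = RNG.normal(size=(5, 1))
    y = RNG.normal(size=(5, 1)) + 1.0
    bw = 0.8

    def k(a, b):
        return np.exp(-np.sum((a - b) ** 2) / (2 * bw ** 2))

    kxx = np.mean([[k(a, b) for b in x] for a in x])
    kyy = np.mean([[k(a, b) for b in y] for a in y])
    kxy = np.mean([[k(a, b) for b in y] for a in x])
    expect = kxx + kyy - 2 * kxy
    got = float(value(mmd_alignment([x, y], bandwidth=bw)))
    assert got == pytest.approx(expect, abs=1e-10)
    assert got >= 0.0, "biased estimator is non-negative"


def test_mmd_single_modality_warns_zero():
    with pytest.warns(UserWarning):
        assert mmd_alignment([RNG.normal(size=(4, 2))]) == 0.0


# ---------------------------------------------------------------------
# margin ranking
# ---------------------------------------------------------------------

def test_margin_ranking_boundary_and_degenerate_cases():
    delta = 0.7
    # gap exactly delta -> hinge at the boundary contributes 0
    z = np.array([[0.0], [1.0], [np.sqrt(1.0 + delta)]])
    batch = TripletBatch(anchors=[0], positives=[1], negatives=[2])
    assert float(value(margin_ranking(z, batch, delta))) == pytest.approx(
        0.0, abs=1e-12)
    # identical positive/negative embeddings -> exactly delta
    z2 = np.array([[0.0], [1.0], [-1.0]])
    assert float(value(margin_ranking(z2, batch, delta))) == pytest.approx(
        delta)


def test_margin_ranking_matches_loop():
    z = RNG.normal(size=(10, 3))
    a = RNG.integers(0, 10, 10)
    p = (a + 1 + RNG.integers(0, 8, 10)) % 10
    nn = (p + 1 + RNG.integers(0, 7, 10)) % 10
    ok = (a != p) & (a != nn) & (p != nn)
    batch = TripletBatch(anchors=a[ok], positives=p[ok], negatives=nn[ok])
    delta = 1.1
    expect = sum(max(0.0, delta + np.sum((z[i] - z[j]) ** 2)
                     - np.sum((z[i] - z[k]) ** 2))
                 for i, j, k in zip(batch.anchors, batch.positives,
                                    batch.negatives))
    assert float(value(margin_ranking(z, batch, delta))) == pytest.approx(
        expect, abs=1e-10)


# ---------------------------------------------------------------------
# gradients (spot checks; the full sweep lives in the acceptance suite)
# ---------------------------------------------------------------------

@pytest.mark.parametrize("make_loss", [
    lambda z, aux: contrastive_triplet(z, aux["batch"]),
    lambda z, aux: similarity_preserving(z, aux["s"], "cosine"),
    lambda z, aux: coprescription_kl(z, aux["co"]),
    lambda z, aux: mmd_alignment([z, aux["z2"]], bandwidth=1.0),
])
def test_loss_gradients_match_finite_differences(make_loss):
    n, d = 5, 3
    aux = {
        "batch": TripletBatch(anchors=[0, 1], positives=[2, 3],
                              negatives=[4, 0]),
        "s": _sym(n),
        "co": coprescription_probabilities(
            np.abs(RNG.integers(0, 5, (n, n))).astype(float)),
        "z2": RNG.normal(size=(n, d)),
    }
    z0 = RNG.normal(size=(n, d))
    err = ad.max_relative_grad_error(lambda z: make_loss(z, aux), z0)
    assert err < 1e-4
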