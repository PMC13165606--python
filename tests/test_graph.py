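"""Graph construction (cosine Top-K, normalized Laplacian), node embedding,
Chebyshev convolution, and the permutation behavior of the region stack."""

import numpy as np
import pytest

from hemignn.graph import (
    ChebBlock,
    NodeTemporalEmbedding,
    RegionEncoder,
    build_adjacency,
    build_region_graph,
    cheb_conv,
    l2_normalize_rows,
    normalized_laplacian,
    region_pool,
)
from hemignn.nn import Parameter
from hemignn.nn.tensor import Tensor
from graph_oracles import brute_force_adjacency, dense_cheb_oracle


# -- row normalization ----------------------------------------------------------

def test_l2_normalize_345_triangle():
    out = l2_normalize_rows(np.array([[3.0, 4.0]]))
    np.testing.assert_allclose(out, [[0.6, 0.8]])


def test_l2_normalize_zero_row_guard():
    out = l2_normalize_rows(np.array([[0.0, 0.0], [1.0, 0.0]]))
    np.testing.assert_array_equal(out[0], [0.0, 0.0])


def test_l2_normalize_norms_zero_or_one(rng):
    x = rng.standard_normal((5, 8, 12))
    x[2, 3] = 0.0
    norms = np.linalg.norm(l2_normalize_rows(x), axis=-1)
    assert np.all((np.abs(norms - 1) < 1e-6) | (norms < 1e-6))


# -- adjacency -------------------------------------------------------------------

def test_adjacency_hand_example_duplicate_rows():
    e1, e2 = np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])
    a = build_adjacency(np.stack([e1, e1, e2]), k=1)
    expect = np.zeros((3, 3))
    expect[0, 1] = expect[1, 0] = 1.0  # the duplicated rows; node 3 isolated
    np.testing.assert_allclose(a, expect, atol=1e-12)


def test_adjacency_identical_rows_complete_graph(rng):
    row = rng.standard_normal(16)
    x = np.tile(row, (11, 1))
    a = build_adjacency(x, k=10)
    np.testing.assert_allclose(a, 1.0 - np.eye(11), atol=1e-9)


def test_adjacency_orthogonal_rows_empty():
    a = build_adjacency(np.eye(6), k=3)
    np.testing.assert_array_equal(a, np.zeros((6, 6)))


def test_adjacency_negative_correlations_suppressed():
    x = np.array([[1.0, 0.0], [-1.0, 0.0], [1.0, 0.1]])
    a = build_adjacency(x, k=2)
    assert a[0, 1] == 0.0 and a[1, 0] == 0.0
    assert a[0, 2] > 0.0


@pytest.mark.parametrize("symmetrize", ["max", "mean"])
def test_adjacency_matches_brute_force(rng, symmetrize):
    for _ in range(120):
        n = int(rng.integers(2, 7))
        t = int(rng.integers(2, 9))
        k = int(rng.integers(1, n))
        x = rng.standard_normal((n, t))
        got = build_adjacency(x, k=k, symmetrize=symmetrize)
        want = brute_force_adjacency(x, k, symmetrize)
        np.testing.assert_allclose(got, want, atol=1e-12)


def test_adjacency_row_sparsity_before_symmetrization(rng):
    # directed Top-K bound survives max-symmetrization as a 2k row bound;
    # the pre-symmetrization matrix itself is checked against the oracle above
    x = rng.standard_normal((8, 6))
    a = build_adjacency(x, k=3)
    assert a.diagonal().max() == 0.0
    assert ((a > 0).sum(axis=1) <= 6).all()


def test_adjacency_batched_consistency(rng):
    x = rng.standard_normal((4, 5, 7))
    batched = build_adjacency(x, k=2)
    for i in range(4):
        np.testing.assert_allclose(batched[i], build_adjacency(x[i], k=2))


# -- laplacian -------------------------------------------------------------------

def test_laplacian_complete_triangle():
    a = 1.0 - np.eye(3)
    lap = normalized_laplacian(a)
    np.testing.assert_allclose(lap, np.eye(3) - (a / 2.0), atol=1e-12)
    eig = np.sort(np.linalg.eigvalsh(lap))
    np.testing.assert_allclose(eig, [0.0, 1.5, 1.5], atol=1e-12)


def test_laplacian_isolated_nodes_identity():
    np.testing.assert_array_equal(normalized_laplacian(np.zeros((4, 4))), np.eye(4))


def test_laplacian_rejects_asymmetry():
    a = np.zeros((3, 3))
    a[0, 1] = 1.0
    with pytest.raises(ValueError, match="symmetric"):
        normalized_laplacian(a)


def test_laplacian_spectrum_on_random_topk_graphs(rng):
    x = rng.standard_normal((200, 7, 12))
    lap = normalized_laplacian(build_adjacency(x, k=3))
    eig = np.linalg.eigvalsh(lap)
    assert eig.min() >= -1e-8 and eig.max() <= 2 + 1e-8


def test_region_graph_bundle(rng):
    x = rng.standard_normal((11, 32))
    g = build_region_graph(x, tuple(f"ch{i}" for i in range(11)), k=10)
    assert g.adjacency.shape == g.laplacian.shape == (11, 11)
    np.testing.assert_allclose(g.laplacian, g.laplacian.T)


# -- node embedding ---------------------------------------------------------------

def test_embedding_output_shape_table_defaults(rng):
    embed = NodeTemporalEmbedding(11, rng).eval()
    out = embed(Tensor(rng.standard_normal((2, 11, 512)).astype(np.float32)))
    assert out.data.shape == (2, 11, 64)


def test_attention_weights_sum_to_one_per_node(rng):
    embed = NodeTemporalEmbedding(5, rng, c1=4, c2=6, t1=8).eval()
    embed(Tensor(rng.standard_normal((3, 5, 40)).astype(np.float32)))
    np.testing.assert_allclose(embed.last_attention.sum(axis=2), 1.0, atol=1e-6)


def test_constant_input_uniform_attention_in_interior(rng):
    """A time-constant signal earns (near-)uniform attention; only the
    zero-padded borders (k-1 samples) may deviate."""
    embed = NodeTemporalEmbedding(4, rng, c1=4, c2=6, t1=8, kernel=7).eval()
    t = 50
    x = np.ones((1, 4, t), dtype=np.float32) * 2.0
    embed(Tensor(x))
    attn = embed.last_attention[0]
    interior = attn[:, 6 : t - 6]
    np.testing.assert_allclose(
        interior, np.broadcast_to(interior[:, :1], interior.shape), rtol=1e-4
    )  # flat inside the padded margin
    np.testing.assert_allclose(attn.sum(axis=1), 1.0, atol=1e-6)


# -- chebyshev convolution --------------------------------------------------------

def test_cheb_theta0_only_is_graph_independent(rng):
    x = Tensor(rng.standard_normal((2, 5, 6)))
    th0 = Parameter(rng.standard_normal((6, 4)))
    zeros = [Parameter(np.zeros((6, 4))) for _ in range(2)]
    lap = normalized_laplacian(build_adjacency(rng.standard_normal((2, 5, 8)), k=2))
    out = cheb_conv(x, lap, [th0, *zeros])
    np.testing.assert_allclose(out.data, x.data @ th0.data, atol=1e-12)


def test_cheb_zero_adjacency_collapses_recurrence(rng):
    """L = I, Lt = 0: T1 vanishes and T2 = -I, so out = x (th0 - th2)."""
    x = Tensor(rng.standard_normal((1, 4, 3)))
    thetas = [Parameter(rng.standard_normal((3, 3))) for _ in range(3)]
    lap = np.eye(4)[None]
    out = cheb_conv(x, lap, thetas)
    expect = x.data @ (thetas[0].data - thetas[2].data)
    np.testing.assert_allclose(out.data, expect, atol=1e-12)


def test_cheb_matches_dense_polynomial_oracle(rng):
    for _ in range(120):
        n = int(rng.integers(2, 9))
        f = int(rng.integers(1, 6))
        x = rng.standard_normal((n, f))
        lap = normalized_laplacian(build_adjacency(rng.standard_normal((n, 10)), k=2))
        thetas = [Parameter(rng.standard_normal((f, f))) for _ in range(3)]
        out = cheb_conv(Tensor(x[None]), lap[None], thetas)
        np.testing.assert_allclose(
            out.data[0], dense_cheb_oracle(x, lap, [t.data for t in thetas]), atol=1e-9
        )


def test_cheb_requires_coefficients(rng):
    with pytest.raises(ValueError):
        cheb_conv(Tensor(np.zeros((1, 3, 2))), np.eye(3)[None], [])


def test_cheb_block_zero_coeffs_is_double_layernorm(rng):
    block = ChebBlock(6, rng, order=3, dropout=0.2).eval()
    for layer in block.layers:
        for th in layer.thetas:
            th.data[...] = 0.0
    x = rng.standard_normal((2, 4, 6)).astype(np.float64)
    lap = np.tile(np.eye(4), (2, 1, 1))
    out = block(Tensor(x), lap).data

    def ln(v):
        mu = v.mean(-1, keepdims=True)
        return (v - mu) / np.sqrt(v.var(-1, keepdims=True) + 1e-5)

    np.testing.assert_allclose(out, ln(ln(x)), atol=1e-6)


def test_cheb_block_dropout_only_in_train_mode(rng):
    block = ChebBlock(6, rng, order=2, dropout=0.5,
                      dropout_rng=np.random.default_rng(0))
    x = Tensor(rng.standard_normal((1, 4, 6)).astype(np.float32))
    lap = np.tile(np.eye(4), (1, 1, 1))
    block.eval()
    a = block(x, lap).data
    b = block(x, lap).data
    np.testing.assert_array_equal(a, b)  # eval is deterministic
    block.train()
    c = block(x, lap).data
    assert np.abs(c - a).max() > 1e-6  # dropout mask active


# -- pooling and permutation -------------------------------------------------------

def test_region_pool_examples():
    x = Tensor(np.array([[[0.0, 0.0], [2.0, 2.0]]]))
    np.testing.assert_allclose(region_pool(x).data, [[1.0, 1.0]])
    same = Tensor(np.tile(np.array([1.5, -2.0]), (1, 5, 1)))
    np.testing.assert_allclose(region_pool(same).data, [[1.5, -2.0]])


def test_region_pool_permutation_invariant(rng):
    x = rng.standard_normal((2, 7, 5))
    perm = rng.permutation(7)
    np.testing.assert_allclose(
        region_pool(Tensor(x)).data, region_pool(Tensor(x[:, perm])).data, atol=1e-12
    )


def test_region_encoder_permutation_equivariance(rng):
    """Permuting a region's channels (and re-resolving the per-node weights
    through their electrode labels) leaves the region embedding unchanged."""
    labels = tuple(f"ch{i}" for i in range(11))
    enc = RegionEncoder(labels, rng, dropout_rng=np.random.default_rng(1)).eval()
    x = rng.standard_normal((2, 11, 128)).astype(np.float32) * 5
    base = enc(Tensor(x)).data
    perm = list(rng.permutation(11))
    enc_p = enc.reordered(perm).eval()
    out = enc_p(Tensor(x[:, perm])).data
    assert enc_p.node_labels == tuple(labels[i] for i in perm)
    np.testing.assert_allclose(out, base, atol=1e-5)
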