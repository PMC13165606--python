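"""Brain-partition-based graph learning.

Per region and per window: cosine-similarity Top-K adjacency over the
filtered channel time series, symmetric normalized Laplacian, node-wise
temporal embedding with time-attention pooling, a two-layer Chebyshev
graph-convolution block with residual connections and layer normalization,
and mean pooling over nodes into a region embedding.

Graphs are data-derived, recomputed for every window, and detached from the
autodiff tape: gradients flow through the node embeddings, not through graph
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Dropout, LayerNorm, Linear, Module, NodewiseConv1d, Parameter
from .nn import tensor as T
from .nn.layers import _uniform
from .nn.tensor import Tensor

__all__ = [
    "RegionGraph",
    "l2_normalize_rows",
    "build_adjacency",
    "normalized_laplacian",
    "build_region_graph",
    "NodeTemporalEmbedding",
    "cheb_conv",
    "ChebConvLayer",
    "ChebBlock",
    "region_pool",
    "RegionEncoder",
]


# -- graph construction (plain numpy, batched over leading axes) --------------

def l2_normalize_rows(x: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Scale each row (last axis) to unit Euclidean norm; zero rows stay zero.

    Floating dtypes are preserved (the model runs this in float32); other
    inputs are promoted to float64.
    """
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(np.float64)
    norms = np.linalg.norm(x, axis=-1, keepdims=True)
    out = x / np.where(norms > eps, norms, 1.0)
    out[np.broadcast_to(norms <= eps, out.shape)] = 0.0
    return out


def build_adjacency(
    x: np.ndarray, k: int = 10, symmetrize: str = "max"
) -> np.ndarray:
    """Cosine Top-K functional-connectivity adjacency from (..., N, T) signals.

    Pairwise cosine similarities of the channel time series; negative entries
    suppressed (ReLU), the self-similarity diagonal excluded, the ``k``
    largest positive entries kept per row (ties broken toward the lower
    column index) and the result symmetrized -- element-wise maximum by
    default, so every retained directed edge survives, or ``"mean"``.
    """
    if k < 1:
        raise ValueError("top_k must be >= 1")
    xn = l2_normalize_rows(x)
    s = xn @ np.swapaxes(xn, -1, -2)
    np.maximum(s, 0.0, out=s)  # suppress negative correlations
    n = s.shape[-1]
    eye = np.eye(n, dtype=bool)
    s[..., eye] = -1.0  # self-similarity never competes for a Top-K slot
    order = np.argsort(-s, axis=-1, kind="stable")
    keep = np.zeros(s.shape, dtype=bool)
    np.put_along_axis(keep, order[..., :k], True, axis=-1)
    keep &= s > 0.0
    a = np.where(keep, s, 0.0)
    at = np.swapaxes(a, -1, -2)
    if symmetrize == "max":
        a = np.maximum(a, at)
    elif symmetrize == "mean":
        a = 0.5 * (a + at)
    else:
        raise ValueError(f"unknown symmetrization {symmetrize!r}; use 'max' or 'mean'")
    return a


def normalized_laplacian(adjacency: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """L = I - D^{-1/2} A D^{-1/2} for symmetric nonnegative A, zero diagonal.

    Isolated (zero-degree) nodes use D^{-1/2} = 0, leaving an identity
    row/column; the spectrum then stays within [0, 2].
    """
    a = np.asarray(adjacency, dtype=np.float64)
    if not np.allclose(a, np.swapaxes(a, -1, -2), atol=atol):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -atol:
        raise ValueError("adjacency must be nonnegative")
    d = a.sum(axis=-1)
    with np.errstate(divide="ignore"):
        dinv = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    lap = -dinv[..., :, None] * a * dinv[..., None, :]
    n = a.shape[-1]
    lap[..., np.arange(n), np.arange(n)] += 1.0
    return lap


@dataclass(frozen=True)
class RegionGraph:
    """One region's sparse functional graph for one window."""

    node_labels: tuple[str, ...]
    adjacency: np.ndarray
    laplacian: np.ndarray


def build_region_graph(
    x_region: np.ndarray,
    node_labels: tuple[str, ...],
    k: int = 10,
    symmetrize: str = "max",
) -> RegionGraph:
    """Adjacency + Laplacian for a single (N, T) region slice."""
    a = build_adjacency(x_region, k=k, symmetrize=symmetrize)
    return RegionGraph(tuple(node_labels), a, normalized_laplacian(a))


# -- node-wise temporal embedding ---------------------------------------------

class NodeTemporalEmbedding(Module):
    """Encode each node's time course into a fixed-length vector.

    Two per-node temporal convolution stages (1 -> C1 -> C2 channels, time
    extent 7, ReLU) extract local dynamics; a per-node scoring convolution
    plus softmax over time yields attention weights that pool the feature map
    over time; a shared linear layer projects C2 -> T1.  Per-node weight
    groups are tied to electrode labels via ``reordered``.
    """

    def __init__(
        self,
        n_nodes: int,
        rng: np.random.Generator,
        c1: int = 16,
        c2: int = 32,
        t1: int = 64,
        kernel: int = 7,
    ):
        super().__init__()
        self.n_nodes = n_nodes
        self.conv1 = NodewiseConv1d(n_nodes, kernel, 1, c1, rng, activation="relu")
        self.conv2 = NodewiseConv1d(n_nodes, kernel, c1, c2, rng, activation="relu")
        self.score = NodewiseConv1d(n_nodes, 1, c2, 1, rng)
        self.proj = Linear(c2, t1, rng)
        self.last_attention: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        """(B, N, T) -> (B, N, T1)."""
        b, n, t = x.data.shape
        h = x.reshape((b, n, t, 1))
        h1 = self.conv1(h)  # ReLU fused into the conv kernels
        h2 = self.conv2(h1)  # (B, N, T, C2)
        scores = self.score(h2).reshape((b, n, t))
        attn = T.softmax(scores, axis=2)  # per-node weights over time, sum 1
        self.last_attention = attn.data
        pooled = T.matmul(attn.reshape((b, n, 1, t)), h2).reshape((b, n, -1))
        return self.proj(pooled)

    def reordered(self, perm: list[int]) -> "NodeTemporalEmbedding":
        out = object.__new__(NodeTemporalEmbedding)
        Module.__init__(out)
        out.n_nodes = self.n_nodes
        out.conv1 = self.conv1.reordered(perm)
        out.conv2 = self.conv2.reordered(perm)
        out.score = self.score.reordered(perm)
        out.proj = self.proj  # shared across nodes: order-free
        out.last_attention = None
        return out


# -- Chebyshev graph convolution ----------------------------------------------

def cheb_conv(x: Tensor, laplacian: np.ndarray, thetas: list[Parameter]) -> Tensor:
    """Spectral graph convolution via a Chebyshev polynomial in the Laplacian.

    Uses the scaled operator Lt = L - I (upper bound lambda_max = 2 for a
    normalized Laplacian) and the recurrence T_0 = I, T_1 = Lt,
    T_p = 2 Lt T_{p-1} - T_{p-2}; output = sum_p T_p(Lt) x Theta_p.
    ``laplacian`` may be batched (B, N, N) against x (B, N, F).
    """
    if not thetas:
        raise ValueError("Chebyshev order must be >= 1")
    lt = laplacian - np.eye(laplacian.shape[-1], dtype=laplacian.dtype)
    lt_t = T.Tensor(lt.astype(x.data.dtype))
    terms = [x]
    if len(thetas) > 1:
        terms.append(T.matmul(lt_t, x))
    for _ in range(2, len(thetas)):
        terms.append(T.matmul(lt_t, terms[-1]) * 2.0 + terms[-2] * -1.0)
    out = T.matmul(terms[0], thetas[0])
    for tp, theta in zip(terms[1:], thetas[1:]):
        out = out + T.matmul(tp, theta)
    return out


class ChebConvLayer(Module):
    def __init__(self, width: int, order: int, rng: np.random.Generator):
        super().__init__()
        if order < 1:
            raise ValueError("Chebyshev order must be >= 1")
        self.thetas = [
            Parameter(_uniform(rng, (width, width), width * order)) for _ in range(order)
        ]

    def forward(self, x: Tensor, laplacian: np.ndarray) -> Tensor:
        return cheb_conv(x, laplacian, self.thetas)


class ChebBlock(Module):
    """Two stacked residual Chebyshev layers: LN(x + Dropout(ReLU(Cheb(x)))).

    The residual forces the hidden width to equal the input width (T2 = T1).
    Dropout is active only in train mode; each layer owns its coefficients
    and layer norm.
    """

    def __init__(
        self,
        width: int,
        rng: np.random.Generator,
        order: int = 3,
        dropout: float = 0.2,
        dropout_rng: np.random.Generator | None = None,
    ):
        super().__init__()
        self.layers = [ChebConvLayer(width, order, rng) for _ in range(2)]
        self.norms = [LayerNorm(width) for _ in range(2)]
        drng = dropout_rng if dropout_rng is not None else np.random.default_rng(0)
        self.drops = [Dropout(dropout, drng) for _ in range(2)]

    def forward(self, x: Tensor, laplacian: np.ndarray) -> Tensor:
        for layer, norm, drop in zip(self.layers, self.norms, self.drops):
            x = norm(x + drop(T.relu(layer(x, laplacian))))
        return x


def region_pool(x: Tensor) -> Tensor:
    """Mean over the node axis: (B, N, T2) -> (B, T2)."""
    return x.mean(axis=1)


# -- full region stack ---------------------------------------------------------

class RegionEncoder(Module):
    """Graph construction + node embedding + Chebyshev block + node pooling
    for one region; the per-window unit of the partition-based graph stage."""

    def __init__(
        self,
        node_labels: tuple[str, ...],
        rng: np.random.Generator,
        top_k: int = 10,
        symmetrize: str = "max",
        c1: int = 16,
        c2: int = 32,
        t1: int = 64,
        embed_kernel: int = 7,
        cheb_order: int = 3,
        dropout: float = 0.2,
        dropout_rng: np.random.Generator | None = None,
    ):
        super().__init__()
        self.node_labels = tuple(node_labels)
        self.top_k = top_k
        self.symmetrize = symmetrize
        self.embed = NodeTemporalEmbedding(
            len(node_labels), rng, c1=c1, c2=c2, t1=t1, kernel=embed_kernel
        )
        self.cheb = ChebBlock(t1, rng, order=cheb_order, dropout=dropout,
                              dropout_rng=dropout_rng)

    def forward(self, x_region: Tensor) -> Tensor:
        """(B, N, T) region slice -> (B, T1) region embedding."""
        adjacency = build_adjacency(
            x_region.data, k=self.top_k, symmetrize=self.symmetrize
        )
        laplacian = normalized_laplacian(adjacency)
        h = self.embed(x_region)
        h = self.cheb(h, laplacian)
        return region_pool(h)

    def reordered(self, perm: list[int]) -> "RegionEncoder":
        """The same encoder under a permuted node (channel) order.

        Per-node embedding weights follow their electrode labels; the
        Chebyshev block, layer norms and projections are node-symmetric and
        shared, so the returned encoder computes the identical region
        embedding on correspondingly permuted input.
        """
        out = object.__new__(RegionEncoder)
        Module.__init__(out)
        out.node_labels = tuple(self.node_labels[i] for i in perm)
        out.top_k = self.top_k
        out.symmetrize = self.symmetrize
        out.embed = self.embed.reordered(perm)
        out.cheb = self.cheb
        return out
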