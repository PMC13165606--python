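"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine carrying exactly the operations the
model needs: broadcast arithmetic, (batched) matmul, FFT-based depthwise
temporal convolution, per-node grouped temporal convolution (channels-last
im2col + GEMM, the hot path), fused softmax / layer norm / batch norm /
cross-entropy, dropout and the usual reductions.  Float32 by default; ops
follow their inputs' dtype so gradient checks can run in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (evaluation passes)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward  # fn(g) -> tuple of parent grads (None allowed)

    # -- bookkeeping ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep (per-epoch chains)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = grad
        for node in reversed(topo):
            if node._backward is None:
                continue
            gs = node._backward(node.grad)
            for parent, g in zip(node._parents, gs):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad += g  # closures hand out fresh arrays; in-place is safe
            node._backward = None  # free closures/caches as we go

    def zero_grad(self) -> None:
        self.grad = None

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other, self.data.dtype))

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, as_tensor(other, self.data.dtype) * -1.0)

    def __mul__(self, other):
        return mul(self, as_tensor(other, self.data.dtype))

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("tensor/tensor division is not supported")
        return mul(self, as_tensor(1.0 / other, self.data.dtype))

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def as_tensor(x, dtype=np.float32) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _make(data, parents, backward) -> Tensor:
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, _parents=parents if req else (),
                  _backward=backward if req else None)


# -- arithmetic --------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    return _make(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)),
    )


def mul(a: Tensor, b: Tensor) -> Tensor:
    return _make(
        a.data * b.data,
        (a, b),
        lambda g: (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        ),
    )


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return _unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape)

    return _make(a.data @ b.data, (a, b), backward)


# -- shape ops ---------------------------------------------------------------

def reshape(x: Tensor, shape) -> Tensor:
    old = x.data.shape
    return _make(x.data.reshape(shape), (x,), lambda g: (g.reshape(old),))


def transpose(x: Tensor, axes) -> Tensor:
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return _make(np.transpose(x.data, axes), (x,), lambda g: (np.transpose(g, inv),))


def take(x: Tensor, idx) -> Tensor:
    def backward(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, idx, g)  # duplicated indices (shared midline channels) accumulate
        return (gx,)

    return _make(x.data[idx], (x,), backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    def backward(g):
        return tuple(np.take(g, i, axis=axis) for i in range(len(tensors)))

    return _make(np.stack([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


# -- reductions --------------------------------------------------------------

def reduce_sum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, x.data.shape).copy(),)

    return _make(x.data.sum(axis=axis, keepdims=keepdims), (x,), backward)


def reduce_mean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    count = x.data.size if axis is None else np.prod(
        [x.data.shape[a] for a in np.atleast_1d(axis)]
    )

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, x.data.shape) / count,)

    return _make(x.data.mean(axis=axis, keepdims=keepdims), (x,), backward)


def reduce_max(x: Tensor, axis: int) -> Tensor:
    idx = np.argmax(x.data, axis=axis)

    def backward(g):
        gx = np.zeros_like(x.data)
        np.put_along_axis(
            gx, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis=axis
        )
        return (gx,)

    return _make(np.max(x.data, axis=axis), (x,), backward)


# -- activations and normalizations ------------------------------------------

def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, 0)

    def backward(g):
        g *= y > 0  # tape grads are single-owner arrays; in-place is safe
        return (g,)

    return _make(y, (x,), backward)


def elu(x: Tensor) -> Tensor:
    pos = x.data > 0
    y = np.where(pos, x.data, np.expm1(np.minimum(x.data, 0)))
    return _make(y, (x,), lambda g: (g * np.where(pos, 1.0, y + 1.0),))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        return (y * (g - (g * y).sum(axis=axis, keepdims=True)),)

    return _make(y, (x,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last (feature) axis with learned affine rescaling."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    inv = 1.0 / np.sqrt((xc**2).mean(axis=-1, keepdims=True) + eps)
    xh = xc * inv
    y = xh * gamma.data + beta.data

    def backward(g):
        red = tuple(range(g.ndim - 1))
        dgamma = (g * xh).sum(axis=red)
        dbeta = g.sum(axis=red)
        dxh = g * gamma.data
        dx = inv * (
            dxh
            - dxh.mean(axis=-1, keepdims=True)
            - xh * (dxh * xh).mean(axis=-1, keepdims=True)
        )
        return dx, dgamma, dbeta

    return _make(y, (x, gamma, beta), backward)


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    axes: tuple[int, ...],
    training: bool,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalization over ``axes`` (per remaining channel axis).

    In training mode the batch statistics are used and the running estimates
    updated in place (biased variance); in eval mode the running estimates
    are used.  ``gamma``/``beta`` broadcast against the kept axis.
    """
    keep = tuple(i for i in range(x.data.ndim) if i not in axes)
    bshape = tuple(x.data.shape[i] if i in keep else 1 for i in range(x.data.ndim))
    gam = gamma.data.reshape(bshape)
    bet = beta.data.reshape(bshape)
    if training:
        mu = x.data.mean(axis=axes, keepdims=True)
        var = x.data.var(axis=axes, keepdims=True)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu.reshape(running_mean.shape)
        running_var *= 1.0 - momentum
        running_var += momentum * var.reshape(running_var.shape)
    else:
        mu = running_mean.reshape(bshape)
        var = running_var.reshape(bshape)
    inv = 1.0 / np.sqrt(var + eps)
    xh = (x.data - mu) * inv
    y = xh * gam + bet

    def backward(g):
        dgamma = (g * xh).sum(axis=axes).reshape(gamma.data.shape)
        dbeta = g.sum(axis=axes).reshape(beta.data.shape)
        if training:
            dxh = g * gam
            dx = inv * (
                dxh
                - dxh.mean(axis=axes, keepdims=True)
                - xh * (dxh * xh).mean(axis=axes, keepdims=True)
            )
        else:
            dx = g * gam * inv
        return dx, dgamma, dbeta

    return _make(y, (x, gamma, beta), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    return _make(x.data * mask, (x,), lambda g: (g * mask,))


def cross_entropy_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer class labels against raw scores."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logz = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logz
    n = logits.data.shape[0]
    loss = -logp[np.arange(n), labels].mean()

    def backward(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        return (g * p / n,)

    return _make(np.asarray(loss, dtype=logits.data.dtype), (logits,), backward)


# -- convolutions ------------------------------------------------------------

def conv1d_depthwise(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Per-channel temporal cross-correlation with same padding (odd kernel).

    ``x``: (B, C, T); ``w``: (C, k); ``b``: (C,).  Computed via FFT, which is
    the cheap route for the long kernels of the multi-scale temporal filter.
    """
    from scipy import fft as sfft  # preserves float32, unlike numpy.fft

    B, C, T = x.data.shape
    k = w.data.shape[1]
    p = (k - 1) // 2
    L = sfft.next_fast_len(T + k - 1)
    xf = sfft.rfft(x.data, n=L, axis=-1)
    wrev_f = sfft.rfft(w.data[:, ::-1], n=L, axis=-1)
    y = sfft.irfft(xf * wrev_f, n=L, axis=-1)[..., p : p + T]
    y = y + b.data[:, None]

    def backward(g):
        gf = sfft.rfft(g, n=L, axis=-1)
        wf = sfft.rfft(w.data, n=L, axis=-1)
        gx = sfft.irfft(gf * wf, n=L, axis=-1)[..., p : p + T]
        # gw[c, j] = sum_{b,t} g[b,c,t] * x[b,c,t+j-p]  (linear correlation)
        z = sfft.irfft((np.conj(gf) * xf).sum(axis=0), n=L, axis=-1)
        lags = (np.arange(k) - p) % L
        gw = np.ascontiguousarray(z[..., lags])
        gb = g.sum(axis=(0, 2))
        return gx, gw, gb

    return _make(y, (x, w, b), backward)


def _workspace(ws: dict | None, key: str, shape, dtype) -> np.ndarray:
    """Fetch (or grow) a persistent scratch array to avoid allocator churn."""
    if ws is None:
        return np.empty(shape, dtype=dtype)
    buf = ws.get(key)
    if buf is None or buf.dtype != dtype or buf.shape != tuple(shape):
        buf = np.empty(shape, dtype=dtype)
        ws[key] = buf
    return buf


def conv1d_nodewise(
    x: Tensor,
    w: Tensor,
    b: Tensor,
    ws: dict | None = None,
    activation: str | None = None,
) -> Tensor:
    """Grouped temporal conv with independent weights per node (channels-last).

    ``x``: (B, N, T, Ci); ``w``: (N, k, Ci, Co); ``b``: (N, Co); same padding,
    odd kernel.  ``activation="relu"`` fuses the nonlinearity into the kernel
    (applied in place on the output, masked in the backward pass).  Each
    node's im2col buffer feeds one GEMM; the buffers are kept for the weight
    gradient and recycled across calls through the caller-owned workspace
    ``ws``, which is safe because a module's backward always precedes its
    next forward.
    """
    if activation not in (None, "relu"):
        raise ValueError(f"unsupported activation {activation!r}")
    B, N, T, Ci = x.data.shape
    _, k, _, Co = w.data.shape
    p = (k - 1) // 2
    dt = x.data.dtype

    if k == 1:  # pointwise: no im2col needed
        if Co == 1:  # scoring conv: a per-node inner product over channels
            y = np.einsum("bntc,nc->bnt", x.data, w.data[:, 0, :, 0])[..., None]
            y += b.data[None, :, None, :]
        else:
            y = np.matmul(x.data, w.data[:, 0]) + b.data[None, :, None, :]
        if activation == "relu":
            np.maximum(y, 0, out=y)

        def backward_k1(g):
            if activation == "relu":
                g = g * (y > 0)
            if Co == 1:  # outer product, cheaper as a broadcast multiply
                gx = g * w.data[:, 0, :, 0][None, :, None, :]
                gw = np.einsum("bntc,bnt->nc", x.data, g[..., 0])[:, None, :, None]
            else:
                gx = np.matmul(g, np.swapaxes(w.data[:, 0], -1, -2))
                gw = np.einsum("bntc,bnto->nco", x.data, g)[:, None]
            return gx, gw, g.sum(axis=(0, 2))

        return _make(y, (x, w, b), backward_k1)

    y = np.empty((B, N, T, Co), dtype=dt)  # op output: always a fresh array
    cols = _workspace(ws, "cols", (N, B, T, k, Ci), dt)
    xp = _workspace(ws, "xp", (B, T + 2 * p, Ci), dt)
    xp[:, :p] = 0.0
    xp[:, p + T :] = 0.0
    for n in range(N):
        xp[:, p : p + T] = x.data[:, n]
        for j in range(k):
            cols[n, :, :, j, :] = xp[:, j : j + T]
        y[:, n] = (
            cols[n].reshape(B * T, k * Ci) @ w.data[n].reshape(k * Ci, Co)
        ).reshape(B, T, Co)
    y += b.data[None, :, None, :]
    if activation == "relu":
        np.maximum(y, 0, out=y)

    def backward(g):
        if activation == "relu":
            g *= y > 0  # single-owner tape grad: in-place is safe
        gx = np.empty_like(x.data)
        gw = np.empty_like(w.data)
        gxp = _workspace(ws, "gxp", (B, T + 2 * p, Ci), dt)
        gcols = _workspace(ws, "gcols", (B, T, k, Ci), dt)
        for n in range(N):
            gy = np.ascontiguousarray(g[:, n]).reshape(B * T, Co)
            cols2d = cols[n].reshape(B * T, k * Ci)
            gw[n] = (cols2d.T @ gy).reshape(k, Ci, Co)
            np.matmul(gy, w.data[n].reshape(k * Ci, Co).T, out=gcols.reshape(B * T, k * Ci))
            gxp[...] = 0.0
            for j in range(k):
                gxp[:, j : j + T] += gcols[:, :, j]
            gx[:, n] = gxp[:, p : p + T]
        gb = g.sum(axis=(0, 2))
        return gx, gw, gb

    return _make(y, (x, w, b), backward)
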