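"""Module/parameter containers and the layers used by the model."""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "BatchNorm1d",
    "Dropout",
    "DepthwiseConv1d",
    "NodewiseConv1d",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Minimal parameter container with train/eval modes and state dicts."""

    def __init__(self) -> None:
        self.training = True
        self._buffers: dict[str, np.ndarray] = {}

    # attribute walk: parameters/submodules live as attributes or in lists/dicts
    def _children(self):
        for name, value in vars(self).items():
            if name.startswith("_") and name != "_buffers":
                continue
            yield name, value

    def named_parameters(self, prefix: str = ""):
        for name, value in self._children():
            yield from _walk(value, f"{prefix}{name}", Parameter)

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for _, value in self._children():
            yield from _walk_modules(value)

    def train(self, flag: bool = True) -> "Module":
        for m in self.modules():
            m.training = flag
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def named_buffers(self, prefix: str = ""):
        for m_name, m in _named_modules(self, prefix):
            for b_name, buf in m._buffers.items():
                yield f"{m_name}.{b_name}".lstrip("."), buf

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, value in state.items():
            if name in params:
                params[name].data = value.copy()
            elif name in buffers:
                buffers[name][...] = value
            else:
                raise KeyError(f"unexpected state entry {name!r}")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _walk(value, name, cls):
    if isinstance(value, cls):
        yield name, value
    elif isinstance(value, Module):
        yield from value.named_parameters(prefix=f"{name}.")
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            yield from _walk(v, f"{name}.{i}", cls)
    elif isinstance(value, dict):
        for k, v in value.items():
            yield from _walk(v, f"{name}.{k}", cls)


def _walk_modules(value):
    if isinstance(value, Module):
        yield from value.modules()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _walk_modules(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _walk_modules(v)


def _named_modules(value, name):
    if isinstance(value, Module):
        yield name, value
        for child_name, child in value._children():
            yield from _named_modules(child, f"{name}.{child_name}")
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            yield from _named_modules(v, f"{name}.{i}")
    elif isinstance(value, dict):
        for k, v in value.items():
            yield from _named_modules(v, f"{name}.{k}")


def _uniform(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32):
    limit = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_uniform(rng, (n_in, n_out), n_in))
        self.bias = Parameter(np.zeros(n_out, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim, dtype=np.float32))
        self.beta = Parameter(np.zeros(dim, dtype=np.float32))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return T.layer_norm(x, self.gamma, self.beta, self.eps)


class BatchNorm1d(Module):
    """Per-channel normalization of (B, C, T) over batch x time."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.momentum = momentum
        self.eps = eps
        self._buffers["running_mean"] = np.zeros(channels, dtype=np.float32)
        self._buffers["running_var"] = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return T.batch_norm(
            x,
            self.gamma,
            self.beta,
            axes=(0, 2),
            training=self.training,
            running_mean=self._buffers["running_mean"],
            running_var=self._buffers["running_var"],
            momentum=self.momentum,
            eps=self.eps,
        )


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        return T.dropout(x, self.p, self.rng, self.training)


class DepthwiseConv1d(Module):
    """One temporal kernel per channel (groups = channels), same padding."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel length must be odd for exact same padding")
        self.weight = Parameter(_uniform(rng, (channels, kernel), kernel))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return T.conv1d_depthwise(x, self.weight, self.bias)


class NodewiseConv1d(Module):
    """Independent Ci -> Co temporal conv per node; weights tied to node labels.

    ``reordered(perm)`` returns a copy whose per-node weight groups follow a
    new node order, so a permuted channel list resolves to the same function.
    """

    def __init__(self, n_nodes: int, kernel: int, c_in: int, c_out: int,
                 rng: np.random.Generator, activation: str | None = None):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel length must be odd for exact same padding")
        self.weight = Parameter(_uniform(rng, (n_nodes, kernel, c_in, c_out), kernel * c_in))
        self.bias = Parameter(np.zeros((n_nodes, c_out), dtype=np.float32))
        self.activation = activation
        self._ws: dict = {}  # im2col scratch; reused call-to-call (see op docstring)

    def forward(self, x: Tensor) -> Tensor:
        return T.conv1d_nodewise(x, self.weight, self.bias, self._ws, self.activation)

    def reordered(self, perm: list[int]) -> "NodewiseConv1d":
        out = object.__new__(NodewiseConv1d)
        Module.__init__(out)
        out.weight = Parameter(self.weight.data[perm].copy())
        out.bias = Parameter(self.bias.data[perm].copy())
        out.activation = self.activation
        out._ws = {}
        return out
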