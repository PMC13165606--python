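def _tune_allocator() -> None:
    """Keep large blocks on the reusable heap instead of mmap/munmap.

    Training repeatedly allocates and frees tens-of-MB activation arrays;
    with glibc's default mmap threshold every such array is returned to the
    kernel and page-faulted back in on the next step, which dominates the
    runtime.  Best effort: silently skipped off glibc.
    """
    try:
        import ctypes

        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
        libc.mallopt(-1, 1 << 30)  # M_TRIM_THRESHOLD
    except Exception:
        pass


_tune_allocator()

from . import tensor
from .layers import (
    BatchNorm1d,
    DepthwiseConv1d,
    Dropout,
    LayerNorm,
    Linear,
    Module,
    NodewiseConv1d,
    Parameter,
)
from .optim import Adam, CosineAnnealingLR
from .tensor import Tensor, as_tensor, no_grad

__all__ = [
    "tensor",
    "Tensor",
    "as_tensor",
    "no_grad",
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "BatchNorm1d",
    "Dropout",
    "DepthwiseConv1d",
    "NodewiseConv1d",
    "Adam",
    "CosineAnnealingLR",
]
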