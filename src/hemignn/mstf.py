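"""Multi-scale temporal filtering.

Parallel depthwise temporal convolutions with receptive fields of 0.4, 0.2
and 0.1 s (103/51/25 samples at 256 Hz), each batch-normalized per channel
and ELU-activated, fused by an arithmetic mean.  Depthwise means one kernel
per EEG channel (groups = channels), so channels never mix here; spatial
mixing is the graph stage's job.
"""

from __future__ import annotations

import numpy as np

from .nn import BatchNorm1d, DepthwiseConv1d, Module
from .nn import tensor as T
from .nn.tensor import Tensor

__all__ = ["kernel_length", "MSTF", "DEFAULT_SCALES"]

DEFAULT_SCALES: tuple[float, ...] = (0.4, 0.2, 0.1)


def kernel_length(alpha: float, fs: float) -> int:
    """Odd kernel length for a temporal window of ``alpha`` seconds.

    floor(alpha * fs), incremented to the next odd integer when even, which
    yields 103/51/25 samples for 0.4/0.2/0.1 s at 256 Hz and makes symmetric
    same padding exact.
    """
    if alpha <= 0 or fs <= 0:
        raise ValueError("alpha and fs must be positive")
    k = int(np.floor(alpha * fs))
    if k < 1:
        raise ValueError(f"window {alpha} s is shorter than one sample at {fs} Hz")
    return k if k % 2 == 1 else k + 1


class MSTF(Module):
    """Mean-fused bank of depthwise temporal filter branches.

    Any non-empty subset of the three default scales is a valid
    configuration (ablation axis); a single scale degenerates to that
    branch's activation.
    """

    def __init__(
        self,
        channels: int,
        rng: np.random.Generator,
        scales: tuple[float, ...] = DEFAULT_SCALES,
        sampling_rate: float = 256.0,
    ):
        super().__init__()
        if not scales:
            raise ValueError("at least one temporal scale is required")
        self.scales = tuple(scales)
        self.sampling_rate = sampling_rate
        self.kernel_lengths = tuple(kernel_length(a, sampling_rate) for a in scales)
        self.convs = [DepthwiseConv1d(channels, k, rng) for k in self.kernel_lengths]
        self.bns = [BatchNorm1d(channels) for _ in self.kernel_lengths]

    def forward(self, x: Tensor) -> Tensor:
        """(B, C, T) -> (B, C, T): mean over branch activations."""
        if x.data.shape[-1] < max(self.kernel_lengths):
            raise ValueError(
                f"window of {x.data.shape[-1]} samples is shorter than the "
                f"longest kernel ({max(self.kernel_lengths)})"
            )
        branches = [
            T.elu(bn(conv(x))) for conv, bn in zip(self.convs, self.bns)
        ]
        out = branches[0]
        for b in branches[1:]:
            out = out + b
        return out / float(len(branches))
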