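"""Attentive fusion of region embeddings and the final classifier.

The default strategy scores each region embedding with a shared linear map,
softmax-normalizes the scores into weights, and takes the weighted sum; the
ablation alternatives are plain averaging, element-wise max, and
concatenation feeding a widened classifier.  The fused vector is
layer-normalized and mapped linearly to two class scores (MDD = index 1).
"""

from __future__ import annotations

import numpy as np

from .nn import LayerNorm, Linear, Module
from .nn import tensor as T
from .nn.tensor import Tensor

__all__ = ["FUSION_STRATEGIES", "FusionHead"]

FUSION_STRATEGIES = ("attn", "avg", "max", "concat_mlp")


class FusionHead(Module):
    def __init__(
        self,
        t2: int,
        n_regions: int,
        rng: np.random.Generator,
        strategy: str = "attn",
        n_classes: int = 2,
    ):
        super().__init__()
        if strategy not in FUSION_STRATEGIES:
            raise ValueError(
                f"unknown fusion strategy {strategy!r}; expected one of {FUSION_STRATEGIES}"
            )
        self.strategy = strategy
        self.n_regions = n_regions
        self.t2 = t2
        # one scoring map shared across regions (only used by 'attn')
        self.score = Linear(t2, 1, rng)
        width = t2 * n_regions if strategy == "concat_mlp" else t2
        self.norm = LayerNorm(width)
        self.classifier = Linear(width, n_classes, rng)
        self.last_weights: np.ndarray | None = None

    def fuse(self, regions: Tensor) -> Tensor:
        """(B, R, T2) region embeddings -> fused (B, T2) (or (B, R*T2)).

        For 'attn' the softmax weights are cached in ``last_weights``; the
        fused vector is a convex combination of the region embeddings.
        """
        b, r, t2 = regions.data.shape
        self.last_weights = None
        if self.strategy == "attn":
            scores = self.score(regions).reshape((b, r))
            w = T.softmax(scores, axis=1)
            self.last_weights = w.data
            return T.matmul(w.reshape((b, 1, r)), regions).reshape((b, t2))
        if self.strategy == "avg":
            self.last_weights = np.full((b, r), 1.0 / r, dtype=regions.data.dtype)
            return regions.mean(axis=1)
        if self.strategy == "max":
            return T.reduce_max(regions, axis=1)
        return regions.reshape((b, r * t2))  # concat_mlp

    def classify(self, fused: Tensor) -> Tensor:
        """Layer-normalize the fused vector and map it to 2 class scores."""
        return self.classifier(self.norm(fused))

    def forward(self, regions: Tensor) -> Tensor:
        return self.classify(self.fuse(regions))
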