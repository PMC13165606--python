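"""The full classifier: temporal filter bank, per-region graph learning,
attentive fusion.  One forward pass maps a batch of 2-s EEG windows
(B, 19, 512) to two class scores per window."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .fusion import FusionHead
from .graph import RegionEncoder
from .montage import build_partition, channel_indices, standard_1020_montage
from .mstf import DEFAULT_SCALES, MSTF
from .nn import Module
from .nn import tensor as T
from .nn.tensor import Tensor, as_tensor, no_grad

__all__ = ["ModelConfig", "HemiGraphNet"]


@dataclass(frozen=True)
class ModelConfig:
    """All architecture hyperparameters, including the ablation switches."""

    scales: tuple[float, ...] = DEFAULT_SCALES  # temporal receptive fields, s
    partition: str = "two_region"  # two_region | four_region | ap | full_brain
    top_k: int = 10  # retained positive correlations per node
    symmetrize: str = "max"  # max | mean
    c1: int = 16  # node-embedding widths (first/second conv stage)
    c2: int = 32
    t1: int = 64  # embedding length (= T2, forced by the residual)
    embed_kernel: int = 7
    cheb_order: int = 3
    dropout: float = 0.2
    fusion: str = "attn"  # attn | avg | max | concat_mlp
    sampling_rate: float = 256.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scales"] = list(self.scales)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "scales" in d:
            d["scales"] = tuple(d["scales"])
        return cls(**d)


class HemiGraphNet(Module):
    """Partition-aware spatiotemporal graph network for MDD vs HC windows."""

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0):
        super().__init__()
        self.config = config
        self.montage = standard_1020_montage(config.sampling_rate)
        self.partition = build_partition(self.montage, config.partition)
        self.region_indices = channel_indices(self.partition, self.montage)
        ss = np.random.SeedSequence(seed)
        init_rng, drop_rng = (np.random.default_rng(s) for s in ss.spawn(2))

        self.mstf = MSTF(
            self.montage.n_channels,
            init_rng,
            scales=config.scales,
            sampling_rate=config.sampling_rate,
        )
        self.encoders = {
            region: RegionEncoder(
                labels,
                init_rng,
                top_k=config.top_k,
                symmetrize=config.symmetrize,
                c1=config.c1,
                c2=config.c2,
                t1=config.t1,
                embed_kernel=config.embed_kernel,
                cheb_order=config.cheb_order,
                dropout=config.dropout,
                dropout_rng=drop_rng,
            )
            for region, labels in self.partition.regions.items()
        }
        self.head = FusionHead(
            config.t1,
            len(self.encoders),
            init_rng,
            strategy=config.fusion,
        )

    @property
    def region_names(self) -> tuple[str, ...]:
        return tuple(self.encoders)

    def forward(self, x) -> Tensor:
        """(B, 19, T) microvolt windows -> (B, 2) class scores."""
        xt = as_tensor(np.asarray(x, dtype=np.float32) if not isinstance(x, Tensor) else x)
        filtered = self.mstf(xt)
        embeddings = [
            self.encoders[region](filtered[:, idx, :])
            for region, idx in self.region_indices.items()
        ]
        return self.head(T.stack(embeddings, axis=1))

    def predict(self, x, batch_size: int = 256) -> np.ndarray:
        """Hard labels (1 = MDD) in eval mode, without building the tape."""
        was_training = self.training
        self.eval()
        x = np.asarray(x, dtype=np.float32)
        out = []
        with no_grad():
            for i in range(0, len(x), batch_size):
                scores = self.forward(x[i : i + batch_size])
                out.append(np.argmax(scores.data, axis=1))
        if was_training:
            self.train()
        return np.concatenate(out) if out else np.empty(0, dtype=np.int64)
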