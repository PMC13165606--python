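"""19-channel 10-20 montage and brain-partition strategies.

The model operates on the classic 19-electrode 10-20 layout and groups
electrodes into region subgraphs before graph learning.  The reference
partition is the left/right hemispheric split with the midline electrodes
(Fz, Cz, Pz) shared by both hemispheres; anterior-posterior and four-region
splits are provided for ablations, plus a degenerate full-brain "partition".
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Montage",
    "RegionPartition",
    "MontageError",
    "normalize_channel",
    "standard_1020_montage",
    "build_partition",
    "channel_indices",
    "PARTITION_STRATEGIES",
]


class MontageError(KeyError):
    """A channel label cannot be resolved against the montage."""


#: Old/new 10-20 nomenclature equivalences (modern name -> legacy name used here).
CHANNEL_ALIASES = {
    "T7": "T3",
    "T8": "T4",
    "P7": "T5",
    "P8": "T6",
}

#: Canonical electrode order of the 19-channel montage.
STANDARD_19 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

_CANONICAL = {name.upper(): name for name in STANDARD_19}
_ALIASES_UPPER = {k.upper(): v for k, v in CHANNEL_ALIASES.items()}


def normalize_channel(label: str) -> str:
    """Map a channel label to its canonical montage spelling.

    Matching is case-insensitive and resolves legacy/modern 10-20 aliases
    (T7/T8/P7/P8 -> T3/T4/T5/T6).  Unknown labels are returned stripped but
    otherwise untouched so callers can produce a precise error.  Idempotent.
    """
    key = label.strip().upper()
    key = _ALIASES_UPPER.get(key, key).upper()
    return _CANONICAL.get(key, label.strip())


@dataclass(frozen=True)
class Montage:
    """An ordered set of electrode labels with a sampling rate."""

    channel_names: tuple[str, ...]
    sampling_rate: float = 256.0

    def __post_init__(self) -> None:
        names = tuple(normalize_channel(c) for c in self.channel_names)
        if len(set(names)) != len(names):
            raise MontageError("duplicate channel labels after normalization")
        object.__setattr__(self, "channel_names", names)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, label: str) -> int:
        name = normalize_channel(label)
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise MontageError(f"channel {label!r} not in montage") from None


def standard_1020_montage(sampling_rate: float = 256.0) -> Montage:
    """The 19-channel 10-20 montage (Fp1..O2) at 256 Hz by default."""
    return Montage(channel_names=STANDARD_19, sampling_rate=sampling_rate)


# Region definitions.  Midline electrodes are deliberately shared across
# hemispheres: they sit on the boundary and carry bilateral activity.
_LEFT = ("Fp1", "F7", "F3", "Fz", "T3", "C3", "Cz", "T5", "P3", "Pz", "O1")
_RIGHT = ("Fp2", "F8", "F4", "Fz", "T4", "C4", "Cz", "T6", "P4", "Pz", "O2")
_ANTERIOR = ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz", "C4", "T4")
_POSTERIOR = ("T5", "P3", "Pz", "P4", "T6", "O1", "O2", "Cz")

PARTITION_STRATEGIES = ("two_region", "four_region", "ap", "full_brain")


@dataclass(frozen=True)
class RegionPartition:
    """Named electrode groups defining per-region subgraphs."""

    strategy: str
    regions: dict[str, tuple[str, ...]]
    shared_channels: frozenset[str] = field(default_factory=frozenset)

    @property
    def region_names(self) -> tuple[str, ...]:
        return tuple(self.regions)

    def to_dict(self) -> dict:
        """Serializable form (region label -> electrode list)."""
        return {
            "strategy": self.strategy,
            "regions": {k: list(v) for k, v in self.regions.items()},
            "shared_channels": sorted(self.shared_channels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegionPartition":
        regions = {
            k: tuple(normalize_channel(c) for c in v) for k, v in d["regions"].items()
        }
        shared = frozenset(normalize_channel(c) for c in d.get("shared_channels", ()))
        if not d.get("shared_channels"):
            shared = _infer_shared(regions)
        return cls(strategy=d.get("strategy", "custom"), regions=regions, shared_channels=shared)


def _infer_shared(regions: dict[str, tuple[str, ...]]) -> frozenset[str]:
    seen: dict[str, int] = {}
    for chans in regions.values():
        for c in set(chans):
            seen[c] = seen.get(c, 0) + 1
    return frozenset(c for c, n in seen.items() if n > 1)


def build_partition(montage: Montage, strategy: str) -> RegionPartition:
    """Assign montage channels to region subgraphs.

    ``two_region``
        Left/right hemispheres, 11 electrodes each, sharing {Fz, Cz, Pz}.
    ``ap``
        Anterior/posterior split at the central line, sharing Cz.
    ``four_region``
        Pairwise intersections of hemisphere x anterior-posterior.
    ``full_brain``
        A single region with all 19 channels (no partition prior).
    """
    if strategy == "two_region":
        regions = {"left": _LEFT, "right": _RIGHT}
    elif strategy == "ap":
        regions = {"anterior": _ANTERIOR, "posterior": _POSTERIOR}
    elif strategy == "four_region":
        regions = {}
        for hname, hemi in (("left", _LEFT), ("right", _RIGHT)):
            for aname, ap in (("anterior", _ANTERIOR), ("posterior", _POSTERIOR)):
                regions[f"{aname}_{hname}"] = tuple(c for c in hemi if c in ap)
    elif strategy == "full_brain":
        regions = {"brain": montage.channel_names}
    else:
        raise ValueError(
            f"unknown partition strategy {strategy!r}; expected one of {PARTITION_STRATEGIES}"
        )
    regions = {k: tuple(v) for k, v in regions.items()}
    covered = set().union(*(set(v) for v in regions.values()))
    missing = set(montage.channel_names) - covered
    if missing:  # all strategies above cover the montage; guards custom edits
        raise MontageError(f"partition does not cover channels: {sorted(missing)}")
    return RegionPartition(
        strategy=strategy, regions=regions, shared_channels=_infer_shared(regions)
    )


def channel_indices(
    partition: RegionPartition, montage: Montage
) -> dict[str, list[int]]:
    """Resolve each region's electrode labels to montage row indices.

    Order follows the partition's electrode order.  Raises
    :class:`MontageError` naming the first unresolvable label.
    """
    return {
        region: [montage.index(label) for label in labels]
        for region, labels in partition.regions.items()
    }
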