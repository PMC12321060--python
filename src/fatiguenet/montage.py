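"""56-channel EEG montage and the ten cortical region groupings.

The montage mirrors a 64-channel 10-20 recording cap after bad-channel
removal: 56 retained scalp electrodes, grouped into ten named regions
(prefrontal through temporo-parietal) used to aggregate nodal network
metrics. The region → channel assignments are stored verbatim from the
source tables; the prefrontal row lists F1/FZ/F2, which also belong to
the frontal row — ``validate_montage`` surfaces that overlap as a warning
instead of silently renaming the labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Montage",
    "REGION_ORDER",
    "INFERRED_CHANNELS",
    "default_montage",
    "region_mask",
    "validate_montage",
]

#: Region names in fixed reporting order.
REGION_ORDER: tuple[str, ...] = (
    "prefrontal",
    "frontal",
    "fronto-central",
    "central",
    "centro-parietal",
    "parietal",
    "parieto-occipital",
    "occipital",
    "temporal",
    "temporo-parietal",
)

# Region → channels, transcribed from the published region tables.
_REGIONS: dict[str, tuple[str, ...]] = {
    "prefrontal": ("F1", "FZ", "F2"),
    "frontal": ("F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8"),
    "fronto-central": ("FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6"),
    "central": ("C5", "C3", "C1", "CZ", "C2", "C4", "C6"),
    "centro-parietal": ("CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6"),
    "parietal": ("P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8"),
    "parieto-occipital": ("PO7", "PO3", "POZ", "PO4", "PO8"),
    "occipital": ("O1", "OZ", "O2"),
    "temporal": ("T7", "T8"),
    "temporo-parietal": ("TP7", "TP8"),
}

#: Channels not listed in any region table; inferred standard 10-20 names
#: added to reach the 56 retained channels.
INFERRED_CHANNELS: tuple[str, ...] = ("FP1", "FPZ", "FP2", "FT7", "FT8")

_CHANNELS: tuple[str, ...] = (
    "FP1", "FPZ", "FP2",
    "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POZ", "PO4", "PO8",
    "O1", "OZ", "O2",
)


@dataclass(frozen=True)
class Montage:
    """Ordered channel labels plus named region groupings.

    Parameters
    ----------
    channels
        Ordered tuple of unique channel labels (recording order).
    regions
        Mapping of region name to the tuple of channel labels it contains.
        Every region label must appear in ``channels``.
    """

    channels: tuple[str, ...]
    regions: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        for name, chans in self.regions.items():
            missing = set(chans) - set(self.channels)
            if missing:
                raise ValueError(
                    f"region {name!r} references unknown channels: {sorted(missing)}"
                )

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def index(self, label: str) -> int:
        """Position of ``label`` in recording order."""
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None

    def to_json(self) -> str:
        return json.dumps(
            {"channels": list(self.channels),
             "regions": {k: list(v) for k, v in self.regions.items()}}
        )

    @classmethod
    def from_json(cls, text: str) -> "Montage":
        obj = json.loads(text)
        return cls(
            channels=tuple(obj["channels"]),
            regions={k: tuple(v) for k, v in obj["regions"].items()},
        )


def default_montage() -> Montage:
    """The 56-channel montage with the ten published region groupings."""
    return Montage(channels=_CHANNELS, regions=dict(_REGIONS))


def region_mask(montage: Montage, region: str) -> np.ndarray:
    """Channel indices (recording order) of one region.

    Raises
    ------
    KeyError
        If ``region`` is not one of the montage's region names.
    """
    if region not in montage.regions:
        raise KeyError(
            f"unknown region {region!r}; expected one of {sorted(montage.regions)}"
        )
    return np.array([montage.index(c) for c in montage.regions[region]], dtype=int)


def validate_montage(montage: Montage) -> list[str]:
    """Consistency warnings that do not invalidate the montage.

    Currently reports channel labels shared between regions (the published
    prefrontal row overlaps the frontal row) and any channel assigned to no
    region.
    """
    warnings: list[str] = []
    seen: dict[str, str] = {}
    for name in montage.regions:
        for ch in montage.regions[name]:
            if ch in seen:
                warnings.append(
                    f"channel {ch} appears in both {seen[ch]!r} and {name!r}"
                )
            else:
                seen[ch] = name
    unassigned = [c for c in montage.channels if c not in seen]
    if unassigned:
        warnings.append(f"channels in no region: {unassigned}")
    return warnings
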