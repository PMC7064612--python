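"""Staining-panel description.

The staining design uses three 8-colour antibody sets. Every set carries the
pooled lymphocyte-lineage channel (CD3/CD19/CD335 on one fluorochrome) plus
CD14 and CD16 so that the monocyte gating can be reproduced in each set; the
remaining five markers are unique to a set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping

from .errors import ConfigurationError

#: pooled CD3/CD19/CD335 exclusion channel
LINEAGE = "LIN"

SHARED_MARKERS = (LINEAGE, "CD14", "CD16")

SCATTER_COLUMNS = ("FSC-A", "FSC-H", "FSC-W", "SSC-A", "SSC-H", "SSC-W")

DEFAULT_STAINING_SETS: Dict[int, List[str]] = {
    1: ["CD64", "CD32", "CCR2", "CCR5", "CX3CR1"],
    2: ["CD80", "CD86", "HLA-DR", "CD163", "CD7"],
    3: ["CD62L", "CD162", "CD43", "CD49d", "CD56"],
}


@dataclass
class PanelConfig:
    """Marker layout of the staining sets.

    Parameters
    ----------
    staining_sets:
        Mapping set id -> list of set-specific marker names.
    channel_map:
        Bijection marker name -> event-table column name. Defaults to the
        identity map over all markers (shared + set-specific).
    """

    staining_sets: Dict[int, List[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_STAINING_SETS.items()}
    )
    channel_map: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_id, markers in self.staining_sets.items():
            if len(set(markers)) != len(markers):
                raise ConfigurationError(f"duplicate marker in staining set {set_id}")
            overlap = set(markers) & set(SHARED_MARKERS)
            if overlap:
                raise ConfigurationError(
                    f"set {set_id} lists shared markers explicitly: {sorted(overlap)}"
                )
        if not self.channel_map:
            self.channel_map = {m: m for m in self.all_markers()}
        values = list(self.channel_map.values())
        if len(set(values)) != len(values):
            raise ConfigurationError("channel_map is not a bijection")
        missing = set(self.all_markers()) - set(self.channel_map)
        if missing:
            raise ConfigurationError(f"channel_map missing markers: {sorted(missing)}")

    def all_markers(self) -> List[str]:
        out = list(SHARED_MARKERS)
        for markers in self.staining_sets.values():
            out.extend(markers)
        return out

    def markers_for_set(self, set_id: int) -> List[str]:
        """Shared markers plus the set-specific ones, in column order."""
        if set_id not in self.staining_sets:
            raise ConfigurationError(f"unknown staining set {set_id!r}")
        return list(SHARED_MARKERS) + list(self.staining_sets[set_id])

    def columns_for_set(self, set_id: int) -> List[str]:
        return list(SCATTER_COLUMNS) + [
            self.channel_map[m] for m in self.markers_for_set(set_id)
        ]

    def channel(self, marker: str) -> str:
        try:
            return self.channel_map[marker]
        except KeyError:
            raise ConfigurationError(f"marker {marker!r} not in panel") from None

    def to_dict(self) -> Mapping:
        return {
            "staining_sets": {str(k): v for k, v in self.staining_sets.items()},
            "channel_map": dict(self.channel_map),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PanelConfig":
        return cls(
            staining_sets={int(k): list(v) for k, v in d["staining_sets"].items()},
            channel_map=dict(d.get("channel_map", {})),
        )


def default_panel() -> PanelConfig:
    """The three-set panel used throughout the package."""
    return PanelConfig()
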