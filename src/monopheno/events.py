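"""Per-event table container — the pipeline's universal currency.

An :class:`EventTable` wraps a :class:`pandas.DataFrame` with one row per
acquired event. Columns are the six scatter pulse channels (FSC/SSC x
Area/Height/Width) plus one fluorescence column per panel channel; synthetic
tables additionally carry a hidden truth column recording the generating
population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .panel import SCATTER_COLUMNS, PanelConfig

#: hidden column holding the generating class of synthetic events
TRUTH_COLUMN = "__truth__"

ANTIBODY = "antibody"
ISOTYPE = "isotype"


@dataclass
class EventTable:
    """One acquisition tube: metadata plus the per-event value matrix."""

    data: pd.DataFrame
    donor_id: str
    set_id: int
    reagent: str = ANTIBODY

    def __post_init__(self) -> None:
        if self.reagent not in (ANTIBODY, ISOTYPE):
            raise ValidationError(f"reagent must be antibody/isotype, got {self.reagent!r}")
        missing = [c for c in SCATTER_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        value_cols = [c for c in self.data.columns if c != TRUTH_COLUMN]
        values = self.data[value_cols]
        if values.isna().any().any():
            raise FormatError("event table contains missing values")
        scatter = self.data[list(SCATTER_COLUMNS)].to_numpy()
        if np.any(scatter < 0):
            raise ValidationError("scatter values must be non-negative")

    # -- convenience -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def is_synthetic(self) -> bool:
        return TRUTH_COLUMN in self.data.columns

    @property
    def truth(self) -> Optional[pd.Series]:
        if not self.is_synthetic:
            return None
        return self.data[TRUTH_COLUMN]

    def channel_values(self, panel: PanelConfig, marker: str) -> np.ndarray:
        col = panel.channel(marker)
        if col not in self.data.columns:
            raise FormatError(f"missing required column(s): {col}")
        return self.data[col].to_numpy(dtype=float)

    def validate_against_panel(self, panel: PanelConfig) -> None:
        expected = panel.columns_for_set(self.set_id)
        missing = [c for c in expected if c not in self.data.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        known = set(expected) | {TRUTH_COLUMN}
        unknown = [c for c in self.data.columns if c not in known]
        if unknown:
            raise FormatError(f"unknown channel(s): {', '.join(unknown)}")

    def copy(self) -> "EventTable":
        return EventTable(
            data=self.data.copy(), donor_id=self.donor_id,
            set_id=self.set_id, reagent=self.reagent,
        )
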