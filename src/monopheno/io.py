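"""Event-table CSV dialect.

The normative on-disk format is plain CSV, UTF-8, ``.`` decimal separator:

* a header-comment block of ``# key=value`` lines carrying the table
  metadata (``donor_id``, ``set_id``, ``reagent``);
* one header row with the exact column names (scatter channels, one column
  per panel channel, optionally the hidden truth column);
* one row per event. Floats are written with Python's shortest round-trip
  representation, so ``read(write(t)) == t`` exactly.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .errors import FormatError
from .events import TRUTH_COLUMN, EventTable
from .panel import SCATTER_COLUMNS, PanelConfig

_META_PREFIX = "# "


def write_event_table(table: EventTable, path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"{_META_PREFIX}donor_id={table.donor_id}\n")
        fh.write(f"{_META_PREFIX}set_id={table.set_id}\n")
        fh.write(f"{_META_PREFIX}reagent={table.reagent}\n")
        table.data.to_csv(fh, index=False)


def read_event_table(path: Union[str, Path],
                     panel: Optional[PanelConfig] = None) -> EventTable:
    path = Path(path)
    meta = {}
    body_lines = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line.lstrip("#").strip().partition("=")
                meta[key.strip()] = value.strip()
            else:
                body_lines.append(line)
    if not body_lines:
        raise FormatError(f"{path}: no header row found")
    df = pd.read_csv(_io.StringIO("".join(body_lines)))
    for required in ("donor_id", "set_id", "reagent"):
        if required not in meta:
            raise FormatError(f"{path}: missing metadata line '# {required}=...'")
    missing = [c for c in SCATTER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    if TRUTH_COLUMN not in df.columns:
        value_cols = list(df.columns)
    else:
        value_cols = [c for c in df.columns if c != TRUTH_COLUMN]
    non_numeric = [c for c in value_cols
                   if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise FormatError(f"non-numeric value column(s): {', '.join(non_numeric)}")
    table = EventTable(data=df, donor_id=meta["donor_id"],
                       set_id=int(meta["set_id"]), reagent=meta["reagent"])
    if panel is not None:
        table.validate_against_panel(panel)
    return table
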