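"""JSON (de)serialization of the configuration objects.

``data/cohort_defaults.json`` carries the packaged default study conditions
(cohort composition, intensity models, imaging classes, gate and
quantitation policies) in one document; :func:`load_defaults` returns the
corresponding config objects, and any section can be overridden by an
external JSON file with the same layout.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from importlib import resources
from pathlib import Path
from typing import Dict, Optional, Union

from .gating import GateConfig
from .quantitation import QuantConfig
from .simulate import CohortConfig, ImagingConfig


def _gate_from_dict(d: Dict) -> GateConfig:
    d = dict(d)
    if "scatter_components" in d:
        d["scatter_components"] = tuple(d["scatter_components"])
    return GateConfig(**d)


def _quant_from_dict(d: Dict) -> QuantConfig:
    d = dict(d)
    if d.get("mfi_bins"):
        d["mfi_bins"] = {k: tuple(v) for k, v in d["mfi_bins"].items()}
    if "percent_bins" in d:
        d["percent_bins"] = tuple(d["percent_bins"])
    return QuantConfig(**d)


def dump_defaults(cohort: CohortConfig, imaging: ImagingConfig,
                  gate: GateConfig, quant: QuantConfig) -> Dict:
    return {
        "cohort": cohort.to_dict(),
        "imaging": imaging.to_dict(),
        "gate": asdict(gate),
        "quant": asdict(quant),
    }


def load_defaults(path: Optional[Union[str, Path]] = None) -> Dict[str, object]:
    """Load a full config document (packaged defaults when ``path`` is
    None); returns a dict with ``cohort``, ``imaging``, ``gate``, ``quant``
    config objects."""
    if path is None:
        raw = json.loads(resources.files("monopheno.data")
                         .joinpath("cohort_defaults.json").read_text())
    else:
        with open(path, "r", encoding="utf-8") as fh:
            raw = json.load(fh)
    out: Dict[str, object] = {}
    if "cohort" in raw:
        out["cohort"] = CohortConfig.from_dict(raw["cohort"])
    if "imaging" in raw:
        out["imaging"] = ImagingConfig.from_dict(raw["imaging"])
    if "gate" in raw:
        out["gate"] = _gate_from_dict(raw["gate"])
    if "quant" in raw:
        out["quant"] = _quant_from_dict(raw["quant"])
    return out
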