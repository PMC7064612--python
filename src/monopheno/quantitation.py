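"""Isotype-anchored marker quantitation.

For every (subpopulation, marker) pair this module computes the
positivity threshold (the value excluding a configured fraction — by
default 99% — of the matched isotype-control signal), the percent of
positive cells, and the specific MFI

    specific MFI = MFI(antibody) - MFI(isotype),

and maps both onto the qualitative nomenclature used to name expression
profiles: MFI bins dim/med/bri (subscript) and percent-positive bins
lo/int/hi (superscript), e.g. ``CD49d_bri^hi``. Negative specific MFI is
reported as-is and binned ``neg`` so that data problems stay visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError, ValidationError
from .events import EventTable
from .panel import LINEAGE, PanelConfig, default_panel

MFI_BINS = ("neg", "dim", "med", "bri")
PERCENT_BINS = ("neg", "lo", "int", "hi")

#: default fractions of the cohort 99th-percentile specific MFI at which the
#: dim/med/bri cutoffs sit
DEFAULT_MFI_CUTOFF_FRACTIONS = (0.05, 0.25, 0.60)


@dataclass
class QuantConfig:
    """Quantitation policies.

    ``mfi_bins`` maps marker -> (dim, med, bri) lower cutoffs in
    fluorescence units; when ``None`` the cutoffs must be derived from a
    cohort (see :func:`mfi_cutoffs_from_summaries`) before MFI bins can be
    assigned. ``percent_bins`` are the (lo, int, hi) lower cutoffs in
    percent.
    """

    isotype_exclusion: float = 0.99
    mfi_statistic: str = "mean"
    mfi_bins: Optional[Dict[str, Tuple[float, float, float]]] = None
    percent_bins: Tuple[float, float, float] = (10.0, 35.0, 70.0)
    min_events: int = 30
    min_isotype_events: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.isotype_exclusion < 1.0:
            raise ValidationError("isotype_exclusion must be in (0, 1)")
        if self.mfi_statistic not in ("mean", "median"):
            raise ConfigurationError(
                f"mfi_statistic must be 'mean' or 'median', got {self.mfi_statistic!r}")
        if list(self.percent_bins) != sorted(self.percent_bins) or \
                len(set(self.percent_bins)) != 3:
            raise ValidationError("percent_bins cutoffs must be strictly increasing")
        if self.mfi_bins:
            for marker, cuts in self.mfi_bins.items():
                if list(cuts) != sorted(cuts) or len(set(cuts)) != 3:
                    raise ValidationError(
                        f"mfi_bins cutoffs for {marker!r} must be strictly increasing")


@dataclass
class MarkerSummary:
    """Quantitation of one marker in one subpopulation of one donor."""

    donor_id: str
    subpopulation: str
    marker: str
    mfi_mab: float
    mfi_ig: float
    specific_mfi: float
    percent_positive: float
    n_events: int
    flag_low_n: bool
    mfi_bin: Optional[str] = None
    percent_bin: Optional[str] = None

    @property
    def notation(self) -> Optional[str]:
        """Combined subscript/superscript notation, e.g. ``CD49d_bri^hi``."""
        if self.mfi_bin is None or self.percent_bin is None:
            return None
        return f"{self.marker}_{self.mfi_bin}^{self.percent_bin}"


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def positivity_threshold(isotype_values: Sequence[float],
                         exclusion: float = 0.99,
                         min_events: int = 100) -> float:
    """Threshold excluding the configured fraction of the isotype signal.

    The empirical quantile uses linear interpolation; on heavily tied
    samples it is bumped to the next order statistic so that at most
    ``1 - exclusion`` of the isotype sample strictly exceeds it.
    """
    values = np.asarray(isotype_values, dtype=float)
    if len(values) < min_events:
        raise InsufficientDataError(
            f"positivity threshold needs >= {min_events} isotype events, got {len(values)}")
    threshold = float(np.quantile(values, exclusion))
    # discrete samples can defeat the interpolated quantile; bump to the
    # next order statistic until the exclusion contract holds
    if np.mean(values > threshold) > 1.0 - exclusion:
        threshold = float(np.quantile(values, exclusion, method="higher"))
    return threshold


def _statistic(values: np.ndarray, statistic: str) -> float:
    return float(np.median(values) if statistic == "median" else np.mean(values))


def specific_mfi(stained_values: Sequence[float], isotype_values: Sequence[float],
                 config: Optional[QuantConfig] = None) -> float:
    """MFI(antibody) - MFI(isotype); may be negative, never clipped."""
    config = config or QuantConfig()
    stained = np.asarray(stained_values, dtype=float)
    isotype = np.asarray(isotype_values, dtype=float)
    if len(stained) == 0 or len(isotype) == 0:
        raise InsufficientDataError("specific_mfi requires non-empty samples")
    return _statistic(stained, config.mfi_statistic) - \
        _statistic(isotype, config.mfi_statistic)


def percent_positive(stained_values: Sequence[float], threshold: float) -> float:
    """Percent of values at or above the threshold (closed lower bound)."""
    values = np.asarray(stained_values, dtype=float)
    if len(values) == 0:
        raise InsufficientDataError("percent_positive requires a non-empty sample")
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    return 100.0 * float(np.mean(values >= threshold))


def bin_expression(specific_mfi_value: float, percent_positive_value: float,
                   marker: str, config: QuantConfig) -> Tuple[str, str]:
    """Map (specific MFI, percent positive) onto the qualitative bins."""
    if config.mfi_bins is None or marker not in config.mfi_bins:
        raise ConfigurationError(f"no MFI bin cutoffs configured for {marker!r}")
    if not (np.isfinite(specific_mfi_value) and np.isfinite(percent_positive_value)):
        raise ValidationError("bin_expression requires finite inputs")
    lo, int_, hi = config.percent_bins
    if percent_positive_value < lo:
        pct_bin = "neg"
    elif percent_positive_value < int_:
        pct_bin = "lo"
    elif percent_positive_value < hi:
        pct_bin = "int"
    else:
        pct_bin = "hi"
    dim, med, bri = config.mfi_bins[marker]
    if specific_mfi_value <= 0 or specific_mfi_value < dim or pct_bin == "neg":
        mfi_bin = "neg"
    elif specific_mfi_value < med:
        mfi_bin = "dim"
    elif specific_mfi_value < bri:
        mfi_bin = "med"
    else:
        mfi_bin = "bri"
    return mfi_bin, pct_bin


# ---------------------------------------------------------------------------
# per-donor profiling
# ---------------------------------------------------------------------------

def _markers_for_summary(panel: PanelConfig, set_id: int) -> List[str]:
    return [m for m in panel.markers_for_set(set_id) if m != LINEAGE]


def profile_subpopulations(gate_result, stained: EventTable, isotype: EventTable,
                           panel: Optional[PanelConfig] = None,
                           config: Optional[QuantConfig] = None,
                           ) -> List[MarkerSummary]:
    """One :class:`MarkerSummary` per (subpopulation, marker) with >= 1 event.

    ``gate_result`` must come from gating the same donor and staining set;
    subpopulations below ``min_events`` are flagged low-n, mirroring the
    practice of not assessing marker expression on too few cells. MFI bins
    are left unset when no cutoffs are configured (derive them from the
    cohort with :func:`mfi_cutoffs_from_summaries` and re-bin with
    :func:`apply_bins`).
    """
    panel = panel or default_panel()
    config = config or QuantConfig()
    if stained.donor_id != isotype.donor_id or stained.set_id != isotype.set_id:
        raise ValidationError("stained/isotype tables are not a matched pair")
    if len(gate_result.labels) != len(stained.data):
        raise ValidationError("gate result does not match the stained table")

    markers = _markers_for_summary(panel, stained.set_id)
    labels = gate_result.labels
    out: List[MarkerSummary] = []
    iso_values = {m: isotype.channel_values(panel, m) for m in markers}
    thresholds = {
        m: positivity_threshold(iso_values[m], config.isotype_exclusion,
                                config.min_isotype_events)
        for m in markers
    }
    from .simulate import SUBPOPULATIONS  # local import avoids cycle at load

    for subpop in SUBPOPULATIONS:
        members = labels.index[labels == subpop]
        if len(members) == 0:
            continue
        sub = stained.data.loc[members]
        for marker in markers:
            col = panel.channel(marker)
            values = sub[col].to_numpy(dtype=float)
            s_mfi = specific_mfi(values, iso_values[marker], config)
            pct = percent_positive(values, thresholds[marker])
            summary = MarkerSummary(
                donor_id=stained.donor_id, subpopulation=subpop, marker=marker,
                mfi_mab=_statistic(values, config.mfi_statistic),
                mfi_ig=_statistic(np.asarray(iso_values[marker], dtype=float),
                                  config.mfi_statistic),
                specific_mfi=s_mfi, percent_positive=pct,
                n_events=len(values), flag_low_n=len(values) < config.min_events)
            if config.mfi_bins is not None and marker in config.mfi_bins:
                summary.mfi_bin, summary.percent_bin = bin_expression(
                    s_mfi, pct, marker, config)
            out.append(summary)
    return out


def mfi_cutoffs_from_summaries(summaries: Sequence[MarkerSummary],
                               fractions: Tuple[float, float, float]
                               = DEFAULT_MFI_CUTOFF_FRACTIONS,
                               ) -> Dict[str, Tuple[float, float, float]]:
    """Per-marker dim/med/bri cutoffs as fractions of the cohort
    99th-percentile specific MFI of that marker."""
    by_marker: Dict[str, List[float]] = {}
    for s in summaries:
        by_marker.setdefault(s.marker, []).append(s.specific_mfi)
    out = {}
    for marker, values in by_marker.items():
        ref = float(np.quantile(np.asarray(values, dtype=float), 0.99))
        if ref <= 0:
            ref = 1.0
        out[marker] = tuple(f * ref for f in fractions)
    return out


def apply_bins(summaries: Sequence[MarkerSummary], config: QuantConfig,
               ) -> List[MarkerSummary]:
    """Assign qualitative bins to already-computed summaries in place."""
    for s in summaries:
        s.mfi_bin, s.percent_bin = bin_expression(
            s.specific_mfi, s.percent_positive, s.marker, config)
    return list(summaries)


def summaries_to_frame(summaries: Sequence[MarkerSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append({
            "donor_id": s.donor_id, "subpopulation": s.subpopulation,
            "marker": s.marker, "mfi_mab": s.mfi_mab, "mfi_ig": s.mfi_ig,
            "specific_mfi": s.specific_mfi,
            "percent_positive": s.percent_positive,
            "mfi_bin": s.mfi_bin, "percent_bin": s.percent_bin,
            "n_events": s.n_events, "flag_low_n": s.flag_low_n,
            "notation": s.notation,
        })
    return pd.DataFrame(rows)
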