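"""Downstream quantitation utilities.

Small formulas used after the cytometry analysis: relative gene expression
by the 2^-ddCt method, cytokine concentrations normalized to 1e5 cells with
assay detection limits, and the cohort statistics (Mann-Whitney U, one-way
ANOVA, Wilson binomial-proportion confidence intervals at the 98% level).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .errors import ConfigurationError, ValidationError

CT_RANGE = (0.0, 45.0)

#: assay lower detection limits, pg/ml
DETECTION_LIMITS = {"TNF": 15.6, "IL-1b": 3.9}

#: default confidence level of the binomial-proportion interval
DEFAULT_CI_LEVEL = 0.98

NORMALIZATION_CELLS = 1.0e5


def _check_ct(*values: float) -> None:
    lo, hi = CT_RANGE
    for ct in values:
        if not np.isfinite(ct) or not lo < ct < hi:
            raise ValidationError(f"Ct value {ct} outside ({lo}, {hi})")


def delta_ct(ct_target: float, ct_reference) -> float:
    """ct_target - ct_reference; a sequence of reference Cts (several
    internal-control genes) is averaged before subtraction."""
    refs = np.atleast_1d(np.asarray(ct_reference, dtype=float))
    _check_ct(ct_target, *refs)
    return float(ct_target - refs.mean())


def ddct_fold_change(sample: Tuple[float, float],
                     calibrator: Tuple[float, float]) -> float:
    """Relative expression 2^-ddCt.

    Each argument is a (target Ct, reference Ct) pair; the reference Ct may
    itself be a sequence of internal-control Cts, which are averaged.
    """
    ddct = delta_ct(*sample) - delta_ct(*calibrator)
    return float(2.0 ** (-ddct))


@dataclass
class CytokineMeasurement:
    analyte: str
    raw_concentration: float        # pg/ml
    cell_count: float               # cells in the assayed culture
    normalized_concentration: float  # pg/ml per 1e5 cells
    below_lod: bool
    lod: float


def normalize_cytokine(raw: float, cell_count: float, analyte: str,
                       lod_table: Optional[Mapping[str, float]] = None,
                       ) -> CytokineMeasurement:
    """Scale a supernatant concentration to 1e5 cells and flag values under
    the assay detection limit (never imputed, reported as measured)."""
    lods = dict(DETECTION_LIMITS if lod_table is None else lod_table)
    if analyte not in lods:
        raise ConfigurationError(f"unknown analyte {analyte!r}; known: {sorted(lods)}")
    if cell_count <= 0:
        raise ValidationError(f"cell_count must be > 0, got {cell_count}")
    if raw < 0 or not np.isfinite(raw):
        raise ValidationError(f"raw concentration must be finite and >= 0, got {raw}")
    return CytokineMeasurement(
        analyte=analyte, raw_concentration=float(raw), cell_count=float(cell_count),
        normalized_concentration=float(raw * NORMALIZATION_CELLS / cell_count),
        below_lod=raw < lods[analyte], lod=float(lods[analyte]))


# ---------------------------------------------------------------------------
# cohort statistics
# ---------------------------------------------------------------------------

def mann_whitney(group_a: Sequence[float], group_b: Sequence[float],
                 exact_max_n: int = 20) -> Dict[str, float]:
    """Two-sided Mann-Whitney U; the exact null distribution is used for
    small samples without ties."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("Mann-Whitney requires two non-empty groups")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(a), len(b)) <= exact_max_n and not has_ties) \
        else "asymptotic"
    result = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {"statistic": float(result.statistic), "p_value": float(result.pvalue),
            "method": method}


def one_way_anova(groups: Sequence[Sequence[float]]) -> Dict[str, float]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) == 0 for g in arrays):
        raise ValidationError("ANOVA requires >= 2 non-empty groups")
    result = sps.f_oneway(*arrays)
    return {"statistic": float(result.statistic), "p_value": float(result.pvalue)}


def binomial_proportion_ci(k: int, n: int,
                           level: float = DEFAULT_CI_LEVEL) -> Dict[str, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0 or not 0 <= k <= n:
        raise ValidationError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    if not 0.0 < level < 1.0:
        raise ValidationError("confidence level must be in (0, 1)")
    lower, upper = proportion_confint(k, n, alpha=1.0 - level, method="wilson")
    return {"proportion": k / n, "lower": float(lower), "upper": float(upper),
            "level": level}


def cohort_stats(groups, test: str = "mann_whitney", **kwargs) -> Dict[str, float]:
    """Dispatch to the configured cohort test.

    ``groups`` is a mapping/sequence of numeric samples for the rank/ANOVA
    tests, or a ``(k, n)`` pair of counts for ``binomial_ci``.
    """
    if test == "mann_whitney":
        samples = list(groups.values()) if isinstance(groups, Mapping) else list(groups)
        if len(samples) != 2:
            raise ValidationError("mann_whitney requires exactly 2 groups")
        return mann_whitney(samples[0], samples[1], **kwargs)
    if test == "anova":
        samples = list(groups.values()) if isinstance(groups, Mapping) else list(groups)
        return one_way_anova(samples)
    if test == "binomial_ci":
        k, n = groups
        return binomial_proportion_ci(int(k), int(n), **kwargs)
    raise ConfigurationError(f"unknown test {test!r}")
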