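"""Packaged default parameters for the synthetic cohort.

The default cohort emulates the study conditions the pipeline was built for:
28 healthy donors, three staining sets, six CD14/CD16-defined monocyte
subpopulations at the published cohort frequencies, per-marker log-normal
intensities realizing one representative expression profile per
subpopulation, isotype background channels, doublets, and the off-cluster
event smear that manual polygon gates leave unlabelled.

All intensities are in arbitrary fluorescence units on a four-decade scale;
"sigma" values are standard deviations of the natural log.
"""

from __future__ import annotations

import math
from typing import Dict

# ---------------------------------------------------------------------------
# shared intensity scale
# ---------------------------------------------------------------------------

#: unstained-channel background in antibody tubes (log-normal median, log-sd)
BACKGROUND = {"median": 30.0, "sigma": 0.4}

#: isotype-control background; slightly broader than the unstained-channel
#: background, as isotype reagents capture Fc-mediated nonspecific binding
ISOTYPE_BACKGROUND = {"median": 30.0, "sigma": 0.5}

_BG_MEAN = BACKGROUND["median"] * math.exp(BACKGROUND["sigma"] ** 2 / 2)

#: stained-channel log-sd
STAIN_SIGMA = 0.35

#: fraction of events drawn from the stained (positive) component per
#: percent-positive bin
POSITIVE_FRACTION = {"hi": 0.90, "int": 0.50, "lo": 0.22, "neg": 0.03}

#: population-level specific MFI the generator aims at per MFI bin
SPECIFIC_MFI_TARGET = {"bri": 2850.0, "med": 1140.0, "dim": 370.0}


def marker_model(mfi_bin: str, pct_bin: str) -> Dict[str, float]:
    """Log-normal stain model whose measured specific MFI and percent
    positive land in the requested qualitative bins.

    The measured population MFI averages positives and background, so the
    positive-component median is back-computed from the target specific MFI
    and the positive fraction.
    """
    if mfi_bin == "neg" or pct_bin == "neg":
        return {"median": BACKGROUND["median"], "sigma": BACKGROUND["sigma"],
                "pos_fraction": 0.0}
    pos = POSITIVE_FRACTION[pct_bin]
    stained_mean = SPECIFIC_MFI_TARGET[mfi_bin] / pos + _BG_MEAN
    median = stained_mean / math.exp(STAIN_SIGMA ** 2 / 2)
    return {"median": median, "sigma": STAIN_SIGMA, "pos_fraction": pos}


# ---------------------------------------------------------------------------
# cohort composition (published cohort means and between-donor SDs)
# ---------------------------------------------------------------------------

CLUSTER_FRACTIONS = {          # of CD14+ cells; remainder -> scatter_other
    "small": [0.784, 0.140],
    "large": [0.088, 0.060],
}

SMALL_FRACTIONS = {            # of small-cluster cells; remainder -> sm_smear
    "sm14+16neg": [0.772, 0.130],
    "sm14+16+": [0.044, 0.023],
    "sm14dim16+": [0.032, 0.026],
    "sm14dim16neg": [0.024, 0.015],
}

LARGE_FRACTIONS = {            # of large-cluster cells; remainder split
    "la14+16neg": [0.792, 0.100],   # between la_dim and la_smear
    "la14+16+": [0.100, 0.052],
}

#: the CD14dim/CD16neg subpopulation is present in 16 of the 28 donors
DIM16NEG_DONORS = list(range(1, 17))

#: between-donor SDs of the remainder ("unassigned") masses at each level;
#: the dominant fraction of a level is the complement of the independently
#: drawn minor and remainder fractions, so every configured mean is exact
SCATTER_OTHER_SD = 0.10
SM_SMEAR_SD = 0.10
LA_REMAINDER_SD = 0.05

LINEAGE_FRACTION = 0.60        # lymphocytes among acquired events
CD14NEG_FRACTION = 0.10        # lineage-negative, CD14-negative events
DOUBLET_RATE = 0.02

# ---------------------------------------------------------------------------
# scatter models (arbitrary scatter units; log-normal)
# ---------------------------------------------------------------------------

SCATTER_MODELS = {
    "lymphocyte":    {"fsc_median": 5.0e4, "fsc_sigma": 0.15, "ssc_median": 1.5e4, "ssc_sigma": 0.20},
    "cd14neg":       {"fsc_median": 8.0e4, "fsc_sigma": 0.25, "ssc_median": 3.0e4, "ssc_sigma": 0.30},
    "scatter_other": {"fsc_median": 1.3e5, "fsc_sigma": 0.25, "ssc_median": 4.0e5, "ssc_sigma": 0.20},
    "small":         {"fsc_median": 1.0e5, "fsc_sigma": 0.12, "ssc_median": 6.0e4, "ssc_sigma": 0.15},
    "large":         {"fsc_median": 2.2e5, "fsc_sigma": 0.12, "ssc_median": 1.1e5, "ssc_sigma": 0.15},
}

CLASS_SCATTER = {
    "lymphocyte": "lymphocyte",
    "cd14neg": "cd14neg",
    "scatter_other": "scatter_other",
    "sm14+16neg": "small", "sm14+16+": "small", "sm14dim16+": "small",
    "sm14dim16neg": "small", "sm_smear": "small",
    "la14+16neg": "large", "la14+16+": "large", "la_dim": "large",
    "la_smear": "large",
}

# pulse-geometry parameters: height tracks area, width is narrow for singlets
HEIGHT_RATIO = 0.95
HEIGHT_JITTER = 0.03
WIDTH_MEDIAN = 7.0e4
WIDTH_SIGMA = 0.05
DOUBLET_WIDTH_FACTOR = 1.8

# ---------------------------------------------------------------------------
# lineage / CD14 / CD16 models per generating class (missing channel -> bg)
# ---------------------------------------------------------------------------

CORE_MODELS = {
    "lymphocyte":    {"LIN": [5000.0, 0.40]},
    "scatter_other": {"CD14": [5000.0, 0.35], "CD16": [5.0e4, 0.35]},
    "sm14+16neg":    {"CD14": [5000.0, 0.35]},
    "sm14+16+":      {"CD14": [5000.0, 0.35], "CD16": [800.0, 0.45]},
    "sm14dim16+":    {"CD14": [300.0, 0.30], "CD16": [2000.0, 0.45]},
    "sm14dim16neg":  {"CD14": [300.0, 0.30]},
    "sm_smear":      {"CD14": [5000.0, 0.35], "CD16": [5.0e4, 0.35]},
    "la14+16neg":    {"CD14": [10000.0, 0.35]},
    "la14+16+":      {"CD14": [10000.0, 0.35], "CD16": [800.0, 0.45]},
    "la_dim":        {"CD14": [300.0, 0.30]},
    "la_smear":      {"CD14": [10000.0, 0.35], "CD16": [5.0e4, 0.35]},
}

# ---------------------------------------------------------------------------
# set-specific marker models: one representative expression profile per
# subpopulation, written as (MFI bin, percent bin) pairs
# ---------------------------------------------------------------------------

_PROFILE_BINS = {
    # representative profile OP-01
    "sm14+16neg": {
        "CD64": ("bri", "hi"), "CD32": ("bri", "hi"), "CCR2": ("bri", "hi"),
        "CCR5": ("dim", "lo"), "CX3CR1": ("dim", "lo"),
        "CD80": ("dim", "lo"), "CD86": ("med", "int"), "HLA-DR": ("bri", "hi"),
        "CD163": ("med", "int"), "CD7": ("dim", "lo"),
        "CD62L": ("bri", "hi"), "CD162": ("bri", "hi"), "CD43": ("med", "hi"),
        "CD49d": ("bri", "hi"), "CD56": ("dim", "lo"),
    },
    # representative profile OP-10; stronger HLA-DR/CD86/CD163 than sm14+16neg
    "la14+16neg": {
        "CD64": ("bri", "hi"), "CD32": ("bri", "hi"), "CCR2": ("bri", "hi"),
        "CCR5": ("dim", "lo"), "CX3CR1": ("med", "int"),
        "CD80": ("dim", "lo"), "CD86": ("bri", "hi"), "HLA-DR": ("bri", "hi"),
        "CD163": ("bri", "hi"), "CD7": ("dim", "lo"),
        "CD62L": ("bri", "hi"), "CD162": ("bri", "hi"), "CD43": ("dim", "hi"),
        "CD49d": ("bri", "hi"), "CD56": ("dim", "lo"),
    },
    # CD43/CD49d/CD62L come from the per-donor component mixture (Table-2
    # compositions); the remaining markers follow the intermediate-like
    # phenotype (CCR5+, strong CX3CR1)
    "sm14+16+": {
        "CD64": ("bri", "hi"), "CD32": ("bri", "hi"), "CCR2": ("med", "int"),
        "CCR5": ("med", "int"), "CX3CR1": ("bri", "hi"),
        "CD80": ("dim", "lo"), "CD86": ("bri", "hi"), "HLA-DR": ("bri", "hi"),
        "CD163": ("med", "int"), "CD7": ("dim", "lo"),
        "CD162": ("bri", "hi"), "CD56": ("dim", "lo"),
    },
    # representative profile OP-33 (bright adhesion molecules incl. CD43)
    "la14+16+": {
        "CD64": ("bri", "hi"), "CD32": ("bri", "hi"), "CCR2": ("bri", "hi"),
        "CCR5": ("med", "int"), "CX3CR1": ("bri", "hi"),
        "CD80": ("dim", "lo"), "CD86": ("bri", "hi"), "HLA-DR": ("bri", "hi"),
        "CD163": ("bri", "hi"), "CD7": ("dim", "lo"),
        "CD62L": ("bri", "hi"), "CD162": ("bri", "hi"), "CD43": ("bri", "hi"),
        "CD49d": ("bri", "hi"), "CD56": ("med", "int"),
    },
    # representative profile OP-40 (non-classical-like: CX3CR1 bright, CCR2 low)
    "sm14dim16+": {
        "CD64": ("med", "int"), "CD32": ("bri", "hi"), "CCR2": ("dim", "lo"),
        "CCR5": ("dim", "lo"), "CX3CR1": ("bri", "hi"),
        "CD80": ("dim", "lo"), "CD86": ("med", "int"), "HLA-DR": ("bri", "hi"),
        "CD163": ("dim", "lo"), "CD7": ("dim", "lo"),
        "CD62L": ("med", "int"), "CD162": ("bri", "hi"), "CD43": ("dim", "hi"),
        "CD49d": ("bri", "hi"), "CD56": ("dim", "lo"),
    },
    # representative profile OP-50 (globally low adhesion; HLA-DR kept,
    # CD86 scant)
    "sm14dim16neg": {
        "CD64": ("med", "int"), "CD32": ("bri", "hi"), "CCR2": ("dim", "lo"),
        "CCR5": ("dim", "lo"), "CX3CR1": ("dim", "lo"),
        "CD80": ("dim", "lo"), "CD86": ("neg", "neg"), "HLA-DR": ("bri", "hi"),
        "CD163": ("dim", "lo"), "CD7": ("dim", "lo"),
        "CD62L": ("dim", "int"), "CD162": ("dim", "lo"), "CD43": ("dim", "lo"),
        "CD49d": ("med", "hi"), "CD56": ("neg", "neg"),
    },
}


def default_marker_models() -> Dict[str, Dict[str, Dict[str, float]]]:
    return {
        subpop: {m: marker_model(*bins) for m, bins in table.items()}
        for subpop, table in _PROFILE_BINS.items()
    }


# ---------------------------------------------------------------------------
# CD43/CD49d/CD62L component subpopulations of sm14+16+ cells
# ---------------------------------------------------------------------------

#: log-normal modes used for the three-level component space; the dim/hi
#: split used downstream is the geometric midpoint of the two stained modes
COMPONENT_DIM_MODE = 300.0
COMPONENT_HI_MODE = 3000.0
COMPONENT_SIGMA = 0.30

COMPONENT_MODELS = {
    # CD43+ CD49d+ CD62Lhi
    "P1":      {"CD43": 3000.0, "CD49d": 3000.0, "CD62L": 3000.0},
    # CD43dim/neg CD49dhi CD62Ldim
    "P2":      {"CD43": 150.0, "CD49d": 3000.0, "CD62L": 300.0},
    # CD43neg CD49ddim CD62Lhi
    "P3":      {"CD43": 30.0, "CD49d": 300.0, "CD62L": 3000.0},
    # intermediate between P1 and P2, variable CD43
    "Pint":    {"CD43": 300.0, "CD49d": 3000.0, "CD62L": 3000.0},
    # donor-10 major population: CD43+ CD49dhi CD62Ldim
    "E_major": {"CD43": 3000.0, "CD49d": 3000.0, "CD62L": 300.0},
    # donor-10 minor population: CD43hi CD49dhi CD62Lhi (falls in the P1 box)
    "E_minor": {"CD43": 3000.0, "CD49d": 3000.0, "CD62L": 3000.0},
}

VISNE_WEIGHTS = {
    "a": {"P1": 0.40, "P2": 0.35, "P3": 0.25},
    "b": {"P2": 0.60, "P3": 0.40},
    "c": {"P1": 0.40, "Pint": 0.25, "P2": 0.35},
    "d": {"P1": 0.55, "P2": 0.45},
    "e": {"E_major": 0.80, "E_minor": 0.20},
}

#: donor -> profile assignments as published; donors without a listed
#: profile (5, 11, 26, 27, 28) are generated with the commonest profile "a"
VISNE_PROFILES = {
    **{d: "a" for d in (2, 4, 8, 14, 15, 16, 19, 21, 25)},
    **{d: "b" for d in (1, 3, 6, 12, 13)},
    **{d: "c" for d in (7, 9, 22, 23)},
    **{d: "d" for d in (17, 18, 20, 24)},
    10: "e",
    **{d: "a" for d in (5, 11, 26, 27, 28)},
}

# ---------------------------------------------------------------------------
# imaging defaults: mask areas chosen so the circle-equivalent diameters of
# the singlet classes are 11.98 um (small) and 12.84 um (large)
# ---------------------------------------------------------------------------

SMALL_DIAMETER_UM = 11.98
LARGE_DIAMETER_UM = 12.84

IMAGING_CLASSES = {
    "small_singlet": {
        "mean_area": math.pi * (SMALL_DIAMETER_UM / 2) ** 2,  # ~112.7 um^2
        "area_cv": 0.15, "ar_mean": 0.95, "ar_sd": 0.03,
    },
    "large_singlet": {
        "mean_area": math.pi * (LARGE_DIAMETER_UM / 2) ** 2,  # ~129.5 um^2
        "area_cv": 0.15, "ar_mean": 0.95, "ar_sd": 0.03,
    },
    "doublet": {
        "mean_area": 225.0, "area_cv": 0.20, "ar_mean": 0.55, "ar_sd": 0.08,
    },
}

IMAGING_N_OBJECTS = {"small_singlet": 1000, "large_singlet": 1000, "doublet": 300}
IMAGING_DOUBLET_CONTAMINATION = 0.03
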