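"""Synthetic cytometry cohort generator.

Generates per-donor event tables (one stained and one matched isotype-control
table per staining set) with the statistical structure the downstream
analysis assumes: a lymphocyte lineage compartment, CD14-negative events,
six CD14/CD16-defined monocyte subpopulations split over a small and a large
scatter cluster, off-cluster/smear events that manual polygon gates leave
out, and doublets synthesized from pairs of singlets with pulse-geometry
signatures (summed areas, peak-held heights, widened widths).

Every generated value is a deterministic function of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import defaults
from .errors import ConfigurationError, ValidationError
from .events import ANTIBODY, ISOTYPE, TRUTH_COLUMN, EventTable
from .panel import LINEAGE, SCATTER_COLUMNS, PanelConfig, default_panel

SUBPOPULATIONS = (
    "sm14+16neg", "sm14+16+", "sm14dim16+", "sm14dim16neg",
    "la14+16neg", "la14+16+",
)

SMALL_SUBPOPULATIONS = SUBPOPULATIONS[:4]
LARGE_SUBPOPULATIONS = SUBPOPULATIONS[4:]

#: truth label for synthesized doublet events
DOUBLET = "doublet"

MIN_EVENTS = 1000


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Cohort composition and intensity models.

    Fraction entries are ``[cohort mean, between-donor SD]``; per-donor
    values are clipped normal draws, so an SD of 0 fixes the fraction
    exactly. Remainders at each level become concrete "unassigned" truth
    classes (``scatter_other``, ``sm_smear``, ``la_dim``/``la_smear``).
    """

    n_donors: int = 28
    events_per_donor: int = 100_000
    isotype_events: int = 20_000
    lineage_fraction: float = defaults.LINEAGE_FRACTION
    cd14neg_fraction: float = defaults.CD14NEG_FRACTION
    doublet_rate: float = defaults.DOUBLET_RATE
    cluster_fractions: Dict[str, List[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in defaults.CLUSTER_FRACTIONS.items()})
    small_fractions: Dict[str, List[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in defaults.SMALL_FRACTIONS.items()})
    large_fractions: Dict[str, List[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in defaults.LARGE_FRACTIONS.items()})
    scatter_other_sd: float = defaults.SCATTER_OTHER_SD
    sm_smear_sd: float = defaults.SM_SMEAR_SD
    la_remainder_sd: float = defaults.LA_REMAINDER_SD
    dim16neg_donors: List[int] = field(
        default_factory=lambda: list(defaults.DIM16NEG_DONORS))
    scatter_models: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in defaults.SCATTER_MODELS.items()})
    class_scatter: Dict[str, str] = field(
        default_factory=lambda: dict(defaults.CLASS_SCATTER))
    background: Dict[str, float] = field(
        default_factory=lambda: dict(defaults.BACKGROUND))
    isotype_background: Dict[str, float] = field(
        default_factory=lambda: dict(defaults.ISOTYPE_BACKGROUND))
    core_models: Dict[str, Dict[str, List[float]]] = field(
        default_factory=lambda: {k: {m: list(v) for m, v in t.items()}
                                 for k, t in defaults.CORE_MODELS.items()})
    marker_models: Dict[str, Dict[str, Dict[str, float]]] = field(
        default_factory=defaults.default_marker_models)
    component_models: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in defaults.COMPONENT_MODELS.items()})
    component_sigma: float = defaults.COMPONENT_SIGMA
    visne_weights: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in defaults.VISNE_WEIGHTS.items()})
    visne_profiles: Dict[int, str] = field(
        default_factory=lambda: dict(defaults.VISNE_PROFILES))
    seed: int = 1

    def __post_init__(self) -> None:
        if self.events_per_donor < MIN_EVENTS:
            raise ValidationError(
                f"events_per_donor must be >= {MIN_EVENTS}, got {self.events_per_donor}")
        if self.isotype_events < MIN_EVENTS:
            raise ValidationError(
                f"isotype_events must be >= {MIN_EVENTS}, got {self.isotype_events}")
        for name, value in (("lineage_fraction", self.lineage_fraction),
                            ("cd14neg_fraction", self.cd14neg_fraction),
                            ("doublet_rate", self.doublet_rate)):
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {value}")
        if self.lineage_fraction + self.cd14neg_fraction >= 1.0:
            raise ValidationError("lineage_fraction + cd14neg_fraction must be < 1")
        for table in (self.cluster_fractions, self.small_fractions, self.large_fractions):
            for key, (mean, sd) in table.items():
                if not 0.0 <= mean <= 1.0 or sd < 0.0:
                    raise ValidationError(f"bad fraction spec for {key!r}: {[mean, sd]}")
        for profile in self.visne_profiles.values():
            if profile not in self.visne_weights:
                raise ConfigurationError(f"unknown component profile {profile!r}")

    def to_dict(self) -> Mapping:
        d = asdict(self)
        d["visne_profiles"] = {str(k): v for k, v in self.visne_profiles.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "visne_profiles" in d:
            d["visne_profiles"] = {int(k): v for k, v in d["visne_profiles"].items()}
        if "core_models" in d:
            d["core_models"] = {k: {m: list(v) for m, v in t.items()}
                                for k, t in d["core_models"].items()}
        return cls(**d)


@dataclass
class ImagingConfig:
    """Synthetic imaging-object generator parameters.

    Mask areas are in square micrometres; the aspect-ratio model of the
    doublet class must sit below the singlet models so that the generated
    aspect-ratio histogram is bimodal by construction.
    """

    classes: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in defaults.IMAGING_CLASSES.items()})
    n_objects: Dict[str, int] = field(
        default_factory=lambda: dict(defaults.IMAGING_N_OBJECTS))
    doublet_contamination: float = defaults.IMAGING_DOUBLET_CONTAMINATION
    seed: int = 1

    def __post_init__(self) -> None:
        singlet_means = [m["ar_mean"] for k, m in self.classes.items() if k != "doublet"]
        for name, model in self.classes.items():
            if model["mean_area"] <= 0:
                raise ValidationError(f"mean_area for {name!r} must be > 0")
            if not 0 < model["ar_mean"] <= 1:
                raise ValidationError(f"ar_mean for {name!r} must be in (0, 1]")
        if "doublet" in self.classes and singlet_means:
            if self.classes["doublet"]["ar_mean"] >= min(singlet_means):
                raise ValidationError(
                    "doublet aspect-ratio model must sit below the singlet models")
        for name, n in self.n_objects.items():
            if n < 0:
                raise ValidationError(f"n_objects for {name!r} must be >= 0")

    def to_dict(self) -> Mapping:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ImagingConfig":
        return cls(**dict(d))


@dataclass
class DonorSample:
    """All tables generated for one donor: set id -> table."""

    donor_id: int
    stained: Dict[int, EventTable]
    isotype: Dict[int, EventTable]


# ---------------------------------------------------------------------------
# composition draws
# ---------------------------------------------------------------------------

def _symmetric_clip(rng: np.random.Generator, mean: float, sd: float,
                    hard_lo: float, hard_hi: float) -> float:
    """Normal draw clipped symmetrically around its mean so the clipping
    is mean-preserving (the cohort mean equals the configured mean)."""
    half = min(mean - hard_lo, hard_hi - mean)
    if half <= 0:
        return float(np.clip(mean, hard_lo, hard_hi))
    if sd == 0.0:
        return float(mean)
    return float(np.clip(rng.normal(mean, sd), mean - half, mean + half))


def donor_composition(config: CohortConfig, donor: int) -> Dict[str, float]:
    """Per-donor singlet class probabilities (deterministic in seed/donor).

    At each composition level the minor fractions and the remainder
    ("unassigned") mass are drawn independently with mean-preserving
    symmetric clips, and the dominant fraction is their complement, so every
    configured cohort mean is realized exactly. The configured SD of a
    dominant fraction is therefore informational (implied by the others).
    """
    rng = np.random.default_rng([config.seed, 90_000 + donor])
    # the large cluster is visible in every donor: floor its fraction at 2%
    f_large = _symmetric_clip(rng, *config.cluster_fractions["large"], 0.02, 0.50)
    other_mean = 1.0 - config.cluster_fractions["small"][0] \
        - config.cluster_fractions["large"][0]
    f_other = _symmetric_clip(rng, other_mean, config.scatter_other_sd, 0.005, 1.0)
    f_small = 1.0 - f_large - f_other

    main_small = "sm14+16neg"
    small = {}
    applicable_means = 0.0
    for name, (mean, sd) in config.small_fractions.items():
        if name == main_small:
            continue
        if name == "sm14dim16neg" and donor not in config.dim16neg_donors:
            small[name] = 0.0
        else:
            small[name] = _symmetric_clip(rng, mean, sd, 0.001, 1.0)
            applicable_means += mean
    smear_mean = 1.0 - config.small_fractions[main_small][0] - applicable_means
    small["sm_smear"] = _symmetric_clip(rng, smear_mean, config.sm_smear_sd,
                                        0.005, 1.0)
    small[main_small] = 1.0 - sum(small.values())

    main_large = "la14+16neg"
    large = {}
    minor_means = 0.0
    for name, (mean, sd) in config.large_fractions.items():
        if name == main_large:
            continue
        large[name] = _symmetric_clip(rng, mean, sd, 0.002, 1.0)
        minor_means += mean
    rem_mean = 1.0 - config.large_fractions[main_large][0] - minor_means
    remainder = _symmetric_clip(rng, rem_mean, config.la_remainder_sd, 0.005, 1.0)
    large["la_dim"] = remainder / 2.0
    large["la_smear"] = remainder / 2.0
    large[main_large] = 1.0 - sum(large.values())

    mono = 1.0 - config.lineage_fraction - config.cd14neg_fraction
    probs = {
        "lymphocyte": config.lineage_fraction,
        "cd14neg": config.cd14neg_fraction,
        "scatter_other": mono * f_other,
    }
    for name, frac in small.items():
        probs[name] = mono * f_small * frac
    for name, frac in large.items():
        probs[name] = mono * f_large * frac
    return probs


# ---------------------------------------------------------------------------
# event synthesis
# ---------------------------------------------------------------------------

def _lognormal(rng: np.random.Generator, median: float, sigma: float,
               n: int) -> np.ndarray:
    return median * np.exp(sigma * rng.standard_normal(n))


def _scatter_block(rng: np.random.Generator, model: Mapping[str, float],
                   n: int) -> Dict[str, np.ndarray]:
    fsc_a = _lognormal(rng, model["fsc_median"], model["fsc_sigma"], n)
    ssc_a = _lognormal(rng, model["ssc_median"], model["ssc_sigma"], n)
    out = {
        "FSC-A": fsc_a,
        "FSC-H": defaults.HEIGHT_RATIO * fsc_a
        * np.exp(defaults.HEIGHT_JITTER * rng.standard_normal(n)),
        "FSC-W": _lognormal(rng, defaults.WIDTH_MEDIAN, defaults.WIDTH_SIGMA, n),
        "SSC-A": ssc_a,
        "SSC-H": defaults.HEIGHT_RATIO * ssc_a
        * np.exp(defaults.HEIGHT_JITTER * rng.standard_normal(n)),
        "SSC-W": _lognormal(rng, defaults.WIDTH_MEDIAN, defaults.WIDTH_SIGMA, n),
    }
    return out


def _marker_values(rng: np.random.Generator, model: Optional[Mapping[str, float]],
                   background: Mapping[str, float], n: int) -> np.ndarray:
    bg = _lognormal(rng, background["median"], background["sigma"], n)
    if model is None or model.get("pos_fraction", 0.0) <= 0.0:
        return bg
    pos = rng.random(n) < model["pos_fraction"]
    stained = _lognormal(rng, model["median"], model["sigma"], n)
    return np.where(pos, stained, bg)


def simulate_component_events(weights: Mapping[str, float], n: int,
                              rng: np.random.Generator | int,
                              component_models: Optional[Mapping] = None,
                              sigma: float = defaults.COMPONENT_SIGMA,
                              ) -> pd.DataFrame:
    """Draw adhesion-marker triplets (CD43, CD49d, CD62L) from a mixture of
    component subpopulations; the truth column records the component."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    models = component_models or defaults.COMPONENT_MODELS
    names = sorted(weights)
    p = np.array([weights[k] for k in names], dtype=float)
    if np.any(p < 0) or p.sum() <= 0:
        raise ValidationError("component weights must be non-negative, sum > 0")
    p = p / p.sum()
    comp_idx = rng.choice(len(names), size=n, p=p)
    data = {}
    for marker in ("CD43", "CD49d", "CD62L"):
        medians = np.array([models[name][marker] for name in names])
        data[marker] = medians[comp_idx] * np.exp(sigma * rng.standard_normal(n))
    data[TRUTH_COLUMN] = np.array(names, dtype=object)[comp_idx]
    return pd.DataFrame(data)


def _class_block(rng: np.random.Generator, cls: str, n: int, donor: int,
                 markers: Sequence[str], config: CohortConfig,
                 stained: bool) -> pd.DataFrame:
    scatter_key = config.class_scatter.get(cls)
    if scatter_key is None:
        raise ConfigurationError(f"no scatter model mapped for class {cls!r}")
    cols = _scatter_block(rng, config.scatter_models[scatter_key], n)

    core = config.core_models.get(cls, {}) if stained else {}
    component_markers: List[str] = []
    if stained and cls == "sm14+16+":
        component_markers = [m for m in markers
                             if m in next(iter(config.component_models.values()))]
    comp_values: Optional[pd.DataFrame] = None
    if component_markers:
        profile = config.visne_profiles.get(donor, "a")
        comp_values = simulate_component_events(
            config.visne_weights[profile], n, rng,
            component_models=config.component_models,
            sigma=config.component_sigma)

    background = config.background if stained else config.isotype_background
    for marker in markers:
        if marker in core:
            median, sigma = core[marker]
            cols[marker] = _lognormal(rng, median, sigma, n)
        elif comp_values is not None and marker in component_markers:
            cols[marker] = comp_values[marker].to_numpy()
        else:
            model = config.marker_models.get(cls, {}).get(marker) if stained else None
            cols[marker] = _marker_values(rng, model, background, n)
    return pd.DataFrame(cols)


def _generate_for_labels(rng: np.random.Generator, labels: np.ndarray,
                         donor: int, markers: Sequence[str],
                         config: CohortConfig, stained: bool) -> pd.DataFrame:
    """Generate one row per label, preserving label order."""
    order = np.argsort(labels, kind="stable")
    sorted_labels = labels[order]
    parts = []
    # contiguous runs of each class after the stable sort
    boundaries = np.flatnonzero(np.r_[True, sorted_labels[1:] != sorted_labels[:-1]])
    boundaries = np.r_[boundaries, len(sorted_labels)]
    for start, stop in zip(boundaries[:-1], boundaries[1:]):
        cls = sorted_labels[start]
        parts.append(_class_block(rng, cls, stop - start, donor, markers,
                                  config, stained))
    df_sorted = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=list(SCATTER_COLUMNS) + list(markers))
    inverse = np.empty(len(labels), dtype=np.intp)
    inverse[order] = np.arange(len(labels))
    return df_sorted.iloc[inverse].reset_index(drop=True)


def _combine_doublets(first: pd.DataFrame, second: pd.DataFrame) -> pd.DataFrame:
    """Pulse-geometry doublet synthesis: areas (and fluorescence) add,
    heights keep the larger pulse, widths widen to the configured factor."""
    out = {}
    for col in first.columns:
        a, b = first[col].to_numpy(), second[col].to_numpy()
        if col.endswith("-H"):
            out[col] = np.maximum(a, b)
        elif col.endswith("-W"):
            out[col] = defaults.DOUBLET_WIDTH_FACTOR * (a + b) / 2.0
        else:
            out[col] = a + b
    return pd.DataFrame(out)


def _generate_table(config: CohortConfig, panel: PanelConfig, donor: int,
                    set_id: int, reagent: str) -> EventTable:
    stained = reagent == ANTIBODY
    n_events = config.events_per_donor if stained else config.isotype_events
    rng = np.random.default_rng(
        [config.seed, donor, set_id, 0 if stained else 1])
    probs = donor_composition(config, donor)
    names = np.array(sorted(probs), dtype=object)
    p = np.array([probs[k] for k in names], dtype=float)
    p = p / p.sum()

    n_doublets = rng.binomial(n_events, config.doublet_rate)
    n_singlets = n_events - n_doublets
    counts = rng.multinomial(n_singlets, p)
    singlet_labels = np.repeat(names, counts)

    markers = panel.markers_for_set(set_id)
    frames = [_generate_for_labels(rng, singlet_labels, donor, markers,
                                   config, stained)]
    labels = [singlet_labels]
    if n_doublets:
        member_labels = names[rng.choice(len(names), size=2 * n_doublets, p=p)]
        members = _generate_for_labels(rng, member_labels, donor, markers,
                                       config, stained)
        frames.append(_combine_doublets(members.iloc[:n_doublets].reset_index(drop=True),
                                        members.iloc[n_doublets:].reset_index(drop=True)))
        labels.append(np.full(n_doublets, DOUBLET, dtype=object))

    df = pd.concat(frames, ignore_index=True)
    df[TRUTH_COLUMN] = np.concatenate(labels)
    perm = rng.permutation(len(df))
    df = df.iloc[perm].reset_index(drop=True)
    df.columns = [panel.channel_map.get(c, c) for c in df.columns]
    return EventTable(data=df, donor_id=str(donor), set_id=set_id, reagent=reagent)


def generate_donor(config: CohortConfig, donor: int,
                   panel: Optional[PanelConfig] = None,
                   sets: Optional[Iterable[int]] = None) -> DonorSample:
    """Generate the stained and matched isotype tables of one donor."""
    panel = panel or default_panel()
    set_ids = list(sets) if sets is not None else sorted(panel.staining_sets)
    for set_id in set_ids:
        if set_id not in panel.staining_sets:
            raise ConfigurationError(f"unknown staining set {set_id!r}")
    stained = {s: _generate_table(config, panel, donor, s, ANTIBODY) for s in set_ids}
    isotype = {s: _generate_table(config, panel, donor, s, ISOTYPE) for s in set_ids}
    return DonorSample(donor_id=donor, stained=stained, isotype=isotype)


def generate_cohort(config: CohortConfig,
                    panel: Optional[PanelConfig] = None,
                    sets: Optional[Iterable[int]] = None) -> List[DonorSample]:
    """Generate the full synthetic cohort (donors are numbered from 1)."""
    return [generate_donor(config, donor, panel=panel, sets=sets)
            for donor in range(1, config.n_donors + 1)]


# ---------------------------------------------------------------------------
# imaging objects
# ---------------------------------------------------------------------------

def generate_imaging_objects(config: ImagingConfig) -> pd.DataFrame:
    """Synthetic imaging-cytometry feature table.

    Returns a frame with one row per object: ``gate`` (small / large /
    doublet_gate), ``mask_area`` (um^2), ``minor_axis``/``major_axis`` (um),
    ``aspect_ratio`` and the hidden truth class. Each singlet gate is
    additionally contaminated with doublet objects at the configured rate,
    emulating imperfect upstream scatter gates.
    """
    rng = np.random.default_rng(config.seed)
    gate_for_class = {"small_singlet": "small", "large_singlet": "large",
                      "doublet": "doublet_gate"}
    rows = []

    def _make(cls: str, n: int, gate: str) -> None:
        if n == 0:
            return
        model = config.classes[cls]
        sigma = np.sqrt(np.log1p(model["area_cv"] ** 2))
        mu = np.log(model["mean_area"]) - sigma ** 2 / 2
        area = np.exp(mu + sigma * rng.standard_normal(n))
        ar = np.clip(rng.normal(model["ar_mean"], model["ar_sd"], n), 0.05, 1.0)
        major = np.sqrt(4.0 * area / (np.pi * ar))
        rows.append(pd.DataFrame({
            "gate": gate, "mask_area": area,
            "minor_axis": ar * major, "major_axis": major,
            "aspect_ratio": ar, TRUTH_COLUMN: cls,
        }))

    for cls, n in sorted(config.n_objects.items()):
        gate = gate_for_class.get(cls, cls)
        _make(cls, n, gate)
        if cls != "doublet" and "doublet" in config.classes and config.doublet_contamination > 0:
            n_cont = rng.binomial(n, config.doublet_contamination)
            _make("doublet", n_cont, gate)

    if not rows:
        return pd.DataFrame(columns=["gate", "mask_area", "minor_axis",
                                     "major_axis", "aspect_ratio", TRUTH_COLUMN])
    df = pd.concat(rows, ignore_index=True)
    df.insert(0, "object_id", np.arange(len(df)))
    return df
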