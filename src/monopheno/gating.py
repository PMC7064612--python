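"""Sequential monocyte gating.

Reproduces the manual strategy as a deterministic pipeline: lymphocyte
lineage exclusion -> CD14 selection -> scatter-space split into the small
and large monocyte clusters -> per-cluster doublet exclusion from pulse
geometry (FSC-H vs FSC-A residuals plus an FSC-W fence) -> CD14/CD16
classification into six subpopulations.

Positivity thresholds default to the isotype-control policy (the value that
excludes 99% of the isotype signal); all thresholds are closed below
(``value >= threshold`` is positive). The CD14 dim/bright boundary defaults
to the valley of a kernel-density estimate of log CD14 within the small
cluster. Manual cluster polygons are emulated by a Gaussian-mixture fit
with a Mahalanobis fence: events outside every kept component are reported
as unassigned rather than silently forced into a cluster, and optional
upper fluorescence fences mirror the bounded manual CD14/CD16 gates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Dict, List, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import signal, stats
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .errors import FormatError, InsufficientDataError, ValidationError
from .events import EventTable
from .panel import LINEAGE, PanelConfig, default_panel
from .quantitation import positivity_threshold
from .simulate import LARGE_SUBPOPULATIONS, SMALL_SUBPOPULATIONS, SUBPOPULATIONS

EXCLUDED_LINEAGE = "excluded_lineage"
EXCLUDED_CD14NEG = "excluded_cd14neg"
EXCLUDED_DOUBLET = "excluded_doublet"
UNASSIGNED = "unassigned"

GATE_LABELS = (EXCLUDED_LINEAGE, EXCLUDED_CD14NEG, EXCLUDED_DOUBLET,
               *SUBPOPULATIONS, UNASSIGNED)


@dataclass
class GateConfig:
    """Gating thresholds and the policies that derive them.

    Explicit thresholds are fluorescence units; ``None`` means "derive from
    the matched isotype table" (lineage/CD14/CD16 positivity) or "derive
    from the data" (dim boundary). ``cd14_upper``/``cd16_upper`` are the
    optional upper fences of the classification gates; ``None`` disables
    them (the 2x2 rule then labels every cluster singlet).
    """

    lineage_threshold: Optional[float] = None
    cd14_threshold: Optional[float] = None
    cd14_dim_boundary: Optional[float] = None
    cd16_threshold: Optional[float] = None
    cd14_upper: Optional[float] = None
    cd16_upper: Optional[float] = None
    isotype_exclusion: float = 0.99
    scatter_components: Tuple[int, ...] = (2, 3)
    mahalanobis_limit: float = 3.5
    posterior_floor: float = 0.8
    min_cd14_events: int = 100
    min_cluster_events: int = 50
    doublet_residual_mads: float = 3.0
    width_fence_quantile: float = 0.995
    max_theilsen_points: int = 2000
    dim_boundary_quantile: float = 0.15
    random_state: int = 0

    def __post_init__(self) -> None:
        for name in ("lineage_threshold", "cd14_threshold", "cd14_dim_boundary",
                     "cd16_threshold", "cd14_upper", "cd16_upper"):
            value = getattr(self, name)
            if value is not None and not (np.isfinite(value) and value > 0):
                raise ValidationError(f"{name} must be finite and > 0, got {value}")
        if (self.cd14_threshold is not None and self.cd14_dim_boundary is not None
                and not self.cd14_dim_boundary > self.cd14_threshold):
            raise ValidationError("cd14_dim_boundary must exceed cd14_threshold")
        if not 0.0 < self.isotype_exclusion < 1.0:
            raise ValidationError("isotype_exclusion must be in (0, 1)")


def default_gate_config() -> GateConfig:
    """Gate configuration matched to the packaged synthetic cohort: finite
    upper fences bound the CD14/CD16 classification gates the way the manual
    rectangles do."""
    return GateConfig(cd14_upper=1.0e5, cd16_upper=1.0e4)


@dataclass
class GateResult:
    """Per-event labels plus the per-donor summary of one gating run."""

    labels: pd.Series
    clusters: pd.Series          # small/large/unassigned over CD14+ events
    thresholds: Dict[str, float]
    counts: Dict[str, int]
    cluster_percentages: Dict[str, float]   # of CD14+ singlets
    subpop_percentages: Dict[str, float]    # of the parent cluster's singlets
    subpop_absent: Dict[str, bool]
    n_events: int
    warnings: List[str] = field(default_factory=list)

    @property
    def n_cd14_singlets(self) -> int:
        return sum(self.counts.get(k, 0) for k in (*SUBPOPULATIONS, UNASSIGNED))


def _frame(events: Union[EventTable, pd.DataFrame]) -> pd.DataFrame:
    return events.data if isinstance(events, EventTable) else events


def _channel(df: pd.DataFrame, panel: PanelConfig, marker: str) -> np.ndarray:
    col = panel.channel(marker)
    if col not in df.columns:
        raise FormatError(f"missing required column(s): {col}")
    return df[col].to_numpy(dtype=float)


def resolve_thresholds(isotype: Union[EventTable, pd.DataFrame],
                       config: GateConfig,
                       panel: Optional[PanelConfig] = None) -> Dict[str, float]:
    """Fill in lineage/CD14/CD16 positivity thresholds from the isotype
    table wherever the config leaves them implicit."""
    panel = panel or default_panel()
    iso = _frame(isotype)
    out = {}
    for name, marker in (("lineage_threshold", LINEAGE),
                         ("cd14_threshold", "CD14"),
                         ("cd16_threshold", "CD16")):
        explicit = getattr(config, name)
        if explicit is not None:
            out[name] = float(explicit)
        else:
            out[name] = positivity_threshold(
                _channel(iso, panel, marker), exclusion=config.isotype_exclusion)
    return out


# ---------------------------------------------------------------------------
# individual gates
# ---------------------------------------------------------------------------

def exclude_lineage(events: Union[EventTable, pd.DataFrame], config: GateConfig,
                    isotype: Optional[Union[EventTable, pd.DataFrame]] = None,
                    panel: Optional[PanelConfig] = None) -> np.ndarray:
    """Boolean mask of retained (lineage-negative) events."""
    panel = panel or default_panel()
    df = _frame(events)
    threshold = config.lineage_threshold
    if threshold is None:
        if isotype is None:
            raise ValidationError("lineage_threshold unset and no isotype table given")
        threshold = resolve_thresholds(isotype, config, panel)["lineage_threshold"]
    return _channel(df, panel, LINEAGE) < threshold


def select_cd14(events: Union[EventTable, pd.DataFrame], config: GateConfig,
                isotype: Optional[Union[EventTable, pd.DataFrame]] = None,
                panel: Optional[PanelConfig] = None) -> np.ndarray:
    """Boolean mask of CD14-positive events (closed lower bound)."""
    panel = panel or default_panel()
    df = _frame(events)
    threshold = config.cd14_threshold
    if threshold is None:
        if isotype is None:
            raise ValidationError("cd14_threshold unset and no isotype table given")
        threshold = resolve_thresholds(isotype, config, panel)["cd14_threshold"]
    return _channel(df, panel, "CD14") >= threshold


def split_scatter_clusters(cd14_events: Union[EventTable, pd.DataFrame],
                           config: GateConfig,
                           ) -> Tuple[np.ndarray, List[str]]:
    """Label CD14+ events as small / large / unassigned in scatter space.

    A Gaussian mixture (component count selected by BIC among the
    configured candidates) is fitted on (log FSC-A, log SSC-A). The
    component with the lowest FSC-A mean is the small-monocyte cluster, the
    highest is the large one; any middle component collects off-cluster
    events. Events with a low posterior for every kept component, or lying
    beyond the Mahalanobis fence of their best component, are unassigned —
    the automated counterpart of falling outside the manual polygons.
    """
    df = _frame(cd14_events)
    n = len(df)
    if n < config.min_cd14_events:
        raise InsufficientDataError(
            f"scatter split needs >= {config.min_cd14_events} CD14+ events, got {n}")
    X = np.log(df[["FSC-A", "SSC-A"]].to_numpy(dtype=float) + 1.0)
    warnings: List[str] = []
    spread = X.max(axis=0) - X.min(axis=0)
    if np.all(spread < 1e-9):
        warnings.append("degenerate single-mode scatter; all events labelled small")
        return np.full(n, "small", dtype=object), warnings
    # standardize so neither axis dominates the k-means initialization
    scale = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    Xs = (X - X.mean(axis=0)) / scale

    # fit on row-sorted data so the result is invariant to event order
    sort_order = np.lexsort((Xs[:, 1], Xs[:, 0]))
    X_fit = Xs[sort_order]
    best = None
    for k in config.scatter_components:
        if k < 2 or k > n:
            continue
        gmm = GaussianMixture(n_components=k, covariance_type="full",
                              n_init=10, init_params="k-means++",
                              random_state=config.random_state)
        gmm.fit(X_fit)
        bic = gmm.bic(X_fit)
        if best is None or bic < best[0]:
            best = (bic, gmm)
    if best is None:
        raise ValidationError("scatter_components yielded no admissible model")
    gmm = best[1]

    order = np.argsort(gmm.means_[:, 0])
    small_comp, large_comp = order[0], order[-1]
    if small_comp == large_comp:  # k == 1 cannot happen, defensive
        warnings.append("degenerate single-mode scatter; all events labelled small")
        return np.full(n, "small", dtype=object), warnings

    posterior = gmm.predict_proba(Xs)
    maha = np.empty((n, gmm.n_components))
    for j in range(gmm.n_components):
        diff = Xs - gmm.means_[j]
        inv = np.linalg.inv(gmm.covariances_[j])
        maha[:, j] = np.sqrt(np.einsum("ij,jk,ik->i", diff, inv, diff))

    labels = np.full(n, UNASSIGNED, dtype=object)
    for comp, name in ((small_comp, "small"), (large_comp, "large")):
        is_best = posterior.argmax(axis=1) == comp
        confident = posterior[:, comp] >= config.posterior_floor
        inside = maha[:, comp] <= config.mahalanobis_limit
        labels[is_best & confident & inside] = name
    return labels, warnings


def exclude_doublets(cluster_events: Union[EventTable, pd.DataFrame],
                     config: GateConfig) -> np.ndarray:
    """Singlet mask within one scatter cluster.

    Doublets carry roughly doubled pulse areas with singlet-like peak
    heights, so they fall far below the FSC-H-on-FSC-A ridge; a robust
    Theil-Sen fit of that ridge plus a +-k*MAD residual band removes them,
    and an FSC-W fence at the configured quantile of the residual-pass core
    removes wide pulses the residual test misses.
    """
    df = _frame(cluster_events)
    n = len(df)
    if n < config.min_cluster_events:
        raise InsufficientDataError(
            f"doublet fit needs >= {config.min_cluster_events} events, got {n}")
    A = df["FSC-A"].to_numpy(dtype=float)
    H = df["FSC-H"].to_numpy(dtype=float)
    W = df["FSC-W"].to_numpy(dtype=float)

    # fit on the unique (A, H) support, evenly subsampled in sorted order:
    # deterministic and invariant to event order and to exact duplication
    points = np.unique(np.column_stack([A, H]), axis=0)
    if len(points) > config.max_theilsen_points:
        points = points[np.linspace(0, len(points) - 1,
                                    config.max_theilsen_points).astype(int)]
    if len(points) < 2:
        return np.ones(n, dtype=bool)
    slope, intercept, _, _ = stats.theilslopes(points[:, 1], points[:, 0])
    resid = H - (intercept + slope * A)
    center = np.median(resid)
    mad = 1.4826 * np.median(np.abs(resid - center))
    if mad == 0:
        band = np.ones(n, dtype=bool)
    else:
        band = np.abs(resid - center) <= config.doublet_residual_mads * mad
    if not band.any():
        return band
    fence = np.quantile(W[band], config.width_fence_quantile,
                        method="inverted_cdf")
    return band & (W <= fence)


def classify_cd14_cd16(events: Union[EventTable, pd.DataFrame], cluster: str,
                       thresholds: Mapping[str, float], config: GateConfig,
                       panel: Optional[PanelConfig] = None) -> np.ndarray:
    """CD14/CD16 subpopulation labels for the singlets of one cluster.

    Small cluster: the 2x2 rule over (CD14 bright/dim, CD16 +/neg). Large
    cluster: la14+16neg / la14+16+, with CD14-dim events unassigned (no
    large-dim class is defined). Events above an upper fence, when fences
    are configured, are unassigned in either cluster.
    """
    if cluster not in ("small", "large"):
        raise ValidationError(f"cluster must be 'small' or 'large', got {cluster!r}")
    panel = panel or default_panel()
    df = _frame(events)
    cd14 = _channel(df, panel, "CD14")
    cd16 = _channel(df, panel, "CD16")
    dim_boundary = thresholds["cd14_dim_boundary"]
    cd16_thr = thresholds["cd16_threshold"]

    bright = cd14 >= dim_boundary
    cd16_pos = cd16 >= cd16_thr
    labels = np.full(len(df), UNASSIGNED, dtype=object)
    if cluster == "small":
        labels[bright & ~cd16_pos] = "sm14+16neg"
        labels[bright & cd16_pos] = "sm14+16+"
        labels[~bright & cd16_pos] = "sm14dim16+"
        labels[~bright & ~cd16_pos] = "sm14dim16neg"
    else:
        labels[bright & ~cd16_pos] = "la14+16neg"
        labels[bright & cd16_pos] = "la14+16+"
        # large-cluster CD14dim events stay unassigned
    if config.cd14_upper is not None:
        labels[cd14 > config.cd14_upper] = UNASSIGNED
    if config.cd16_upper is not None:
        labels[cd16 > config.cd16_upper] = UNASSIGNED
    return labels


def derive_dim_boundary(cd14_values: np.ndarray, config: GateConfig) -> float:
    """CD14 dim/bright boundary: KDE valley of log CD14 between the two
    strongest modes of the small cluster; quantile fallback when unimodal."""
    values = np.asarray(cd14_values, dtype=float)
    values = values[values > 0]
    if len(values) < 10:
        return float(np.quantile(values, config.dim_boundary_quantile)) if len(values) else 1.0
    logv = np.log(values)
    if np.ptp(logv) < 1e-9:
        return float(np.exp(logv[0]))
    kde = stats.gaussian_kde(logv, bw_method="silverman")
    grid = np.linspace(logv.min(), logv.max(), 512)
    density = kde(grid)
    peaks, props = signal.find_peaks(density, prominence=0.01 * density.max())
    if len(peaks) < 2:
        return float(np.quantile(values, config.dim_boundary_quantile))
    top_two = peaks[np.argsort(props["prominences"])[-2:]]
    lo, hi = sorted(top_two)
    valley = grid[lo + int(np.argmin(density[lo:hi + 1]))]
    return float(np.exp(valley))


# ---------------------------------------------------------------------------
# sklearn-style estimator and end-to-end wrapper
# ---------------------------------------------------------------------------

class MonocyteGater(BaseEstimator):
    """Sequential monocyte gater with a scikit-learn estimator surface.

    ``fit`` derives all thresholds from a stained/isotype table pair and
    labels every event; the per-event labels are available as ``labels_``
    and the per-donor summary as ``result_``. Parameters mirror
    :class:`GateConfig`.
    """

    def __init__(self, lineage_threshold=None, cd14_threshold=None,
                 cd14_dim_boundary=None, cd16_threshold=None,
                 cd14_upper=None, cd16_upper=None, isotype_exclusion=0.99,
                 scatter_components=(2, 3), mahalanobis_limit=3.5,
                 posterior_floor=0.8, min_cd14_events=100,
                 min_cluster_events=50, doublet_residual_mads=3.0,
                 width_fence_quantile=0.995, max_theilsen_points=2000,
                 dim_boundary_quantile=0.15, random_state=0):
        self.lineage_threshold = lineage_threshold
        self.cd14_threshold = cd14_threshold
        self.cd14_dim_boundary = cd14_dim_boundary
        self.cd16_threshold = cd16_threshold
        self.cd14_upper = cd14_upper
        self.cd16_upper = cd16_upper
        self.isotype_exclusion = isotype_exclusion
        self.scatter_components = scatter_components
        self.mahalanobis_limit = mahalanobis_limit
        self.posterior_floor = posterior_floor
        self.min_cd14_events = min_cd14_events
        self.min_cluster_events = min_cluster_events
        self.doublet_residual_mads = doublet_residual_mads
        self.width_fence_quantile = width_fence_quantile
        self.max_theilsen_points = max_theilsen_points
        self.dim_boundary_quantile = dim_boundary_quantile
        self.random_state = random_state

    @classmethod
    def from_config(cls, config: GateConfig) -> "MonocyteGater":
        return cls(**asdict(config))

    def _config(self) -> GateConfig:
        return GateConfig(**self.get_params())

    def fit(self, X: Union[EventTable, pd.DataFrame],
            y=None, *, isotype: Union[EventTable, pd.DataFrame],
            panel: Optional[PanelConfig] = None) -> "MonocyteGater":
        panel = panel or default_panel()
        config = self._config()
        df = _frame(X)
        n = len(df)
        warnings: List[str] = []

        labels = pd.Series(np.full(n, UNASSIGNED, dtype=object), index=df.index)
        clusters = pd.Series(np.full(n, "", dtype=object), index=df.index)

        if n == 0:
            thresholds = {"lineage_threshold": np.nan, "cd14_threshold": np.nan,
                          "cd16_threshold": np.nan, "cd14_dim_boundary": np.nan}
            self._finalize(labels, clusters, thresholds, n, warnings)
            return self

        try:
            thresholds = resolve_thresholds(isotype, config, panel)
        except Exception as exc:
            raise type(exc)(f"threshold derivation: {exc}") from exc
        explicit = replace(config,
                           lineage_threshold=thresholds["lineage_threshold"],
                           cd14_threshold=thresholds["cd14_threshold"],
                           cd16_threshold=thresholds["cd16_threshold"])

        lineage_mask = exclude_lineage(df, explicit, panel=panel)
        labels[~lineage_mask] = EXCLUDED_LINEAGE

        retained = df[lineage_mask]
        cd14_mask = select_cd14(retained, explicit, panel=panel)
        labels[retained.index[~cd14_mask]] = EXCLUDED_CD14NEG
        cd14_events = retained[cd14_mask]

        if len(cd14_events) == 0:
            thresholds["cd14_dim_boundary"] = config.cd14_dim_boundary or np.nan
            self._finalize(labels, clusters, thresholds, n, warnings)
            return self

        try:
            cluster_labels, split_warnings = split_scatter_clusters(cd14_events, explicit)
        except Exception as exc:
            raise type(exc)(f"scatter split: {exc}") from exc
        warnings.extend(split_warnings)
        clusters[cd14_events.index] = cluster_labels

        singlet_index: Dict[str, pd.Index] = {}
        for name in ("small", "large"):
            members = cd14_events.index[cluster_labels == name]
            if len(members) == 0:
                singlet_index[name] = members
                continue
            if len(members) < explicit.min_cluster_events:
                warnings.append(f"{name} cluster below doublet-fit minimum; "
                                "no doublet exclusion applied")
                singlet_index[name] = members
                continue
            singlet_mask = exclude_doublets(df.loc[members], explicit)
            labels[members[~singlet_mask]] = EXCLUDED_DOUBLET
            singlet_index[name] = members[singlet_mask]

        if config.cd14_dim_boundary is not None:
            dim_boundary = float(config.cd14_dim_boundary)
        else:
            small_cd14 = _channel(df.loc[singlet_index["small"]], panel, "CD14") \
                if len(singlet_index["small"]) else np.array([])
            dim_boundary = derive_dim_boundary(small_cd14, explicit) \
                if len(small_cd14) else thresholds["cd14_threshold"] * 10.0
        if dim_boundary <= thresholds["cd14_threshold"]:
            dim_boundary = thresholds["cd14_threshold"] * (1.0 + 1e-9)
            warnings.append("dim boundary at or below CD14 threshold; nudged above")
        thresholds["cd14_dim_boundary"] = dim_boundary

        for name in ("small", "large"):
            members = singlet_index[name]
            if len(members) == 0:
                continue
            labels[members] = classify_cd14_cd16(
                df.loc[members], name, thresholds, explicit, panel=panel)

        self._finalize(labels, clusters, thresholds, n, warnings,
                       singlet_index=singlet_index)
        return self

    def _finalize(self, labels, clusters, thresholds, n, warnings,
                  singlet_index=None) -> None:
        counts = {k: int((labels == k).sum()) for k in GATE_LABELS}
        if singlet_index is None:
            singlet_index = {"small": pd.Index([]), "large": pd.Index([])}
        n_small = len(singlet_index["small"])
        n_large = len(singlet_index["large"])
        n_unassigned_cluster = int((clusters == UNASSIGNED).sum())
        denom = n_small + n_large + n_unassigned_cluster
        cluster_pct = {
            "small": 100.0 * n_small / denom if denom else 0.0,
            "large": 100.0 * n_large / denom if denom else 0.0,
            "unassigned": 100.0 * n_unassigned_cluster / denom if denom else 0.0,
        }
        subpop_pct = {}
        for name, parent_n in (("small", n_small), ("large", n_large)):
            pops = SMALL_SUBPOPULATIONS if name == "small" else LARGE_SUBPOPULATIONS
            for pop in pops:
                subpop_pct[pop] = 100.0 * counts[pop] / parent_n if parent_n else 0.0
        absent = {pop: counts[pop] == 0 for pop in SUBPOPULATIONS}
        self.thresholds_ = thresholds
        self.labels_ = labels
        self.result_ = GateResult(
            labels=labels, clusters=clusters, thresholds=thresholds,
            counts=counts, cluster_percentages=cluster_pct,
            subpop_percentages=subpop_pct, subpop_absent=absent,
            n_events=n, warnings=list(warnings))

    def fit_predict(self, X, y=None, **kwargs) -> pd.Series:
        return self.fit(X, y, **kwargs).labels_


def run_gating(stained: Union[EventTable, pd.DataFrame],
               isotype: Union[EventTable, pd.DataFrame],
               config: Optional[GateConfig] = None,
               panel: Optional[PanelConfig] = None) -> GateResult:
    """Run the full gating strategy on one stained/isotype table pair."""
    config = config or GateConfig()
    gater = MonocyteGater.from_config(config)
    gater.fit(stained, isotype=isotype, panel=panel)
    return gater.result_
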