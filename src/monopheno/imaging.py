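"""Imaging-cytometry quantitation.

Works on extracted mask features (area, minor/major axis), not pixels:
singlet/doublet discrimination from the aspect-ratio (minor/major)
distribution with a data-driven nadir threshold, per-gate doublet
percentages, and circle-equivalent diameters from mask areas
(``d = 2 * sqrt(A / pi)``).
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import signal, stats
from sklearn.base import BaseEstimator

from .errors import InsufficientDataError, ValidationError

DEFAULT_NADIR_FALLBACK = 0.7


def diameter_from_area(mask_area: Union[float, Sequence[float]]
                       ) -> Union[float, np.ndarray]:
    """Diameter of the circle with the same area as the mask (micrometres
    for areas in square micrometres)."""
    area = np.asarray(mask_area, dtype=float)
    if np.any(area <= 0) or not np.all(np.isfinite(area)):
        raise ValidationError("mask_area must be finite and > 0")
    diameter = 2.0 * np.sqrt(area / np.pi)
    return float(diameter) if np.isscalar(mask_area) else diameter


class AspectRatioThresholder(BaseEstimator):
    """Nadir-based singlet/doublet discriminator on aspect ratios.

    ``fit`` locates the minimum of a Silverman-bandwidth kernel-density
    estimate between the two most prominent modes of the aspect-ratio
    distribution (round singlets near 1, oblong doublets below); when the
    sample is too small or unimodal the configured fallback threshold is
    used. ``predict`` flags objects below the threshold as doublets.
    """

    def __init__(self, fallback: float = DEFAULT_NADIR_FALLBACK,
                 min_objects: int = 50, grid_points: int = 512):
        self.fallback = fallback
        self.min_objects = min_objects
        self.grid_points = grid_points

    def fit(self, X: Sequence[float], y=None) -> "AspectRatioThresholder":
        ratios = np.asarray(X, dtype=float)
        if len(ratios) == 0:
            raise InsufficientDataError("no aspect ratios given")
        if np.any((ratios <= 0) | (ratios > 1)):
            raise ValidationError("aspect ratios must lie in (0, 1]")
        self.bimodal_ = False
        self.threshold_ = float(self.fallback)
        if len(ratios) >= self.min_objects and np.ptp(ratios) > 1e-9:
            kde = stats.gaussian_kde(ratios, bw_method="silverman")
            grid = np.linspace(ratios.min(), ratios.max(), self.grid_points)
            density = kde(grid)
            peaks, props = signal.find_peaks(density,
                                             prominence=0.01 * density.max())
            if len(peaks) >= 2:
                top_two = peaks[np.argsort(props["prominences"])[-2:]]
                lo, hi = sorted(top_two)
                nadir = grid[lo + int(np.argmin(density[lo:hi + 1]))]
                self.threshold_ = float(nadir)
                self.bimodal_ = True
        return self

    def predict(self, X: Sequence[float]) -> np.ndarray:
        """True for objects scored as doublets (below the threshold)."""
        return np.asarray(X, dtype=float) < self.threshold_


def quantify_singlet_doublet(objects: pd.DataFrame,
                             fallback: float = DEFAULT_NADIR_FALLBACK,
                             min_objects: int = 50,
                             ) -> Tuple[float, Dict[str, float]]:
    """Nadir threshold over all objects plus per-gate doublet percentages.

    ``objects`` needs ``aspect_ratio`` and ``gate`` columns. The doublet
    percentage of a gate is the share of its objects with aspect ratio
    strictly below the threshold.
    """
    if len(objects) == 0:
        raise InsufficientDataError("no imaging objects given")
    for col in ("aspect_ratio", "gate"):
        if col not in objects.columns:
            raise ValidationError(f"objects frame lacks column {col!r}")
    model = AspectRatioThresholder(fallback=fallback, min_objects=min_objects)
    model.fit(objects["aspect_ratio"].to_numpy(dtype=float))
    percentages = {
        str(gate): 100.0 * float((group["aspect_ratio"] < model.threshold_).mean())
        for gate, group in objects.groupby("gate")
    }
    return model.threshold_, percentages


def imaging_report(objects: pd.DataFrame,
                   fallback: float = DEFAULT_NADIR_FALLBACK) -> Dict[str, object]:
    """Summary of an imaging run: nadir threshold, per-gate doublet
    percentages, and per-gate circle-equivalent diameters.

    Two diameter summaries are reported per gate — the diameter of the mean
    mask area and the mean of per-object diameters — since either reading
    of "diameter inferred from cell size" is defensible.
    """
    threshold, doublet_pct = quantify_singlet_doublet(objects, fallback=fallback)
    sizes = {}
    for gate, group in objects.groupby("gate"):
        areas = group["mask_area"].to_numpy(dtype=float)
        sizes[str(gate)] = {
            "n": int(len(areas)),
            "diameter_of_mean_area": float(diameter_from_area(float(areas.mean()))),
            "mean_of_diameters": float(np.mean(diameter_from_area(areas))),
        }
    return {"nadir_threshold": threshold, "doublet_percent": doublet_pct,
            "sizes": sizes}
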