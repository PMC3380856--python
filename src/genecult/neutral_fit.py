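"""Goodness-of-fit to neutrality by summary-statistic distance.

Observed and simulated locus sets are summarised to vectors S* and S of
heterozygosity and F_ST statistics, and compared by the Euclidean distance
d = ||S - S*||.  Because the coordinates mix scales, the default mode first
standardises every coordinate by its standard deviation in the neutral
ensemble; the raw mode is retained.  A dataset "fits" neutrality when its
distances to the neutral ensemble resemble the ensemble's internal spread
(each simulation's distance to the ensemble mean), and two observed
datasets are compared by which one the neutral simulations reproduce with
higher fidelity (smaller mean distance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .coalescent import SummaryStats
from .errors import LayoutMismatchError, ValidationError

__all__ = ["FitReport", "euclidean_distance", "neutrality_fit"]


@dataclass
class FitReport:
    """Distances between one observed summary vector and a neutral ensemble."""

    mean_distance: float
    median_distance: float
    min_distance: float
    n_sims: int
    standardization: str
    distances: np.ndarray | None = None
    baseline_distances: np.ndarray | None = None  # each sim vs ensemble mean
    degenerate: bool = False


def _check_layout(a: SummaryStats, b: SummaryStats) -> None:
    la, lb = a.vector_labels(), b.vector_labels()
    if la != lb:
        first = next((x for x, y in zip(la, lb) if x != y), la[min(len(la), len(lb)) - 1])
        raise LayoutMismatchError(f"summary layouts differ at field {first!r}")


def euclidean_distance(
    s: SummaryStats | np.ndarray,
    s_star: SummaryStats | np.ndarray,
    scale: np.ndarray | None = None,
) -> float:
    """||S - S*||, optionally with per-coordinate standardisation by ``scale``."""
    if isinstance(s, SummaryStats) and isinstance(s_star, SummaryStats):
        _check_layout(s, s_star)
        v, w = s.as_vector(), s_star.as_vector()
    else:
        v = s.as_vector() if isinstance(s, SummaryStats) else np.asarray(s, float)
        w = s_star.as_vector() if isinstance(s_star, SummaryStats) else np.asarray(s_star, float)
    if v.shape != w.shape:
        raise LayoutMismatchError(f"vector lengths differ: {v.shape} vs {w.shape}")
    d = v - w
    if scale is not None:
        d = d / scale
    return float(np.sqrt((d**2).sum()))


def neutrality_fit(
    observed: SummaryStats,
    ensemble: Sequence[SummaryStats],
    standardization: str = "null_sd",
    keep_distances: bool = True,
) -> FitReport:
    """Distance profile of an observed summary vector against a neutral ensemble.

    ``standardization="null_sd"`` divides each coordinate by its ensemble
    standard deviation before measuring distances (coordinates whose
    ensemble SD is 0 are left unscaled); ``"none"`` uses raw coordinates.
    The report also carries the internal baseline: each simulation's
    distance to the ensemble mean, so callers can judge whether the
    observed set sits inside the neutral scatter.
    """
    if len(ensemble) == 0:
        raise ValidationError("empty neutral ensemble")
    for s in ensemble:
        _check_layout(observed, s)
    mat = np.vstack([s.as_vector() for s in ensemble])
    if standardization == "null_sd":
        scale = mat.std(axis=0, ddof=1) if len(ensemble) > 1 else np.ones(mat.shape[1])
        scale = np.where(scale > 0, scale, 1.0)
    elif standardization == "none":
        scale = np.ones(mat.shape[1])
    else:
        raise ValueError(f"unknown standardization {standardization!r}")
    obs = observed.as_vector()
    dists = np.sqrt((((mat - obs[None, :]) / scale) ** 2).sum(axis=1))
    centre = mat.mean(axis=0)
    baseline = np.sqrt((((mat - centre[None, :]) / scale) ** 2).sum(axis=1))
    return FitReport(
        mean_distance=float(dists.mean()),
        median_distance=float(np.median(dists)),
        min_distance=float(dists.min()),
        n_sims=len(ensemble),
        standardization=standardization,
        distances=dists if keep_distances else None,
        baseline_distances=baseline if keep_distances else None,
        degenerate=len(ensemble) == 1,
    )
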