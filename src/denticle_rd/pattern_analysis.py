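"""Quantification of the emergent spot pattern.

Turns a final activator field into the quantities the biological claims are
stated in: segmented spots with per-spot area and centroid, the
initiator-versus-emergent size split, coverage density, nearest-neighbor
spacing regularity, and gap-infill statistics for the ablation experiment.
The field itself carries no intrinsic spot boundary, so spots are defined by
thresholding at a fraction of the field's dynamic range (default half-range)
followed by 8-connected component labeling; the steady pattern is
high-contrast, which makes the metrics insensitive to the exact fraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure

from .grid_solver import GridSpec
from .initiators import SpotConfig

__all__ = ["SpotSummary", "PatternMetrics", "GapReport",
           "DensityOrderingError", "segment_spots",
           "compare_initiator_emergent", "gap_infill_metrics",
           "density_suite", "replicate_proportion",
           "nearest_neighbor_stats"]


class DensityOrderingError(ValueError):
    """Calibration failure: spot-count ordering across presets violated."""


@dataclass
class SpotSummary:
    """One segmented spot."""

    label: int
    x: float                  # centroid, domain units
    y: float
    area_cells: int
    area_units: float         # area_cells * dx^2
    mean_u: float
    is_initiator: bool = False


@dataclass
class PatternMetrics:
    """Whole-pattern summary over one segmented field.

    ``ratio_defined`` is false (and the ratio NaN) when either the initiator
    or the emergent class is empty.
    """

    count: int
    density: float            # count / L^2
    initiator_count: int
    emergent_count: int
    mean_initiator_area: float
    median_initiator_area: float
    mean_emergent_area: float
    median_emergent_area: float
    initiator_emergent_ratio: float
    ratio_defined: bool
    nn_distance_mean: float
    nn_distance_cv: float
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        return d


@dataclass
class GapReport:
    """Spots infilling the region vacated by removed initiator spots."""

    window_radius: float
    gap_spot_count: int
    gap_mean_area: float          # NaN if no spot in the window
    surviving_initiator_mean_area: float
    infill_ok: bool               # >=1 gap spot, smaller than survivors
    per_center: list[dict] = field(default_factory=list)


def segment_spots(u_field: np.ndarray, g: GridSpec,
                  threshold_fraction: float = 0.5, min_area: int = 3,
                  cfg: SpotConfig | None = None) -> list[SpotSummary]:
    """Segment supra-threshold spots from an activator field.

    Binarizes at min + threshold_fraction * (max - min), labels 8-connected
    components, and drops components smaller than ``min_area`` cells
    (suppresses single-cell numerical speckle).  A constant field yields no
    spots (with a warning, not an error).  When ``cfg`` is given, a spot is
    flagged ``is_initiator`` iff its footprint contains the grid cell of a
    non-removed initiator center.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    u = np.asarray(u_field, dtype=float)
    if not np.isfinite(u).all():
        raise ValueError("field contains non-finite values")
    lo, hi = float(u.min()), float(u.max())
    if hi == lo:
        warnings.warn("constant field: no spots segmented", stacklevel=2)
        return []
    thr = lo + threshold_fraction * (hi - lo)
    labels = measure.label(u > thr, connectivity=2)

    initiator_cells: set[tuple[int, int]] = set()
    if cfg is not None:
        for xc, yc in cfg.active_centers:
            col = min(int(xc / g.dx), g.n - 1)
            row = min(int(yc / g.dx), g.n - 1)
            initiator_cells.add((row, col))

    dx2 = g.dx * g.dx
    spots: list[SpotSummary] = []
    for rp in measure.regionprops(labels, intensity_image=u):
        if rp.area < min_area:
            continue
        row_c, col_c = rp.centroid
        is_init = any(labels[r, c] == rp.label for r, c in initiator_cells)
        spots.append(SpotSummary(
            label=int(rp.label),
            x=(col_c + 0.5) * g.dx,
            y=(row_c + 0.5) * g.dx,
            area_cells=int(rp.area),
            area_units=float(rp.area) * dx2,
            mean_u=float(rp.intensity_mean),
            is_initiator=bool(is_init),
        ))
    return spots


def nearest_neighbor_stats(spots: list[SpotSummary]) -> tuple[float, float]:
    """Mean and coefficient of variation of nearest-neighbor centroid
    distances.  A low CV indicates a periodic rather than random arrangement.
    Returns (nan, nan) with fewer than two spots."""
    if len(spots) < 2:
        return math.nan, math.nan
    pts = np.array([(s.x, s.y) for s in spots])
    d, _ = cKDTree(pts).query(pts, k=2)
    nn = d[:, 1]
    mean = float(nn.mean())
    cv = float(nn.std() / mean) if mean > 0 else math.nan
    return mean, cv


def compare_initiator_emergent(spots: list[SpotSummary], cfg: SpotConfig,
                               g: GridSpec) -> PatternMetrics:
    """Partition spots into initiator vs emergent and summarize the pattern.

    The biological expectation for the dense baseline is that initiator
    spots stay larger than newly formed spots, i.e. the mean-area ratio
    exceeds 1.  If the configuration has active initiator centers but no
    spot is initiator-flagged, a topology-mismatch warning is recorded in
    the report rather than raised.
    """
    if not spots:
        raise ValueError("spots must be non-empty")
    init = [s.area_units for s in spots if s.is_initiator]
    emer = [s.area_units for s in spots if not s.is_initiator]
    warns: list[str] = []
    if cfg.active_centers and not init:
        warns.append("topology mismatch: no initiator-flagged spot despite "
                     "active initiator centers")
    ratio_defined = bool(init) and bool(emer)
    ratio = (float(np.mean(init)) / float(np.mean(emer))
             if ratio_defined else math.nan)
    nn_mean, nn_cv = nearest_neighbor_stats(spots)
    return PatternMetrics(
        count=len(spots),
        density=len(spots) / (g.L * g.L),
        initiator_count=len(init),
        emergent_count=len(emer),
        mean_initiator_area=float(np.mean(init)) if init else math.nan,
        median_initiator_area=float(np.median(init)) if init else math.nan,
        mean_emergent_area=float(np.mean(emer)) if emer else math.nan,
        median_emergent_area=float(np.median(emer)) if emer else math.nan,
        initiator_emergent_ratio=ratio,
        ratio_defined=ratio_defined,
        nn_distance_mean=nn_mean,
        nn_distance_cv=nn_cv,
        warnings=warns,
    )


def gap_infill_metrics(spots: list[SpotSummary], cfg: SpotConfig,
                       window_radius: float | None = None) -> GapReport:
    """Quantify infilling of the region vacated by removed initiator spots.

    For each removed center, counts spots whose centroid lies within
    ``window_radius`` (default 1.5 R_spot).  The ablation claim passes when
    at least one spot occupies the gap and the mean gap-spot area is smaller
    than the mean area of the surviving initiator spots.
    """
    if not cfg.removed_indices:
        raise ValueError("gap metrics require a config with removed spots")
    if window_radius is None:
        window_radius = 1.5 * cfg.R_spot

    surviving = [s.area_units for s in spots if s.is_initiator]
    surv_mean = float(np.mean(surviving)) if surviving else math.nan

    per_center = []
    gap_areas: list[float] = []
    for xc, yc in cfg.removed_centers:
        inside = [s for s in spots if not s.is_initiator
                  and (s.x - xc) ** 2 + (s.y - yc) ** 2 <= window_radius ** 2]
        areas = [s.area_units for s in inside]
        gap_areas.extend(areas)
        per_center.append({"center": [xc, yc], "count": len(inside),
                           "mean_area": float(np.mean(areas)) if areas
                           else math.nan})

    n_gap = sum(pc["count"] for pc in per_center)
    gap_mean = float(np.mean(gap_areas)) if gap_areas else math.nan
    ok = (n_gap >= 1 and not math.isnan(surv_mean) and gap_mean < surv_mean)
    return GapReport(window_radius=float(window_radius),
                     gap_spot_count=n_gap, gap_mean_area=gap_mean,
                     surviving_initiator_mean_area=surv_mean,
                     infill_ok=bool(ok), per_center=per_center)


def density_suite(results: dict[str, PatternMetrics],
                  order: tuple[str, ...] = ("catshark", "thornback",
                                            "little_skate")) -> dict:
    """Check that coverage density decreases strictly along ``order``.

    Spot counts (hence densities, on the identical domain) must be strictly
    decreasing from the dense catshark-like regime through the thornback- to
    the little-skate-like regime.  Returns the densities and counts; raises
    :class:`DensityOrderingError` naming the first offending pair.
    """
    missing = [k for k in order if k not in results]
    if missing:
        raise KeyError(f"missing presets: {missing}")
    counts = {k: results[k].count for k in order}
    densities = {k: results[k].density for k in order}
    for a, b in zip(order, order[1:]):
        if not counts[a] > counts[b]:
            raise DensityOrderingError(
                f"calibration failure: count({a}) = {counts[a]} is not "
                f"greater than count({b}) = {counts[b]}")
    return {"order": list(order), "counts": counts, "densities": densities,
            "ordering_ok": True}


def replicate_proportion(affected: int, total: int) -> int:
    """Percentage of affected replicates, rounded to the nearest integer.

    Half-up rounding on 100 * affected / total (e.g. 20 of 23 -> 87).
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= affected <= total:
        raise ValueError("affected must lie in [0, total]")
    return int(math.floor(100.0 * affected / total + 0.5))
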