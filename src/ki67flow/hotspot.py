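"""Ki-67 hotspot identification and density-ordered 100-cell increments.

The hotspot is found on a measurement heat map: a grid whose cells hold
the Gaussian-weighted mean nuclear DAB OD (50 um smoothing) of nearby
tumour nuclei.  Scoring then proceeds exactly as in the digital
counting protocol: the first set of 100 tumour nuclei is taken at the
hottest cell, further sets continue in decreasing order of local
positive-staining density until five sets of 100 are counted.  Manual
delineation is replaced by a deterministic greedy rule — seed at the
hottest unmasked cell, take the 100 nearest unassigned tumour nuclei,
recompute the map from what remains, repeat.

A visual-assessment (VA) oracle is provided for synthetic experiments:
the same increment procedure driven by ground-truth positivity with a
perturbed hotspot seed, standing in for counting at the microscope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree
import shapely
from shapely.geometry import Polygon

from .classify import PositivityRule, TUMOUR
from .detect import NucleusDetection

__all__ = [
    "HeatMap",
    "IncrementSet",
    "build_heatmap",
    "exclude_artefacts",
    "select_increments",
    "truth_to_detections",
    "va_oracle_increments",
]


@dataclass
class HeatMap:
    """Raster of spatially smoothed nuclear DAB OD over a grid."""

    origin_um: tuple[float, float]
    grid_um: float
    values: np.ndarray          # (rows, cols), NaN where masked
    mask: np.ndarray            # True = masked (no data or excluded)
    smoothing_radius_um: float
    region: Polygon | None = None
    exclusion_polygons: tuple = ()

    def cell_centers(self):
        rows, cols = self.values.shape
        ys = self.origin_um[1] + (np.arange(rows) + 0.5) * self.grid_um
        xs = self.origin_um[0] + (np.arange(cols) + 0.5) * self.grid_um
        xx, yy = np.meshgrid(xs, ys)
        return xx, yy

    def argmax_center(self) -> tuple[float, float]:
        vals = np.where(self.mask, -np.inf, self.values)
        if not np.isfinite(vals).any():
            raise ValueError("no unmasked cells in heat map")
        r, c = np.unravel_index(np.argmax(vals), vals.shape)
        return (self.origin_um[0] + (c + 0.5) * self.grid_um,
                self.origin_um[1] + (r + 0.5) * self.grid_um)


@dataclass
class IncrementSet:
    """One density-ordered set of 100 counted tumour nuclei."""

    rank: int
    member_ids: list[int]
    n_positive: int
    centroid_um: tuple[float, float]


def _weighted_grid(points, values, origin, shape, grid_um, radius_um):
    """Gaussian-weighted mean of ``values`` at each grid-cell centre.

    Smoothing scale sigma = radius/2 (matching feature smoothing);
    cells with no point within 2*radius are NaN.
    """
    rows, cols = shape
    ys = origin[1] + (np.arange(rows) + 0.5) * grid_um
    xs = origin[0] + (np.arange(cols) + 0.5) * grid_um
    xx, yy = np.meshgrid(xs, ys)
    centers = np.column_stack([xx.ravel(), yy.ravel()])
    out = np.full(centers.shape[0], np.nan)
    if len(points) == 0:
        return out.reshape(shape)
    sigma = radius_um / 2.0
    cutoff = 2.0 * radius_um
    tree_c = cKDTree(centers)
    tree_p = cKDTree(points)
    w = tree_c.sparse_distance_matrix(tree_p, cutoff,
                                      output_type="coo_matrix")
    if w.nnz:
        data = np.exp(-(w.data**2) / (2 * sigma**2))
        num = np.bincount(w.row, weights=data * values[w.col],
                          minlength=len(centers))
        den = np.bincount(w.row, weights=data, minlength=len(centers))
        has = np.bincount(w.row, minlength=len(centers)) > 0
        with np.errstate(invalid="ignore"):
            out[has] = num[has] / den[has]
    return out.reshape(shape)


def _eligible(detections, region, exclusions, tumour_only=True):
    out = []
    for det in detections:
        if tumour_only and det.class_label != TUMOUR:
            continue
        x, y = det.centroid_um
        if region is not None and not shapely.contains_xy(region, x, y):
            continue
        if any(shapely.contains_xy(p, x, y) for p in exclusions):
            continue
        out.append(det)
    return out


def build_heatmap(detections, tumour_region_polygon: Polygon | None = None,
                  smoothing_radius_um: float = 50.0, grid_um: float = 25.0,
                  feature: str = "nucleus_dab_od_mean",
                  tumour_only: bool = True,
                  exclusion_polygons=()) -> HeatMap:
    """Build the smoothed nucleus-DAB-OD heat map over the tumour region.

    ``tumour_only=False`` includes unclassified/non-tumour nuclei (for
    workflows that map before classification).
    """
    if tumour_region_polygon is not None and tumour_region_polygon.is_empty:
        raise ValueError("empty tumour region")
    exclusions = tuple(exclusion_polygons)
    nuclei = _eligible(detections, tumour_region_polygon, exclusions,
                       tumour_only=tumour_only)
    if not nuclei:
        raise ValueError("no eligible tumour detections inside the region")

    if tumour_region_polygon is not None:
        x0, y0, x1, y1 = tumour_region_polygon.bounds
    else:
        pts = np.asarray([d.centroid_um for d in nuclei])
        x0, y0 = pts.min(axis=0)
        x1, y1 = pts.max(axis=0)
    shape = (max(1, int(np.ceil((y1 - y0) / grid_um))),
             max(1, int(np.ceil((x1 - x0) / grid_um))))

    pts = np.asarray([d.centroid_um for d in nuclei])
    vals = np.asarray([d.features[feature] for d in nuclei])
    values = _weighted_grid(pts, vals, (x0, y0), shape, grid_um,
                            smoothing_radius_um)

    mask = ~np.isfinite(values)
    hm = HeatMap(origin_um=(x0, y0), grid_um=grid_um, values=values,
                 mask=mask, smoothing_radius_um=smoothing_radius_um,
                 region=tumour_region_polygon)
    if tumour_region_polygon is not None:
        xx, yy = hm.cell_centers()
        inside = shapely.contains_xy(tumour_region_polygon, xx.ravel(),
                                     yy.ravel()).reshape(shape)
        hm.mask |= ~inside
    if exclusions:
        hm = exclude_artefacts(hm, exclusions)
    return hm


def exclude_artefacts(heatmap: HeatMap, exclusion_polygons) -> HeatMap:
    """Mask artefact regions so they never seed or feed hotspots."""
    exclusions = tuple(exclusion_polygons)
    if not exclusions:
        return heatmap
    xx, yy = heatmap.cell_centers()
    mask = heatmap.mask.copy()
    for poly in exclusions:
        inside = shapely.contains_xy(poly, xx.ravel(), yy.ravel())
        mask |= inside.reshape(heatmap.mask.shape)
    return replace(heatmap, mask=mask,
                   exclusion_polygons=heatmap.exclusion_polygons + exclusions)


def select_increments(detections, heatmap: HeatMap, n_sets: int = 5,
                      set_size: int = 100,
                      rule: PositivityRule | None = None,
                      feature: str = "nucleus_dab_od_mean"
                      ) -> list[IncrementSet]:
    """Greedy density-ordered selection of ``n_sets`` disjoint sets.

    Each round recomputes the heat map from still-unassigned tumour
    nuclei, seeds at its hottest unmasked cell and takes the
    ``set_size`` nearest unassigned nuclei.  Raises when fewer than
    ``n_sets * set_size`` eligible tumour nuclei exist.
    """
    if rule is None:
        rule = PositivityRule()
    if heatmap.mask.all():
        raise ValueError("no unmasked cells in heat map")
    eligible = _eligible(detections, heatmap.region,
                         heatmap.exclusion_polygons)
    need = n_sets * set_size
    if len(eligible) < need:
        raise ValueError(
            f"only {len(eligible)} eligible tumour nuclei; "
            f"{need} required ({need - len(eligible)} short)")

    pts = np.asarray([d.centroid_um for d in eligible])
    vals = np.asarray([d.features[feature] for d in eligible])
    positive = np.asarray([
        d.ki67_positive if d.ki67_positive is not None
        else d.features[feature] >= rule.threshold
        for d in eligible])

    unassigned = np.ones(len(eligible), dtype=bool)
    sets: list[IncrementSet] = []
    for rank in range(1, n_sets + 1):
        grid = _weighted_grid(pts[unassigned], vals[unassigned],
                              heatmap.origin_um, heatmap.values.shape,
                              heatmap.grid_um, heatmap.smoothing_radius_um)
        grid = np.where(heatmap.mask, np.nan, grid)
        if not np.isfinite(grid).any():
            raise ValueError("no unmasked cells with unassigned nuclei")
        r, c = np.unravel_index(np.nanargmax(grid), grid.shape)
        seed = np.array([heatmap.origin_um[0] + (c + 0.5) * heatmap.grid_um,
                         heatmap.origin_um[1] + (r + 0.5) * heatmap.grid_um])
        idx_un = np.flatnonzero(unassigned)
        d2 = ((pts[idx_un] - seed) ** 2).sum(axis=1)
        chosen = idx_un[np.argsort(d2)[:set_size]]
        unassigned[chosen] = False
        members = [eligible[i] for i in chosen]
        for det in members:
            det.increment_rank = rank
        centroid = pts[chosen].mean(axis=0)
        sets.append(IncrementSet(
            rank=rank, member_ids=[m.id for m in members],
            n_positive=int(positive[chosen].sum()),
            centroid_um=(float(centroid[0]), float(centroid[1]))))
    return sets


def truth_to_detections(truth_nuclei) -> list[NucleusDetection]:
    """Wrap ground-truth nuclei as detections with exact DAB features.

    The true DAB concentration plays the role of the measured
    ``nucleus_dab_od_mean`` (rendering followed by exact deconvolution
    recovers it), so heat maps and increments can run on ground truth.
    """
    out = []
    for t in truth_nuclei:
        det = NucleusDetection(
            id=t.id, nucleus_polygon=t.polygon,
            centroid_um=t.centroid_um,
            class_label=t.class_label,
            ki67_positive=t.ki67_positive)
        det.features["nucleus_dab_od_mean"] = t.dab_concentration
        out.append(det)
    return out


def va_oracle_increments(truth_nuclei, n_sets: int = 5, set_size: int = 100,
                         seed_offset_sd_um: float = 75.0,
                         smoothing_radius_um: float = 50.0,
                         grid_um: float = 25.0,
                         rng=None) -> list[IncrementSet]:
    """Emulated visual counting on ground truth.

    Builds a positivity-fraction heat map from true labels, perturbs
    the hotspot seed by a Gaussian offset (the pathologist's imprecision
    in locating the hotspot by eye), then counts five concentric sets
    of 100 tumour nuclei in increasing distance from that seed.
    """
    if rng is None:
        rng = np.random.default_rng()
    tumour = [t for t in truth_nuclei if t.class_label == TUMOUR]
    need = n_sets * set_size
    if len(tumour) < need:
        raise ValueError(
            f"only {len(tumour)} tumour nuclei; {need} required")
    pts = np.asarray([t.centroid_um for t in tumour])
    pos = np.asarray([t.ki67_positive for t in tumour], dtype=float)

    x0, y0 = pts.min(axis=0)
    x1, y1 = pts.max(axis=0)
    shape = (max(1, int(np.ceil((y1 - y0) / grid_um))),
             max(1, int(np.ceil((x1 - x0) / grid_um))))
    grid = _weighted_grid(pts, pos, (x0, y0), shape, grid_um,
                          smoothing_radius_um)
    r, c = np.unravel_index(np.nanargmax(np.nan_to_num(grid, nan=-np.inf)),
                            shape)
    seed = np.array([x0 + (c + 0.5) * grid_um, y0 + (r + 0.5) * grid_um])
    seed = seed + rng.normal(0.0, seed_offset_sd_um, size=2)

    order = np.argsort(((pts - seed) ** 2).sum(axis=1))
    sets = []
    for rank in range(1, n_sets + 1):
        chosen = order[(rank - 1) * set_size: rank * set_size]
        centroid = pts[chosen].mean(axis=0)
        sets.append(IncrementSet(
            rank=rank, member_ids=[tumour[i].id for i in chosen],
            n_positive=int(pos[chosen].sum()),
            centroid_um=(float(centroid[0]), float(centroid[1]))))
    return sets
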