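"""Consensus tumor boundary and N / IF / CT tissue partition.

The tumor boundary drawn on each of the five coregistered marker slides is
overlaid into a *score map* (per-pixel count of containing annotation
polygons); smoothing and a majority threshold (score > 2.5 of 5) give the
consensus boundary, which is buffered inward and outward by half the
invasive-front width to split the tissue into normal (N), invasive front
(IF) and central tumor (CT).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import MultiPolygon, Polygon
from skimage import measure

from .geometry import PointPattern, UM2_PER_MM2, as_multipolygon, clean_polygon

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreMap",
    "RegionPartition",
    "build_score_map",
    "consensus_boundary",
    "partition_regions",
    "extract_foreground",
    "assign_region",
    "mask_to_polygons",
]

#: default raster resolution, μm per pixel (well below the 500 μm IF buffer)
DEFAULT_RESOLUTION = 10.0
#: minimum island area retained, mm² (matches the profile-exclusion area)
MIN_ISLAND_MM2 = 1.1


@dataclass
class ScoreMap:
    """Integer raster of annotation-overlap counts.

    ``values[i, j]`` counts the annotation polygons containing the center of
    pixel row i / column j; ``origin`` is the world coordinate (μm) of the
    top-left pixel *corner*; ``resolution`` is μm per pixel.
    """

    values: np.ndarray
    resolution: float
    origin: tuple[float, float]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.values.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.resolution
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.resolution
        return xs, ys

    def world_to_pixel(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        xy = np.asarray(xy, float).reshape(-1, 2)
        col = np.floor((xy[:, 0] - self.origin[0]) / self.resolution).astype(int)
        row = np.floor((xy[:, 1] - self.origin[1]) / self.resolution).astype(int)
        return row, col


@dataclass
class RegionPartition:
    """Disjoint N / IF / CT polygons around a consensus tumor boundary."""

    boundary: Polygon | MultiPolygon
    normal: MultiPolygon
    invasive_front: MultiPolygon
    central_tumor: MultiPolygon
    if_width_mm: float = 1.0

    def region(self, name: str) -> MultiPolygon:
        return {"N": self.normal, "IF": self.invasive_front, "CT": self.central_tumor}[name]

    def areas_mm2(self) -> dict[str, float]:
        return {
            "N": self.normal.area / UM2_PER_MM2,
            "IF": self.invasive_front.area / UM2_PER_MM2,
            "CT": self.central_tumor.area / UM2_PER_MM2,
        }

    @property
    def foreground(self) -> MultiPolygon:
        return as_multipolygon(
            self.normal.union(self.invasive_front).union(self.central_tumor)
        )


def build_score_map(
    annotations: list[Polygon],
    resolution: float = DEFAULT_RESOLUTION,
    pad_um: float = 200.0,
) -> ScoreMap:
    """Overlay annotation polygons into a per-pixel overlap-count raster."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if not annotations:
        raise ValueError("need at least one annotation polygon")
    annotations = [clean_polygon(p) for p in annotations]
    xs0 = min(p.bounds[0] for p in annotations) - pad_um
    ys0 = min(p.bounds[1] for p in annotations) - pad_um
    xs1 = max(p.bounds[2] for p in annotations) + pad_um
    ys1 = max(p.bounds[3] for p in annotations) + pad_um
    nx = max(1, int(np.ceil((xs1 - xs0) / resolution)))
    ny = max(1, int(np.ceil((ys1 - ys0) / resolution)))
    sm = ScoreMap(np.zeros((ny, nx), dtype=np.int16), resolution, (xs0, ys0))
    xs, ys = sm.pixel_centers()
    gx, gy = np.meshgrid(xs, ys)
    for poly in annotations:
        sm.values += shapely.contains_xy(poly, gx, gy).astype(np.int16)
    return sm


def mask_to_polygons(
    mask: np.ndarray,
    resolution: float,
    origin: tuple[float, float],
    min_area_mm2: float = 0.0,
) -> MultiPolygon:
    """Vectorise a boolean raster mask into world-coordinate polygons.

    Contours are traced at the half level on a zero-padded copy, mapped from
    pixel to μm coordinates, and nested rings are resolved into exteriors
    and holes.  Components smaller than *min_area_mm2* are dropped.
    """
    if not mask.any():
        return MultiPolygon([])
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    rings = []
    for c in contours:
        # rows/cols of the padded array -> world μm; pixel center offset 0.5
        y = origin[1] + (c[:, 0] - 1 + 0.5) * resolution
        x = origin[0] + (c[:, 1] - 1 + 0.5) * resolution
        if len(c) >= 4:
            rings.append(Polygon(np.column_stack([x, y])))
    if not rings:
        return MultiPolygon([])
    rings.sort(key=lambda p: p.area, reverse=True)
    exteriors: list[tuple[Polygon, list]] = []
    for ring in rings:
        placed = False
        for ext, holes in exteriors:
            if ext.contains(ring.representative_point()):
                holes.append(ring.exterior.coords)
                placed = True
                break
        if not placed:
            exteriors.append((ring, []))
    polys = [
        clean_polygon(Polygon(ext.exterior.coords, holes)) for ext, holes in exteriors
    ]
    flat: list[Polygon] = []
    for p in polys:
        flat.extend(as_multipolygon(p).geoms)
    keep = [p for p in flat if p.area / UM2_PER_MM2 >= min_area_mm2]
    return MultiPolygon(keep)


def consensus_boundary(
    score_map: ScoreMap,
    threshold: float = 2.5,
    smooth_sigma: float = 50.0,
    min_island_mm2: float = MIN_ISLAND_MM2,
) -> Polygon | MultiPolygon:
    """Threshold the smoothed score map into the consensus tumor boundary.

    The raster is Gaussian-smoothed (σ in μm) *before* thresholding; pixels
    with score > *threshold* form the tumor mask, each connected component
    above *min_island_mm2* becomes one boundary polygon (multiple tumor
    islands yield a MultiPolygon).
    """
    if score_map.values.size == 0:
        raise ValueError("empty score map")
    sigma_px = smooth_sigma / score_map.resolution
    smoothed = ndimage.gaussian_filter(score_map.values.astype(float), sigma_px)
    mask = smoothed > threshold
    if not mask.any():
        raise ValueError(
            f"no consensus region: no pixel exceeds score {threshold} after smoothing"
        )
    labels, nlab = ndimage.label(mask)
    px_area_mm2 = score_map.resolution**2 / UM2_PER_MM2
    keep = np.zeros_like(mask)
    kept = 0
    for lab in range(1, nlab + 1):
        comp = labels == lab
        if comp.sum() * px_area_mm2 >= min_island_mm2:
            keep |= comp
            kept += 1
    if kept == 0:
        raise ValueError("no consensus region: all components below minimum area")
    mp = mask_to_polygons(keep, score_map.resolution, score_map.origin)
    return mp.geoms[0] if len(mp.geoms) == 1 else mp


def partition_regions(
    boundary: Polygon | MultiPolygon,
    foreground: Polygon | MultiPolygon,
    if_width_mm: float = 1.0,
) -> RegionPartition:
    """Split foreground tissue into N / IF / CT around a tumor boundary.

    The IF is the foreground within ``if_width_mm/2`` on either side of the
    boundary *curve*; CT is the rest of the tumor mask; N is the remaining
    foreground.
    """
    if if_width_mm <= 0:
        raise ValueError("if_width_mm must be positive")
    boundary = clean_polygon(boundary) if isinstance(boundary, Polygon) else boundary
    fg = shapely.make_valid(
        foreground if not isinstance(foreground, Polygon) else clean_polygon(foreground)
    )
    if not fg.intersects(boundary):
        raise ValueError("tumor boundary lies outside the tissue foreground")
    half_um = if_width_mm * 1000.0 / 2.0
    band = boundary.boundary.buffer(half_um)
    invasive = as_multipolygon(fg.intersection(band))
    tumor = boundary if boundary.is_valid else shapely.make_valid(boundary)
    central = as_multipolygon(fg.intersection(tumor).difference(band))
    normal = as_multipolygon(fg.difference(tumor).difference(band))
    return RegionPartition(boundary, normal, invasive, central, if_width_mm)


def extract_foreground(
    rgb_mean_raster: np.ndarray,
    intensity_threshold: float = 230.0,
    resolution: float = DEFAULT_RESOLUTION,
    origin: tuple[float, float] = (0.0, 0.0),
) -> MultiPolygon:
    """Tissue foreground from a mean-RGB raster: keep pixels below threshold."""
    raster = np.asarray(rgb_mean_raster, float)
    if raster.size == 0:
        raise ValueError("empty raster")
    mask = raster < intensity_threshold
    if not mask.any():
        raise ValueError("no foreground: every pixel is at or above the threshold")
    return mask_to_polygons(mask, resolution, origin)


REGION_PRECEDENCE = ("IF", "CT", "N")


def assign_region(pattern: PointPattern, partition: RegionPartition) -> np.ndarray:
    """Label each point N / IF / CT / outside by point-in-polygon tests.

    Points exactly on a shared border are resolved by precedence
    IF > CT > N (``covers`` includes region boundaries).
    """
    labels = np.full(pattern.n, "outside", dtype=object)
    if pattern.n == 0:
        return labels
    x, y = pattern.points[:, 0], pattern.points[:, 1]
    unassigned = np.ones(pattern.n, dtype=bool)
    for name in REGION_PRECEDENCE:
        geom = partition.region(name)
        inside = shapely.contains_xy(geom, x, y) | shapely.intersects_xy(geom.boundary, x, y)
        take = unassigned & inside
        labels[take] = name
        unassigned &= ~take
    return labels
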