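"""Cell density versus distance-to-boundary profiles and IF sectioning.

Implements the pixel-distance banding of the tissue (150 μm bands with
signed indices, 0 = central invasive-front band, negative toward normal
tissue, positive toward the tumor core), the 95 % confidence band
D ± T_c·σ/√n with n = A/(s_l·s_w), the within-IF Voronoi sectioning along
the boundary midline, and the quadrat chi-square heterogeneity test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from shapely.geometry import MultiPolygon, Polygon

from .geometry import PointPattern, UM2_PER_MM2
from .regions import DEFAULT_RESOLUTION, RegionPartition, mask_to_polygons

__all__ = [
    "BandSet",
    "IFSection",
    "QuadratTestResult",
    "distance_bands",
    "band_profile",
    "confidence_band",
    "if_sections",
    "quadrat_chi2",
]

#: critical value of the 95 % confidence interval (two-sided standard normal)
T_CRITICAL = 1.96
#: band/section areas below this are excluded from profiles (mm²)
MIN_BAND_AREA_MM2 = 1.1
#: reliability rule: flag when the CI half-width exceeds this fraction of D
RELIABILITY_FRACTION = 0.8

_BACKGROUND = np.iinfo(np.int32).min  # sentinel index for non-tissue pixels


@dataclass
class BandSet:
    """Signed distance-band labelling of the tissue raster."""

    index_raster: np.ndarray  # int32, _BACKGROUND outside tissue
    resolution: float  # μm / pixel
    origin: tuple[float, float]
    interval_um: float
    band_region: dict[int, str]  # band index -> N / IF / CT

    @property
    def indices(self) -> np.ndarray:
        vals = np.unique(self.index_raster)
        return np.sort(vals[vals != _BACKGROUND])

    def areas_mm2(self) -> dict[int, float]:
        px = self.resolution**2 / UM2_PER_MM2
        idx, counts = np.unique(self.index_raster, return_counts=True)
        return {int(i): float(c) * px for i, c in zip(idx, counts) if i != _BACKGROUND}

    def point_band(self, points: np.ndarray) -> np.ndarray:
        """Band index of each point (background sentinel if off-tissue)."""
        pts = np.asarray(points, float).reshape(-1, 2)
        col = np.floor((pts[:, 0] - self.origin[0]) / self.resolution).astype(int)
        row = np.floor((pts[:, 1] - self.origin[1]) / self.resolution).astype(int)
        ny, nx = self.index_raster.shape
        ok = (row >= 0) & (row < ny) & (col >= 0) & (col < nx)
        out = np.full(len(pts), _BACKGROUND, dtype=np.int64)
        out[ok] = self.index_raster[row[ok], col[ok]]
        return out

    def band_polygon(self, index: int, min_area_mm2: float = 0.0) -> MultiPolygon:
        """Concave outline of one band (raster contour tracing)."""
        return mask_to_polygons(
            self.index_raster == index, self.resolution, self.origin, min_area_mm2
        )


def _region_masks(partition: RegionPartition, resolution: float, pad_um: float = 50.0):
    """Rasterize the partition; returns masks + grid geometry."""
    x0, y0, x1, y1 = partition.foreground.bounds
    x0, y0 = x0 - pad_um, y0 - pad_um
    nx = int(np.ceil((x1 + pad_um - x0) / resolution))
    ny = int(np.ceil((y1 + pad_um - y0) / resolution))
    xs = x0 + (np.arange(nx) + 0.5) * resolution
    ys = y0 + (np.arange(ny) + 0.5) * resolution
    gx, gy = np.meshgrid(xs, ys)
    half_um = partition.if_width_mm * 1000.0 / 2.0
    tumor = partition.boundary
    inner = tumor.buffer(-half_um)
    outer = tumor.buffer(half_um)
    fg = shapely.contains_xy(partition.foreground, gx, gy)
    in_inner = shapely.contains_xy(inner, gx, gy) if not inner.is_empty else np.zeros_like(fg)
    in_outer = shapely.contains_xy(outer, gx, gy)
    ct = fg & in_inner
    iff = fg & in_outer & ~in_inner
    nn = fg & ~in_outer
    return ct, iff, nn, (x0, y0)


def distance_bands(
    partition: RegionPartition,
    interval_um: float = 150.0,
    resolution: float = DEFAULT_RESOLUTION,
) -> BandSet:
    """Band the tissue raster by pixel distance to the IF boundaries.

    CT and IF pixels are grouped by Euclidean distance to the IF *inner*
    boundary (adjacent to CT), N pixels by distance to the IF *outer*
    boundary, in intervals of *interval_um*; indices are signed with 0 the
    central IF band.  An empty region on one side simply yields no bands on
    that side.
    """
    ct, iff, nn, origin = _region_masks(partition, resolution)
    w = partition.if_width_mm * 1000.0
    i = float(interval_um)
    c = int(np.floor((w / 2.0) / i))
    m = int(np.floor((w - 1e-6) / i))

    idx = np.full(ct.shape, _BACKGROUND, dtype=np.int32)
    # distance (px) of every non-CT pixel to the CT zone = inner boundary
    if ct.any():
        d_to_ct = ndimage.distance_transform_edt(~ct) * resolution
        d_in_ct = ndimage.distance_transform_edt(ct) * resolution
        idx[iff] = c - np.floor(d_to_ct[iff] / i).astype(np.int32)
        idx[ct] = c + 1 + np.floor(d_in_ct[ct] / i).astype(np.int32)
    else:  # no tumor core on the raster: index IF from its outer edge
        inside_outer = iff | ct
        d_out_edge = ndimage.distance_transform_edt(inside_outer) * resolution
        idx[iff] = (c - m) + np.floor(d_out_edge[iff] / i).astype(np.int32)
    inside_outer = ct | iff
    if nn.any() and inside_outer.any():
        d_to_if = ndimage.distance_transform_edt(~inside_outer) * resolution
        idx[nn] = (c - m) - 1 - np.floor(d_to_if[nn] / i).astype(np.int32)

    band_region: dict[int, str] = {}
    for mask, name in ((nn, "N"), (iff, "IF"), (ct, "CT")):
        vals, counts = np.unique(idx[mask], return_counts=True)
        for v, cnt in zip(vals, counts):
            if v == _BACKGROUND:
                continue
            # a band is labelled by the tissue type owning most of its pixels
            if v not in band_region or cnt > band_region[v][1]:
                band_region[v] = (name, cnt)
    return BandSet(
        idx, resolution, origin, i, {k: v[0] for k, v in band_region.items()}
    )


def band_profile(
    pattern: PointPattern,
    bands: BandSet,
    min_area_mm2: float = MIN_BAND_AREA_MM2,
) -> pd.DataFrame:
    """Density per distance band; bands smaller than *min_area_mm2* dropped.

    Returns a DataFrame (band_index, distance_mm, area_mm2, count,
    density_mm2, region) ordered by band index; ``distance_mm`` is the
    signed distance of the band center from the boundary midline.
    """
    areas = bands.areas_mm2()
    pt_band = bands.point_band(pattern.points) if pattern.n else np.empty(0, int)
    rows = []
    for index in bands.indices:
        a = areas.get(int(index), 0.0)
        if a < min_area_mm2:
            continue
        count = int(np.sum(pt_band == index))
        rows.append(
            {
                "band_index": int(index),
                "distance_mm": index * bands.interval_um / 1000.0,
                "area_mm2": a,
                "count": count,
                "density_mm2": count / a if a > 0 else 0.0,
                "region": bands.band_region.get(int(index), ""),
            }
        )
    return pd.DataFrame(rows)


def confidence_band(
    profile: pd.DataFrame,
    region_sd: dict[str, float],
    window_mm: float = 0.4,
    t_critical: float = T_CRITICAL,
) -> pd.DataFrame:
    """Attach the 95 % CI D ± T_c·σ/√n to a band profile.

    σ is the density SD of moving windows of the band's tissue type over
    the whole slide; n = A/(s_l·s_w) is the effective number of windows in
    the band.  The lower bound is truncated at 0, and a band is flagged
    unreliable when the half-width exceeds 80 % of its density.
    """
    if (profile["area_mm2"] <= 0).any():
        raise ValueError("confidence band requires positive band areas")
    out = profile.copy()
    n_eff = out["area_mm2"] / (window_mm * window_mm)
    sd = out["region"].map(lambda r: region_sd.get(r, 0.0)).astype(float)
    half = t_critical * sd / np.sqrt(n_eff)
    out["n_windows"] = n_eff
    out["ci_low"] = np.maximum(out["density_mm2"] - half, 0.0)
    out["ci_high"] = out["density_mm2"] + half
    out["reliable"] = half <= RELIABILITY_FRACTION * out["density_mm2"]
    return out


@dataclass
class IFSection:
    """One Voronoi section of the invasive front along the boundary midline."""

    index: int  # 1-based, clockwise from the left-most sample point
    sample_point: tuple[float, float]
    area_mm2: float
    count: int
    density_mm2: float
    polygon: MultiPolygon | None = None


def _boundary_ring(partition: RegionPartition):
    geom = partition.boundary
    if isinstance(geom, MultiPolygon):
        geom = max(geom.geoms, key=lambda g: g.area)
    ring = geom.exterior
    # image convention (y down): visual clockwise traversal = CCW signed area
    if not ring.is_ccw:
        ring = shapely.LinearRing(list(ring.coords)[::-1])
    return ring


def if_sections(
    partition: RegionPartition,
    pattern: PointPattern | None = None,
    spacing_mm: float = 0.2,
    resolution: float = DEFAULT_RESOLUTION,
    with_polygons: bool = False,
) -> list[IFSection]:
    """Voronoi sectioning of the IF from equispaced boundary sample points.

    Sample points are spaced *spacing_mm* by arclength along the consensus
    boundary (the IF centerline); each IF pixel joins the nearest sample
    point (ties to the lowest index); sections are numbered from 1 at the
    left-most sample point, proceeding clockwise.
    """
    ring = _boundary_ring(partition)
    length = ring.length
    spacing = spacing_mm * 1000.0
    n_sec = max(1, int(np.floor(length / spacing)))
    dists = np.arange(n_sec) * spacing
    pts = np.array([ring.interpolate(float(d)).coords[0] for d in dists])
    start = np.lexsort((pts[:, 1], pts[:, 0]))[0]  # left-most, ties by y
    pts = np.roll(pts, -start, axis=0)

    _, iff, _, origin = _region_masks(partition, resolution)
    rows, cols = np.nonzero(iff)
    px = origin[0] + (cols + 0.5) * resolution
    py = origin[1] + (rows + 0.5) * resolution
    tree = cKDTree(pts)
    _, owner = tree.query(np.column_stack([px, py]))
    px_area = resolution**2 / UM2_PER_MM2

    if pattern is not None and pattern.n:
        inside = shapely.contains_xy(partition.invasive_front, pattern.points[:, 0], pattern.points[:, 1])
        cpts = pattern.points[inside]
        _, p_owner = tree.query(cpts) if len(cpts) else (None, np.empty(0, int))
    else:
        p_owner = np.empty(0, int)

    sections = []
    for k in range(len(pts)):
        npix = int(np.sum(owner == k))
        area = npix * px_area
        count = int(np.sum(p_owner == k))
        poly = None
        if with_polygons:
            mask = np.zeros_like(iff)
            mask[rows[owner == k], cols[owner == k]] = True
            poly = mask_to_polygons(mask, resolution, origin)
        sections.append(
            IFSection(
                index=k + 1,
                sample_point=(float(pts[k, 0]), float(pts[k, 1])),
                area_mm2=area,
                count=count,
                density_mm2=count / area if area > 0 else 0.0,
                polygon=poly,
            )
        )
    return sections


@dataclass
class QuadratTestResult:
    chi2: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray
    valid: bool = True  # False when many small expected counts

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"QuadratTestResult(chi2={self.chi2:.3f}, df={self.df}, p={self.p_value:.3g})"


def quadrat_chi2(counts: np.ndarray, areas: np.ndarray) -> QuadratTestResult:
    """Pearson chi-square test of counts against area-proportional expectation.

    Under a homogeneous (binomial) allocation the expected count of section
    i is ``total · area_i / Σ area``; df = k − 1.  A validity warning is
    issued when more than 20 % of expected counts fall below 1.
    """
    counts = np.asarray(counts, float)
    areas = np.asarray(areas, float)
    if counts.size < 2:
        raise ValueError("need at least two sections")
    total = counts.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    expected = total * areas / areas.sum()
    valid = True
    if np.mean(expected < 1.0) > 0.2:
        valid = False
        warnings.warn(
            "more than 20% of expected counts are below 1; chi-square "
            "approximation may be unreliable",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    chi2 = float(terms.sum())
    df = counts.size - 1
    p = float(stats.chi2.sf(chi2, df))
    return QuadratTestResult(chi2, df, p, counts, expected, valid)
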