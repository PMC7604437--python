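"""Core planar geometry and I/O for cell tables, annotations and transforms.

All coordinates are micrometers in the reference-slide frame (image
convention: origin top-left, y increasing downward).  Areas reported to the
user are mm²; densities are mm⁻².  Geometry is backed by :mod:`shapely`.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import (
    GeometryCollection,
    MultiPolygon,
    Polygon,
    box,
    mapping,
    shape,
)

logger = logging.getLogger(__name__)

UM2_PER_MM2 = 1.0e6

__all__ = [
    "PointPattern",
    "AffineTransform",
    "read_cell_table",
    "read_annotations",
    "read_affine_matrices",
    "write_regions_geojson",
    "apply_affine",
    "dice_similarity",
    "polygon_area",
    "clean_polygon",
    "as_multipolygon",
]


@dataclass
class PointPattern:
    """A marker-labelled planar point set with an observation window.

    Parameters
    ----------
    marker : str
        Immune-marker label (e.g. ``"CD8"``).
    points : ndarray of shape (n, 2)
        Cell centroid coordinates in μm.
    window : shapely.Polygon
        Observation region in μm; must have positive area.
    slide_id : str
        Identifier of the originating slide.
    """

    marker: str
    points: np.ndarray
    window: Polygon
    slide_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if pts.size and not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite")
        self.points = pts
        if self.window is None:
            self.window = bounding_window(pts)
        if self.window.area <= 0:
            raise ValueError("observation window must have positive area")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def area_mm2(self) -> float:
        """Window area in mm²."""
        return self.window.area / UM2_PER_MM2

    @property
    def intensity_mm2(self) -> float:
        """Naive intensity estimate n / |W| in mm⁻²."""
        return self.n / self.area_mm2

    def subset(self, mask: np.ndarray, window: Polygon | None = None) -> "PointPattern":
        return PointPattern(
            self.marker, self.points[mask], window or self.window, self.slide_id
        )


@dataclass
class AffineTransform:
    """Homogeneous 3×3 affine transform, slide → reference frame (μm)."""

    matrix: np.ndarray
    slide_id: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("affine matrix must be 3x3")
        if not np.allclose(m[2], [0.0, 0.0, 1.0]):
            raise ValueError("last row of an affine matrix must be (0, 0, 1)")
        if abs(np.linalg.det(m[:2, :2])) < 1e-15:
            raise ValueError("affine matrix is singular")
        self.matrix = m

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3))

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), self.slide_id)

    def __call__(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        return xy @ self.matrix[:2, :2].T + self.matrix[:2, 2]


def bounding_window(points: np.ndarray, pad: float = 0.0) -> Polygon:
    """Axis-aligned bounding box of *points*, optionally padded (μm)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("cannot build a bounding window for an empty point set")
    (x0, y0), (x1, y1) = pts.min(axis=0), pts.max(axis=0)
    if x1 - x0 <= 0 or y1 - y0 <= 0:
        pad = max(pad, 1.0)  # degenerate extent: give it a nominal 1 μm box
    return box(x0 - pad, y0 - pad, x1 + pad, y1 + pad)


REQUIRED_COLUMNS = ("slide_id", "marker", "x_um", "y_um")


def read_cell_table(
    path: str | Path,
    marker_filter: str | None = None,
    window: Polygon | None = None,
) -> list[PointPattern]:
    """Read a cell-coordinate table into one pattern per (slide, marker).

    The table is the standard export of WSI nucleus-detection software:
    CSV or TSV (dialect auto-detected), UTF-8, header required, columns
    ``slide_id, marker, x_um, y_um``.

    Parameters
    ----------
    path : path
        Input table.
    marker_filter : str, optional
        If given, only patterns for this marker are returned.
    window : shapely.Polygon, optional
        Observation window to attach to every pattern; defaults to each
        pattern's bounding box.

    Raises
    ------
    ValueError
        If a required column is missing (the message names it), or a
        coordinate fails to parse (the message gives the file line number).
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        sample = fh.read(4096)
    try:
        dialect = csv.Sniffer().sniff(sample, delimiters=",\t")
        sep = dialect.delimiter
    except csv.Error:
        sep = ","
    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"cell table {path.name}: missing required column '{col}'")
    for col in ("x_um", "y_um"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(
                f"cell table {path.name}: non-numeric {col} value "
                f"{df[col][bad.idxmax()]!r} at line {line}"
            )
        df[col] = coerced
    df = df.dropna(subset=["x_um", "y_um"])
    if marker_filter is not None:
        df = df[df["marker"] == marker_filter]
    patterns = []
    for (slide_id, marker), grp in df.groupby(["slide_id", "marker"], sort=True):
        pts = grp[["x_um", "y_um"]].to_numpy(float)
        patterns.append(
            PointPattern(str(marker), pts, window or bounding_window(pts), str(slide_id))
        )
    return patterns


def write_cell_table(patterns: Iterable[PointPattern], path: str | Path) -> None:
    rows = []
    for p in patterns:
        for x, y in p.points:
            rows.append((p.slide_id, p.marker, x, y))
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)


def clean_polygon(poly: Polygon) -> Polygon | MultiPolygon:
    """Repair an invalid (e.g. self-intersecting) polygon by zero-buffering."""
    if poly.is_valid:
        return poly
    logger.warning("repairing invalid polygon via zero-width buffer")
    fixed = poly.buffer(0)
    if fixed.is_empty:
        raise ValueError("polygon could not be repaired (empty after cleaning)")
    return fixed


def read_annotations(path: str | Path) -> list[tuple[str, Polygon]]:
    """Read a GeoJSON FeatureCollection of annotation polygons.

    Returns ``(marker, polygon)`` pairs; the marker comes from the feature's
    ``properties.marker`` (empty string if absent).  Invalid rings are
    repaired by zero-buffering.
    """
    with open(path, "r", encoding="utf-8") as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    out: list[tuple[str, Polygon]] = []
    for feat in gj.get("features", []):
        geom = shape(feat["geometry"])
        if geom.geom_type == "MultiPolygon":
            geoms = list(geom.geoms)
        elif geom.geom_type == "Polygon":
            geoms = [geom]
        else:
            raise ValueError(f"{path}: unsupported geometry type {geom.geom_type}")
        marker = str(feat.get("properties", {}).get("marker", ""))
        for g in geoms:
            out.append((marker, clean_polygon(g)))
    return out


def write_annotations(
    items: Iterable[tuple[str, Polygon]], path: str | Path, prop: str = "marker"
) -> None:
    feats = [
        {"type": "Feature", "properties": {prop: name}, "geometry": mapping(geom)}
        for name, geom in items
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def write_regions_geojson(partition, path: str | Path) -> None:
    """Export a region partition as GeoJSON with a ``region`` property."""
    items = [
        ("N", partition.normal),
        ("IF", partition.invasive_front),
        ("CT", partition.central_tumor),
    ]
    write_annotations(items, path, prop="region")


def read_affine_matrices(path: str | Path) -> dict[str, AffineTransform]:
    """Read per-slide affine matrices from JSON.

    Accepts either a single object ``{"slide_id": ..., "matrix": [[...]]}``
    or a list of such objects; returns a dict keyed by slide id.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    if isinstance(data, dict):
        data = [data]
    out = {}
    for entry in data:
        sid = str(entry["slide_id"])
        out[sid] = AffineTransform(np.asarray(entry["matrix"], float), sid)
    return out


def _transform_polygon(poly: Polygon, T: AffineTransform) -> Polygon:
    ext = T(np.asarray(poly.exterior.coords))
    holes = [T(np.asarray(ring.coords)) for ring in poly.interiors]
    return Polygon(ext, holes)


def apply_affine(geom, T: AffineTransform):
    """Map a :class:`PointPattern` or polygon through an affine transform.

    The same type comes back: patterns get their points *and* window mapped,
    polygons get exterior and holes mapped.  Point count is preserved.
    """
    if isinstance(geom, PointPattern):
        return PointPattern(
            geom.marker, T(geom.points) if geom.n else geom.points.copy(),
            _transform_polygon(geom.window, T), geom.slide_id,
        )
    if isinstance(geom, MultiPolygon):
        return MultiPolygon([_transform_polygon(p, T) for p in geom.geoms])
    if isinstance(geom, Polygon):
        return _transform_polygon(geom, T)
    raise TypeError(f"cannot apply affine transform to {type(geom).__name__}")


def dice_similarity(a: Polygon, b: Polygon) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) of two polygons."""
    a, b = clean_polygon(a), clean_polygon(b)
    denom = a.area + b.area
    if denom <= 0:
        raise ValueError("Dice similarity undefined: both polygons have zero area")
    return 2.0 * a.intersection(b).area / denom


def polygon_area(poly: Polygon | MultiPolygon) -> float:
    """Area of a polygon in mm² (holes subtracted); input coordinates in μm."""
    if isinstance(poly, Polygon) and len(poly.exterior.coords) < 4:
        raise ValueError("degenerate polygon: fewer than 3 vertices")
    return clean_polygon(poly).area / UM2_PER_MM2 if isinstance(poly, Polygon) else poly.area / UM2_PER_MM2


def as_multipolygon(geom) -> MultiPolygon:
    """Normalise any shapely polygonal geometry to a MultiPolygon."""
    if isinstance(geom, MultiPolygon):
        return geom
    if isinstance(geom, Polygon):
        return MultiPolygon([geom]) if not geom.is_empty else MultiPolygon([])
    if isinstance(geom, GeometryCollection):
        polys = [g for g in geom.geoms if isinstance(g, (Polygon, MultiPolygon))]
        out: list[Polygon] = []
        for g in polys:
            out.extend(g.geoms if isinstance(g, MultiPolygon) else [g])
        return MultiPolygon(out)
    if geom.is_empty:
        return MultiPolygon([])
    raise TypeError(f"not a polygonal geometry: {geom.geom_type}")
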