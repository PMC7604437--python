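"""Moving-window partition of a slide and first-order density statistics.

A rectangular window (default 0.4 × 0.4 mm) traverses the slide bounding
box with a stride (default 0.2 mm, i.e. 50 % overlap); every scanned
rectangle is a *subregion*.  Counts use half-open rectangles
[x0, x0+w) × [y0, y0+h) so a point's membership in each overlapping window
is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPolygon, Polygon, box

from .geometry import PointPattern, UM2_PER_MM2
from .regions import RegionPartition, assign_region

__all__ = ["SubregionGrid", "make_grid", "subregion_counts", "waterfall_table", "landscape_export"]

MM = 1000.0  # μm per mm


@dataclass
class SubregionGrid:
    """Overlapping-window tiling with per-subregion counts and densities.

    ``table`` columns: id, x0_um, y0_um, count, density_mm2, region, partial
    (window not fully inside the foreground extent).
    """

    window_mm: float
    step_mm: float
    table: pd.DataFrame
    extent: Polygon | MultiPolygon

    @property
    def window_area_mm2(self) -> float:
        return self.window_mm * self.window_mm

    def rectangles(self) -> list[Polygon]:
        w = self.window_mm * MM
        return [box(r.x0_um, r.y0_um, r.x0_um + w, r.y0_um + w) for r in self.table.itertuples()]

    def region_sd(self, ddof: int = 1) -> dict[str, float]:
        """Sample SD of window densities per tissue type (CI input)."""
        out = {}
        for name, grp in self.table.groupby("region"):
            out[name] = float(grp["density_mm2"].std(ddof=ddof)) if len(grp) > ddof else 0.0
        return out


def make_grid(
    extent: Polygon | MultiPolygon,
    window_mm: float = 0.4,
    step_mm: float = 0.2,
    partition: RegionPartition | None = None,
) -> SubregionGrid:
    """Tile the extent's bounding box with a moving rectangular window.

    Windows start at the bounding-box corner and advance by *step_mm*; a
    window is laid down whenever it fits inside the bounding box, i.e.
    ``floor((L - w)/s) + 1`` windows per axis.  Each window is labelled with
    the region containing its center (``partition`` given) and flagged
    *partial* when not fully covered by the extent geometry.
    """
    if extent is None or extent.is_empty:
        raise ValueError("extent is empty")
    if not (window_mm >= step_mm > 0):
        raise ValueError("require window >= step > 0")
    x0, y0, x1, y1 = extent.bounds
    w, s = window_mm * MM, step_mm * MM
    nx = max(1, int(np.floor((x1 - x0 - w) / s + 1e-9)) + 1)
    ny = max(1, int(np.floor((y1 - y0 - w) / s + 1e-9)) + 1)
    ii, jj = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    xs = x0 + jj.ravel() * s
    ys = y0 + ii.ravel() * s
    cx, cy = xs + w / 2, ys + w / 2
    if partition is not None:
        centers = PointPattern("_centers", np.column_stack([cx, cy]), box(x0, y0, max(x1, x0 + w), max(y1, y0 + w)))
        region = assign_region(centers, partition)
    else:
        region = np.full(xs.size, "", dtype=object)
    # partial flag: window rectangle not entirely inside the extent geometry
    rects = shapely.box(xs, ys, xs + w, ys + w)
    partial = ~shapely.covers(extent, rects)
    table = pd.DataFrame(
        {
            "id": np.arange(xs.size),
            "x0_um": xs,
            "y0_um": ys,
            "count": 0,
            "density_mm2": 0.0,
            "region": region,
            "partial": partial,
        }
    )
    return SubregionGrid(window_mm, step_mm, table, extent)


def _covering_indices(u: np.ndarray, u0: float, w: float, s: float, nmax: int):
    """Window indices j with u0 + j*s <= u < u0 + j*s + w, clipped to range."""
    jmax = np.floor((u - u0) / s + 1e-12).astype(int)
    jmin = np.ceil((u - u0 - w) / s - 1e-12).astype(int)
    # strict half-open upper edge: u == u0 + j*s + w excluded
    on_edge = np.isclose(u - u0 - jmin * s, w)
    jmin = jmin + on_edge.astype(int)
    return np.clip(jmin, 0, nmax - 1), np.clip(jmax, 0, nmax - 1)


def subregion_counts(pattern: PointPattern, grid: SubregionGrid) -> SubregionGrid:
    """Fill per-subregion point counts and densities (count / window area)."""
    w, s = grid.window_mm * MM, grid.step_mm * MM
    t = grid.table
    x0, y0 = float(t["x0_um"].min()), float(t["y0_um"].min())
    nx = int(round((t["x0_um"].max() - x0) / s)) + 1
    ny = int(round((t["y0_um"].max() - y0) / s)) + 1
    counts = np.zeros((ny, nx), dtype=np.int64)
    if pattern.n:
        px, py = pattern.points[:, 0], pattern.points[:, 1]
        inside = (px >= x0) & (py >= y0) & (px < x0 + (nx - 1) * s + w) & (py < y0 + (ny - 1) * s + w)
        px, py = px[inside], py[inside]
        jmin, jmax = _covering_indices(px, x0, w, s, nx)
        imin, imax = _covering_indices(py, y0, w, s, ny)
        span = int(np.ceil(w / s))
        for dj in range(span):
            for di in range(span):
                j = jmin + dj
                i = imin + di
                ok = (j <= jmax) & (i <= imax)
                np.add.at(counts, (i[ok], j[ok]), 1)
    t = t.copy()
    t["count"] = counts.ravel()
    t["density_mm2"] = t["count"] / grid.window_area_mm2
    return SubregionGrid(grid.window_mm, grid.step_mm, t, grid.extent)


def waterfall_table(grid: SubregionGrid) -> pd.DataFrame:
    """Subregions ranked by density, highest first (ties by id ascending)."""
    t = grid.table.sort_values(["density_mm2", "id"], ascending=[False, True])
    return t[["id", "density_mm2", "region"]].reset_index(drop=True)


def landscape_export(grid: SubregionGrid, path: str | Path) -> pd.DataFrame:
    """Write (x_center, y_center, density, region) surface data as CSV."""
    w = grid.window_mm * MM
    out = pd.DataFrame(
        {
            "x_center_um": grid.table["x0_um"] + w / 2,
            "y_center_um": grid.table["y0_um"] + w / 2,
            "density_mm2": grid.table["density_mm2"],
            "region": grid.table["region"],
        }
    )
    out.to_csv(path, index=False)
    return out
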