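"""Distance-adjusted Shannon entropy of multitype marker patterns.

H_SC = −Σ_i (d_int_i / d_ext_i) · p_i · log2 p_i, where d_int_i is the mean
pairwise distance within type i, d_ext_i the mean distance from type-i
points to all points of other types, and p_i the share of type i.  Mixing
types (small d_ext) raises the entropy; segregating them lowers it; with
d_int = d_ext it reduces to the ordinary Shannon entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from .grid import SubregionGrid, MM
from .geometry import PointPattern

__all__ = ["EntropyRecord", "hsc", "entropy_by_region"]


@dataclass
class EntropyRecord:
    """H_SC of one multitype pattern plus its per-type ingredients."""

    h_sc: float
    p: dict[str, float]
    d_int: dict[str, float]
    d_ext: dict[str, float]
    n_points: dict[str, int]
    subregion_id: int | None = None
    region: str = ""


def hsc(patterns: list[PointPattern]) -> EntropyRecord:
    """Distance-weighted Shannon entropy of co-registered marker patterns.

    Types with no points are ignored; with a single type present the
    entropy is 0 (p log p vanishes); a singleton type contributes d_int = 0
    and therefore a vanishing term.
    """
    groups = {p.marker: p.points for p in patterns if p.n > 0}
    total = sum(len(v) for v in groups.values())
    if total < 1:
        raise ValueError("need at least one point")
    p_i: dict[str, float] = {}
    d_int: dict[str, float] = {}
    d_ext: dict[str, float] = {}
    n_points = {k: len(v) for k, v in groups.items()}
    h = 0.0
    for marker, pts in groups.items():
        p = len(pts) / total
        p_i[marker] = p
        di = float(np.mean(pdist(pts))) if len(pts) > 1 else 0.0
        d_int[marker] = di
        others = [v for k, v in groups.items() if k != marker]
        if others:
            other = np.vstack(others)
            de = float(np.mean(cdist(pts, other)))
        else:
            de = np.nan  # single type: term vanishes via p log p anyway
        d_ext[marker] = de
        if len(groups) > 1 and p < 1.0 and de > 0:
            h += -(di / de) * p * np.log2(p)
    return EntropyRecord(h, p_i, d_int, d_ext, n_points)


def entropy_by_region(grid: SubregionGrid, patterns: list[PointPattern]) -> pd.DataFrame:
    """H_SC per moving-window subregion, grouped by tissue type.

    Empty subregions are skipped.  Returns a DataFrame with one row per
    non-empty subregion: subregion_id, region, h_sc and per-marker counts.
    """
    w = grid.window_mm * MM
    markers = [p.marker for p in patterns]
    rows = []
    for rec in grid.table.itertuples():
        x0, y0 = rec.x0_um, rec.y0_um
        local = []
        for p in patterns:
            if p.n == 0:
                continue
            m = (
                (p.points[:, 0] >= x0)
                & (p.points[:, 0] < x0 + w)
                & (p.points[:, 1] >= y0)
                & (p.points[:, 1] < y0 + w)
            )
            if m.any():
                local.append(PointPattern(p.marker, p.points[m], p.window, p.slide_id))
        if not local:
            continue
        er = hsc(local)
        row = {"subregion_id": rec.id, "region": rec.region, "h_sc": er.h_sc}
        for mk in markers:
            row[f"n_{mk}"] = er.n_points.get(mk, 0)
        rows.append(row)
    return pd.DataFrame(rows)
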