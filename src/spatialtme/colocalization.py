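"""Degree-of-colocalization (DoC) scoring and correlation hotspots.

For every point of channel A, cumulative density gradients of both channels
are computed on growing circles (radii up to R_max); their Spearman rank
correlation ρ_AB is damped by the nearest cross-channel distance,

    DoC_A = ρ_AB · exp(−N_AB / R_max),

bounded in [−1, 1] (1: colocalized, −1: segregated).  The classification
threshold is calibrated by pairing a clustered pattern with a copy of
itself shifted a small registration-scale distance; correlated points of
both channels are then clustered (HDBSCAN, same parameters as the
morphometric module) into positive hotspots, and correlated-A with
non-correlated-B points into A-dominant (negative) hotspots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import rankdata
from shapely.geometry import MultiPolygon, Polygon
from sklearn.cluster import HDBSCAN

from .geometry import PointPattern, UM2_PER_MM2
from .morphometrics import grow_alpha_shape
from .pointprocess import qcod
from .regions import RegionPartition, assign_region

__all__ = [
    "DoCConfig",
    "DoCScores",
    "Hotspot",
    "doc_scores",
    "calibrate_threshold",
    "positive_hotspots",
    "negative_hotspots",
    "correlation_summary",
    "CALIBRATION_SHIFT_UM",
]

#: calibration shift: 10 μm inflated by the registration accuracy 0.976
CALIBRATION_SHIFT_UM = 10.0 / 0.976


@dataclass
class DoCConfig:
    """Search radii for the density gradients and the score threshold."""

    r_max_um: float = 100.0
    radii_um: np.ndarray | None = None
    threshold: float = 0.84

    def __post_init__(self) -> None:
        if self.radii_um is None:
            self.radii_um = np.arange(10.0, self.r_max_um + 1e-9, 10.0)
        self.radii_um = np.asarray(self.radii_um, float)
        if np.any(self.radii_um <= 0) or np.any(self.radii_um > self.r_max_um):
            raise ValueError("radii must lie in (0, r_max]")
        if not np.all(np.diff(self.radii_um) > 0):
            raise ValueError("radii must be strictly increasing")
        if not (-1.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (-1, 1)")


@dataclass
class DoCScores:
    """Per-point DoC results for one channel."""

    marker: str
    points: np.ndarray
    rho: np.ndarray
    nn_cross_um: np.ndarray
    doc: np.ndarray
    undefined: np.ndarray  # zero-variance gradient flag (DoC forced to 0)

    def correlated(self, threshold: float) -> np.ndarray:
        return self.doc > threshold


def _channel_doc(
    pts: np.ndarray, tree_same: cKDTree, tree_other: cKDTree, cfg: DoCConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    radii = cfg.radii_um
    counts_same = np.empty((len(pts), radii.size))
    counts_other = np.empty((len(pts), radii.size))
    for k, r in enumerate(radii):
        counts_same[:, k] = tree_same.query_ball_point(pts, r, return_length=True)
        counts_other[:, k] = tree_other.query_ball_point(pts, r, return_length=True)
    counts_same -= 1  # the subject point itself is not its own neighbour
    # Spearman operates on the cumulative neighbour-count vectors N(<=r_k);
    # ranks across radii are invariant to any per-point normalisation, and
    # the monotone cumulative form is what makes a shifted identical pair
    # score rho ~ 1 (dividing by the circle area instead makes the vectors
    # unimodal and destroys the rank agreement).
    ra = rankdata(counts_same, axis=1)
    rb = rankdata(counts_other, axis=1)
    ra_c = ra - ra.mean(axis=1, keepdims=True)
    rb_c = rb - rb.mean(axis=1, keepdims=True)
    va = (ra_c**2).sum(axis=1)
    vb = (rb_c**2).sum(axis=1)
    undefined = (va <= 0) | (vb <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (ra_c * rb_c).sum(axis=1) / np.sqrt(va * vb)
    rho[undefined] = 0.0
    nn, _ = tree_other.query(pts)
    doc = rho * np.exp(-nn / cfg.r_max_um)
    doc[undefined] = 0.0
    return rho, nn, doc, undefined


def doc_scores(
    a: PointPattern, b: PointPattern, cfg: DoCConfig | None = None
) -> tuple[DoCScores, DoCScores]:
    """Per-point DoC scores for both channels of a marker pair.

    Density gradients are cumulative counts within each radius divided by
    the circle area (the subject point excluded from its own channel);
    points whose gradient vector has zero variance in either channel get
    DoC = 0 with the ``undefined`` flag set.
    """
    cfg = cfg or DoCConfig()
    if a.n == 0 or b.n == 0:
        raise ValueError("both channels must contain points")
    tree_a, tree_b = cKDTree(a.points), cKDTree(b.points)
    rho_a, nn_a, doc_a, und_a = _channel_doc(a.points, tree_a, tree_b, cfg)
    rho_b, nn_b, doc_b, und_b = _channel_doc(b.points, tree_b, tree_a, cfg)
    return (
        DoCScores(a.marker, a.points, rho_a, nn_a, doc_a, und_a),
        DoCScores(b.marker, b.points, rho_b, nn_b, doc_b, und_b),
    )


def calibrate_threshold(
    pattern: PointPattern,
    shift_um: float = CALIBRATION_SHIFT_UM,
    cfg: DoCConfig | None = None,
) -> float:
    """Calibrate the DoC cut-off from a synthetic well-localized pair.

    The pattern is paired with a copy of itself shifted left (−x) by
    *shift_um* — emulating a perfectly colocalized pair blurred only by
    registration error — and the mean DoC over the unshifted channel is
    returned as the threshold.  Meaningful only for clustered patterns.
    """
    if pattern.n == 0:
        raise ValueError("cannot calibrate on an empty pattern")
    from .synthetic import sim_shifted_pair

    a, b = sim_shifted_pair(pattern, -shift_um, 0.0)
    da, _ = doc_scores(a, b, cfg)
    return float(da.doc.mean())


@dataclass
class Hotspot:
    """A density-based cluster of correlated points from a marker pair."""

    hotspot_id: int
    kind: str  # "positive" | "A-dominant" | "B-dominant"
    points_a: np.ndarray
    points_b: np.ndarray
    outline: Polygon
    region: str = ""

    @property
    def n_a(self) -> int:
        return len(self.points_a)

    @property
    def n_b(self) -> int:
        return len(self.points_b)

    @property
    def centroid(self) -> tuple[float, float]:
        pts = np.vstack([self.points_a, self.points_b])
        c = pts.mean(axis=0)
        return float(c[0]), float(c[1])


def _cluster_two_sets(
    pts_a: np.ndarray,
    pts_b: np.ndarray,
    kind: str,
    min_pts: int,
    k: int,
) -> list[Hotspot]:
    union = np.vstack([pts_a, pts_b]) if len(pts_a) and len(pts_b) else None
    if union is None or len(union) < min_pts:
        return []
    channel = np.r_[np.zeros(len(pts_a), bool), np.ones(len(pts_b), bool)]
    labels = HDBSCAN(min_cluster_size=min_pts, min_samples=k, copy=True).fit_predict(union)
    hotspots = []
    hid = 0
    for cid in np.unique(labels[labels >= 0]):
        mask = labels == cid
        in_a = union[mask & ~channel]
        in_b = union[mask & channel]
        if len(in_a) == 0 or len(in_b) == 0:
            continue  # hotspots must contain both kinds of points
        outline, _, _ = grow_alpha_shape(union[mask])
        hotspots.append(Hotspot(hid, kind, in_a, in_b, outline))
        hid += 1
    return hotspots


def positive_hotspots(
    doc_a: DoCScores,
    doc_b: DoCScores,
    threshold: float,
    min_pts: int = 30,
    k: int = 4,
) -> list[Hotspot]:
    """Clusters of correlated (DoC > threshold) points holding both channels."""
    sel_a = doc_a.points[doc_a.correlated(threshold)]
    sel_b = doc_b.points[doc_b.correlated(threshold)]
    return _cluster_two_sets(sel_a, sel_b, "positive", min_pts, k)


def negative_hotspots(
    doc_a: DoCScores,
    doc_b: DoCScores,
    threshold: float,
    min_pts: int = 30,
    k: int = 4,
) -> tuple[list[Hotspot], list[Hotspot]]:
    """A-dominant and B-dominant negative-correlation hotspots.

    A-dominant clusters pair correlated A points with *non*-correlated B
    points (B cells surrounded by A cells); B-dominant is symmetric.
    """
    a_corr = doc_a.points[doc_a.correlated(threshold)]
    a_non = doc_a.points[~doc_a.correlated(threshold)]
    b_corr = doc_b.points[doc_b.correlated(threshold)]
    b_non = doc_b.points[~doc_b.correlated(threshold)]
    a_dom = _cluster_two_sets(a_corr, b_non, "A-dominant", min_pts, k)
    b_dom = _cluster_two_sets(a_non, b_corr, "B-dominant", min_pts, k)
    return a_dom, b_dom


def correlation_summary(
    hotspots: list[Hotspot],
    doc_a: DoCScores,
    doc_b: DoCScores,
    partition: RegionPartition | None = None,
) -> pd.DataFrame:
    """Per-channel hotspot summary (correlated-cell counts, %, densities).

    ``correlated cells`` are the channel's points lying inside any hotspot
    outline; hotspot density is hotspots per mm² of each region (hotspots
    assigned by centroid).  One row per channel; QCoD of the DoC scores is
    included as a dispersion measure.
    """
    import shapely

    outlines = MultiPolygon([h.outline for h in hotspots if h.outline.area > 0])
    rows = []
    if partition is not None and hotspots:
        centroids = np.array([h.centroid for h in hotspots])
        regs = assign_region(
            PointPattern("_h", centroids, partition.foreground.envelope), partition
        )
        for h, r in zip(hotspots, regs):
            h.region = str(r)
        areas = partition.areas_mm2()
    else:
        areas = {}
    for ch in (doc_a, doc_b):
        if len(outlines.geoms) and ch.points.size:
            inside = shapely.contains_xy(outlines, ch.points[:, 0], ch.points[:, 1]) | (
                shapely.intersects_xy(outlines.boundary, ch.points[:, 0], ch.points[:, 1])
            )
            n_corr = int(inside.sum())
        else:
            n_corr = 0
        row = {
            "marker": ch.marker,
            "correlated_cells": n_corr,
            "percentage": 100.0 * n_corr / len(ch.points) if len(ch.points) else 0.0,
            "qcod_doc": _safe_qcod(ch.doc),
        }
        for name in ("N", "IF", "CT"):
            n_h = sum(1 for h in hotspots if h.region == name)
            area = areas.get(name, 0.0)
            row[f"hotspot_density_{name}_mm2"] = n_h / area if area > 0 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def _safe_qcod(values: np.ndarray) -> float:
    try:
        return qcod(values)
    except ValueError:
        return np.nan
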