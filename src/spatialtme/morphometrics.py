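"""Cell-cluster detection and shape morphometrics.

Clusters are found on the full slide pattern with hierarchical
density-based clustering (HDBSCAN: K-th-neighbour core distances,
mutual-reachability hierarchy, stability extraction; minPts = 30, K = 4).
Each cluster's outline is the smallest connected α-shape containing all
members (α grown geometrically from 10 μm); shape is scored by

* convexity  f_convex = A_α / A_convex,
* circularity f_circ = 4πA_α / P_α²,
* eccentricity e = √(1 − λ2/λ1) of the member-coordinate covariance,

and classified nodular (convexity > 0.8, circularity > 0.5, e < 0.8) or
elongated (convexity < 0.3 or circularity < 0.3 or e > 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import MultiPoint, MultiPolygon, Polygon
from shapely.ops import unary_union
from sklearn.cluster import HDBSCAN

from .geometry import PointPattern, UM2_PER_MM2, as_multipolygon
from .pointprocess import CHI2_2DF_95
from .regions import RegionPartition, assign_region

__all__ = [
    "ClusterShape",
    "detect_clusters",
    "grow_alpha_shape",
    "alpha_complex",
    "convexity",
    "circularity",
    "covariance_ellipse",
    "eccentricity",
    "classify_cluster",
    "cluster_region_stats",
]

NODULAR_RULE = dict(convexity=0.8, circularity=0.5, eccentricity=0.8)
ELONGATED_RULE = dict(convexity=0.3, circularity=0.3, eccentricity=0.9)


@dataclass
class ClusterShape:
    """One detected cell cluster with outline and morphometrics."""

    cluster_id: int
    points: np.ndarray
    alpha_shape: Polygon
    alpha_um: float
    convex_hull: Polygon
    f_convex: float
    f_circularity: float
    eigvals: tuple[float, float]  # λ1 >= λ2
    semi_axes: tuple[float, float]  # a >= b, μm
    ecc: float
    shape_class: str
    degenerate: bool = False
    region: str = ""

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.points.mean(axis=0)
        return float(c[0]), float(c[1])

    @property
    def area_mm2(self) -> float:
        return self.alpha_shape.area / UM2_PER_MM2

    @property
    def member_density_mm2(self) -> float:
        """Cells per mm² inside the cluster's α-shape."""
        a = self.area_mm2
        return len(self.points) / a if a > 0 else np.nan


def alpha_complex(points: np.ndarray, alpha: float) -> MultiPolygon:
    """α-complex of a point set: union of Delaunay triangles whose
    circumradius is at most α (α the disk radius, μm)."""
    pts = np.asarray(points, float)
    tri = Delaunay(pts)
    keep = []
    for simplex in tri.simplices:
        a, b, c = pts[simplex]
        la, lb, lc = (
            np.linalg.norm(b - c),
            np.linalg.norm(a - c),
            np.linalg.norm(a - b),
        )
        area2 = abs((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))
        if area2 <= 0:
            continue
        circum = la * lb * lc / (2.0 * area2)
        if circum <= alpha:
            keep.append(Polygon(pts[simplex]))
    if not keep:
        return MultiPolygon([])
    return as_multipolygon(unary_union(keep))


def grow_alpha_shape(
    points: np.ndarray, alpha0: float = 10.0, growth: float = 1.1
) -> tuple[Polygon, float, bool]:
    """Grow α from *alpha0* until the α-shape is one polygon holding all points.

    Returns (polygon, final α, degenerate flag).  Collinear inputs (or
    n < 3) cannot support a 2-D outline and come back as a zero-area
    degenerate hull.  α is capped at the convex hull.
    """
    pts = np.asarray(points, float)
    hull = MultiPoint(pts).convex_hull
    if not isinstance(hull, Polygon) or hull.area <= 0:
        return hull if isinstance(hull, Polygon) else Polygon(), np.inf, True
    # cap: the largest circumradius is bounded by the hull diameter
    x0, y0, x1, y1 = hull.bounds
    alpha_cap = 2.0 * float(np.hypot(x1 - x0, y1 - y0))
    alpha = float(alpha0)
    while alpha <= alpha_cap:
        mp = alpha_complex(pts, alpha)
        if len(mp.geoms) == 1:
            poly = mp.geoms[0]
            if shapely.contains_xy(poly.buffer(1e-6), pts[:, 0], pts[:, 1]).all():
                return poly, alpha, False
        alpha *= growth
    return hull, alpha_cap, False


def detect_clusters(
    pattern: PointPattern,
    min_pts: int = 30,
    k: int = 4,
    partition: RegionPartition | None = None,
) -> tuple[list[ClusterShape], np.ndarray]:
    """HDBSCAN clusters of the full pattern plus per-point labels.

    ``min_pts`` is the minimum cluster size, ``k`` the core-neighbourhood
    size; points in no stable cluster are labelled −1 (noise).  Each
    cluster is outlined and scored; region labels come from the cluster
    centroid when a partition is supplied.
    """
    if pattern.n < min_pts:
        return [], np.full(pattern.n, -1)
    clusterer = HDBSCAN(min_cluster_size=min_pts, min_samples=k, copy=True)
    labels = clusterer.fit_predict(pattern.points)
    shapes: list[ClusterShape] = []
    for cid in np.unique(labels[labels >= 0]):
        members = pattern.points[labels == cid]
        shapes.append(_score_cluster(int(cid), members))
    if partition is not None and shapes:
        centroids = np.array([s.centroid for s in shapes])
        regs = assign_region(
            PointPattern("_centroids", centroids, pattern.window), partition
        )
        for s, r in zip(shapes, regs):
            s.region = str(r)
    return shapes, labels


def _score_cluster(cid: int, members: np.ndarray) -> ClusterShape:
    poly, alpha, degenerate = grow_alpha_shape(members)
    hull = MultiPoint(members).convex_hull
    hull = hull if isinstance(hull, Polygon) else Polygon()
    if degenerate or hull.area <= 0 or poly.area <= 0:
        lam1, lam2 = _cov_eigvals(members)
        ecc_val = eccentricity(lam1, lam2) if lam1 > 0 else np.nan
        return ClusterShape(
            cid, members, poly, alpha, hull, np.nan, np.nan,
            (lam1, lam2), (np.nan, np.nan), ecc_val, "other", degenerate=True,
        )
    f_cvx = convexity(poly, hull)
    f_circ = circularity(poly)
    lam1, lam2, _, a, b = covariance_ellipse(members)
    e = eccentricity(lam1, lam2)
    cls = classify_cluster(f_cvx, f_circ, e)
    return ClusterShape(
        cid, members, poly, alpha, hull, f_cvx, f_circ, (lam1, lam2), (a, b), e, cls
    )


def convexity(alpha_shape: Polygon, convex_hull: Polygon) -> float:
    """A_α / A_convex."""
    if convex_hull.area <= 0:
        raise ValueError("degenerate convex hull (zero area)")
    return float(alpha_shape.area / convex_hull.area)


def circularity(alpha_shape: Polygon) -> float:
    """4πA_α / P_α² (1 for a disk, π/4 for a square outline)."""
    if alpha_shape.length <= 0:
        raise ValueError("degenerate shape (zero perimeter)")
    return float(4.0 * np.pi * alpha_shape.area / alpha_shape.length**2)


def _cov_eigvals(points: np.ndarray) -> tuple[float, float]:
    pts = np.asarray(points, float)
    if len(pts) < 2:
        return 0.0, 0.0
    lam = np.linalg.eigvalsh(np.cov(pts.T))  # ascending
    return float(lam[1]), float(lam[0])


def covariance_ellipse(points: np.ndarray):
    """95 % covariance ellipse of member coordinates.

    Eigendecomposition of the sample (n−1) covariance; semi-axes are
    a = √(λ1·χ²₂(0.95)), b = √(λ2·χ²₂(0.95)) with χ²₂(0.95) = 5.991.
    Returns (λ1, λ2, orientation_rad, a, b).
    """
    pts = np.asarray(points, float)
    if len(pts) < 2:
        raise ValueError("covariance ellipse needs at least 2 points")
    c = np.cov(pts.T)
    lam, vec = np.linalg.eigh(c)
    lam1, lam2 = float(lam[1]), float(lam[0])
    if lam1 <= 0:
        raise ValueError("coincident points: zero covariance")
    ori = float(np.arctan2(vec[1, 1], vec[0, 1]))
    a = float(np.sqrt(lam1 * CHI2_2DF_95))
    b = float(np.sqrt(max(lam2, 0.0) * CHI2_2DF_95))
    return lam1, lam2, ori, a, b


def eccentricity(lam1: float, lam2: float) -> float:
    """e = √(1 − λ2/λ1); 0 for isotropic spread, 1 for collinear points."""
    if lam1 <= 0:
        raise ValueError("lambda1 must be positive")
    return float(np.sqrt(1.0 - max(lam2, 0.0) / lam1))


def classify_cluster(f_convex: float, f_circularity: float, ecc: float) -> str:
    """Nodular / elongated / other classification.

    Nodular requires all of convexity > 0.8, circularity > 0.5 and
    eccentricity < 0.8; elongated fires on any of convexity < 0.3,
    circularity < 0.3 or eccentricity > 0.9 (and takes precedence, though
    the thresholds make dual membership impossible).
    """
    elongated = (
        f_convex < ELONGATED_RULE["convexity"]
        or f_circularity < ELONGATED_RULE["circularity"]
        or ecc > ELONGATED_RULE["eccentricity"]
    )
    nodular = (
        f_convex > NODULAR_RULE["convexity"]
        and f_circularity > NODULAR_RULE["circularity"]
        and ecc < NODULAR_RULE["eccentricity"]
    )
    assert not (elongated and nodular), "classification rules cannot overlap"
    if elongated:
        return "elongated"
    if nodular:
        return "nodular"
    return "other"


def cluster_region_stats(
    clusters: list[ClusterShape], partition: RegionPartition
) -> pd.DataFrame:
    """Per-region cluster metrics (assignment by cluster centroid).

    Columns: region, n_clusters, clusters_per_mm2, nodular_per_mm2,
    elongated_per_mm2, mean_member_density_mm2.
    """
    areas = partition.areas_mm2()
    if clusters and not any(c.region for c in clusters):
        centroids = np.array([c.centroid for c in clusters])
        regs = assign_region(
            PointPattern("_c", centroids, partition.foreground.envelope), partition
        )
        for c, r in zip(clusters, regs):
            c.region = str(r)
    rows = []
    for name in ("N", "IF", "CT"):
        area = areas.get(name, 0.0)
        sub = [c for c in clusters if c.region == name]
        nod = sum(1 for c in sub if c.shape_class == "nodular")
        elo = sum(1 for c in sub if c.shape_class == "elongated")
        dens = [c.member_density_mm2 for c in sub if np.isfinite(c.member_density_mm2)]
        rows.append(
            {
                "region": name,
                "n_clusters": len(sub),
                "clusters_per_mm2": len(sub) / area if area > 0 else 0.0,
                "nodular_per_mm2": nod / area if area > 0 else 0.0,
                "elongated_per_mm2": elo / area if area > 0 else 0.0,
                "mean_member_density_mm2": float(np.mean(dens)) if dens else 0.0,
            }
        )
    return pd.DataFrame(rows)
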