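"""Seeded generators for every input the pipeline consumes.

These emulate the study conditions at desk scale: homogeneous Poisson and
Thomas-clustered patterns, multitype marker panels, shifted pattern pairs
for DoC calibration, co-clustered marker pairs for hotspot checks, and a
tumor *phantom* — a perturbed circular tumor with five jittered boundary
annotations (standing in for five consecutive sections) and five marker
patterns whose density is elevated at the invasive front.  All generators
are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Polygon, box

from .geometry import PointPattern, UM2_PER_MM2
from .regions import RegionPartition, partition_regions

__all__ = [
    "PhantomSpec",
    "sim_poisson",
    "sim_thomas",
    "sim_multitype",
    "sim_shifted_pair",
    "sim_colocalized_pair",
    "sim_tumor_phantom",
]

MM = 1000.0

DEFAULT_MARKERS = ("CD3", "CD4", "CD8", "CD20", "FoxP3")
#: per-region intensities in mm⁻²: IF = 3x CT = 6x N
DEFAULT_INTENSITIES = {"N": 50.0, "CT": 100.0, "IF": 300.0}


def _uniform_in_polygon(rng: np.random.Generator, geom, n: int) -> np.ndarray:
    """Rejection-sample n uniform points inside a polygonal geometry."""
    if n == 0:
        return np.empty((0, 2))
    x0, y0, x1, y1 = geom.bounds
    frac = max(geom.area / ((x1 - x0) * (y1 - y0)), 1e-3)
    out: list[np.ndarray] = []
    need = n
    while need > 0:
        m = int(np.ceil(need / frac * 1.2)) + 16
        cand = np.column_stack(
            [rng.uniform(x0, x1, m), rng.uniform(y0, y1, m)]
        )
        inside = shapely.contains_xy(geom, cand[:, 0], cand[:, 1])
        hit = cand[inside][:need]
        out.append(hit)
        need -= len(hit)
    return np.vstack(out)


def sim_poisson(
    intensity_mm2: float,
    window: Polygon,
    seed: int | None = None,
    marker: str = "sim",
) -> PointPattern:
    """Homogeneous Poisson pattern: count ~ Poisson(λ·|W|), uniform positions."""
    if intensity_mm2 < 0:
        raise ValueError("intensity must be nonnegative")
    rng = np.random.default_rng(seed)
    area_mm2 = window.area / UM2_PER_MM2
    n = int(rng.poisson(intensity_mm2 * area_mm2))
    pts = _uniform_in_polygon(rng, window, n)
    return PointPattern(marker, pts, window)


def sim_thomas(
    kappa_mm2: float,
    mu: float,
    sigma_um: float,
    window: Polygon,
    seed: int | None = None,
    marker: str = "sim",
    keep_parents: bool = False,
):
    """Thomas cluster pattern: Poisson parents, Poisson(μ) Gaussian offspring.

    Parents are drawn on the window bounding box expanded by 4σ so clusters
    straddling the edge are not under-represented; offspring displacements
    are isotropic Gaussian with SD σ and only offspring inside the window
    are kept.  With ``keep_parents`` the parent coordinates and each kept
    offspring's parent index are returned alongside the pattern.
    """
    if kappa_mm2 <= 0 or mu <= 0 or sigma_um <= 0:
        raise ValueError("kappa, mu and sigma must all be positive")
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = window.bounds
    pad = 4.0 * sigma_um
    ext_area_mm2 = ((x1 - x0 + 2 * pad) * (y1 - y0 + 2 * pad)) / UM2_PER_MM2
    n_par = int(rng.poisson(kappa_mm2 * ext_area_mm2))
    parents = np.column_stack(
        [rng.uniform(x0 - pad, x1 + pad, n_par), rng.uniform(y0 - pad, y1 + pad, n_par)]
    )
    offspring = []
    parent_idx = []
    for i in range(n_par):
        m = int(rng.poisson(mu))
        if m == 0:
            continue
        pts = parents[i] + rng.normal(0.0, sigma_um, size=(m, 2))
        offspring.append(pts)
        parent_idx.append(np.full(m, i))
    if offspring:
        pts = np.vstack(offspring)
        pidx = np.concatenate(parent_idx)
        inside = shapely.contains_xy(window, pts[:, 0], pts[:, 1])
        pts, pidx = pts[inside], pidx[inside]
    else:
        pts, pidx = np.empty((0, 2)), np.empty(0, int)
    pattern = PointPattern(marker, pts, window)
    if keep_parents:
        return pattern, parents, pidx
    return pattern


def sim_multitype(
    specs: dict[str, dict],
    window: Polygon,
    seed: int | None = None,
) -> list[PointPattern]:
    """Independent per-marker generators on a shared window.

    Each spec is ``{"kind": "poisson", "intensity_mm2": ...}`` or
    ``{"kind": "thomas", "kappa_mm2": ..., "mu": ..., "sigma_um": ...}``.
    """
    seeds = np.random.SeedSequence(seed).spawn(len(specs))
    patterns = []
    for (marker, spec), ss in zip(specs.items(), seeds):
        sub = int(ss.generate_state(1)[0] % (2**31 - 1))
        kind = spec.get("kind", "poisson")
        if kind == "poisson":
            patterns.append(
                sim_poisson(spec["intensity_mm2"], window, sub, marker=marker)
            )
        elif kind == "thomas":
            patterns.append(
                sim_thomas(
                    spec["kappa_mm2"], spec["mu"], spec["sigma_um"], window, sub, marker=marker
                )
            )
        else:
            raise ValueError(f"unknown generator kind {kind!r}")
    return patterns


def sim_shifted_pair(
    pattern: PointPattern, dx_um: float, dy_um: float
) -> tuple[PointPattern, PointPattern]:
    """Pair a pattern with a rigidly translated copy (shared window)."""
    shifted = PointPattern(
        pattern.marker + "_shifted",
        pattern.points + np.array([dx_um, dy_um]),
        pattern.window,
        pattern.slide_id,
    )
    return pattern, shifted


def sim_colocalized_pair(
    kappa_mm2: float,
    mu: float,
    sigma_um: float,
    parent_region: Polygon | MultiPolygon,
    window: Polygon,
    seed: int | None = None,
    background_mm2: float = 0.0,
    markers: tuple[str, str] = ("A", "B"),
) -> tuple[PointPattern, PointPattern, np.ndarray]:
    """Two channels sharing Thomas parents confined to *parent_region*.

    Both channels draw their own Poisson(μ) offspring around the same
    parents, so their clusters colocalize by construction; optional CSR
    background is added to each channel across the whole window.  Returns
    (A, B, parents).
    """
    rng = np.random.default_rng(seed)
    area_mm2 = parent_region.area / UM2_PER_MM2
    n_par = max(1, int(rng.poisson(kappa_mm2 * area_mm2)))
    parents = _uniform_in_polygon(rng, parent_region, n_par)
    channels = []
    for marker in markers:
        offspring = []
        for p in parents:
            m = int(rng.poisson(mu))
            if m:
                offspring.append(p + rng.normal(0.0, sigma_um, size=(m, 2)))
        pts = np.vstack(offspring) if offspring else np.empty((0, 2))
        if background_mm2 > 0:
            bg = sim_poisson(
                background_mm2, window, int(rng.integers(2**31 - 1))
            ).points
            pts = np.vstack([pts, bg])
        inside = shapely.contains_xy(window, pts[:, 0], pts[:, 1]) if len(pts) else np.empty(0, bool)
        channels.append(PointPattern(marker, pts[inside], window))
    return channels[0], channels[1], parents


@dataclass
class PhantomSpec:
    """Geometry and intensities of the synthetic tumor phantom."""

    center_um: tuple[float, float] = (4000.0, 4000.0)
    radius_um: float = 2500.0
    lobe_amplitude_um: float = 200.0  # smooth harmonic boundary perturbation
    jitter_um: float = 50.0  # per-annotation-copy boundary jitter
    n_annotations: int = 5
    foreground_um: tuple[float, float] = (8000.0, 8000.0)
    if_width_mm: float = 1.0
    markers: tuple[str, ...] = DEFAULT_MARKERS
    intensities_mm2: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    seed: int = 0


def _perturbed_circle(
    center, radius, amplitudes, phases, harmonics, n_vertices=256
) -> Polygon:
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = np.full_like(theta, float(radius))
    for a, ph, h in zip(amplitudes, phases, harmonics):
        r = r + a * np.sin(h * theta + ph)
    xy = np.column_stack(
        [center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)]
    )
    return Polygon(xy)


def sim_tumor_phantom(
    spec: PhantomSpec | None = None,
) -> tuple[list[Polygon], list[PointPattern], RegionPartition]:
    """Synthetic tumor with boundary annotations and marker patterns.

    Returns five (by default) jittered copies of the true boundary —
    emulating pathologist annotations on consecutive sections — one marker
    pattern per panel member with region-specific Poisson intensities
    (default IF : CT : N = 6 : 2 : 1), and the ground-truth partition for
    recovery checks.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    harmonics = (3, 5)
    base_amp = (spec.lobe_amplitude_um, spec.lobe_amplitude_um / 2.0)
    base_phase = tuple(rng.uniform(0, 2 * np.pi, len(harmonics)))
    truth_boundary = _perturbed_circle(
        spec.center_um, spec.radius_um, base_amp, base_phase, harmonics
    )
    foreground = box(0.0, 0.0, spec.foreground_um[0], spec.foreground_um[1])
    truth = partition_regions(truth_boundary, foreground, spec.if_width_mm)

    annotations = []
    for _ in range(spec.n_annotations):
        if spec.jitter_um > 0:
            jit_h = (2, 4, 7)
            amps = tuple(rng.uniform(0, spec.jitter_um, len(jit_h)))
            phases = tuple(rng.uniform(0, 2 * np.pi, len(jit_h)))
            radius = spec.radius_um + rng.normal(0, spec.jitter_um / 2.0)
            ann = _perturbed_circle(
                spec.center_um, radius, base_amp + amps, base_phase + phases,
                harmonics + jit_h,
            )
        else:
            ann = Polygon(truth_boundary.exterior.coords)
        annotations.append(ann)

    patterns = []
    for marker in spec.markers:
        parts = []
        for region_name in ("N", "IF", "CT"):
            lam = spec.intensities_mm2.get(region_name, 0.0)
            geom = truth.region(region_name)
            if lam <= 0 or geom.is_empty:
                continue
            n = int(rng.poisson(lam * geom.area / UM2_PER_MM2))
            parts.append(_uniform_in_polygon(rng, geom, n))
        pts = np.vstack(parts) if parts else np.empty((0, 2))
        patterns.append(PointPattern(marker, pts, foreground, slide_id="phantom"))
    return annotations, patterns, truth
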