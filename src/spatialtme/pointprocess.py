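"""Second-order point-pattern statistics and Thomas cluster-process fitting.

The workflow per subregion is: test complete spatial randomness with the
one-tailed Clark-Evans test (alternative: clustered); if CSR is rejected,
fit a Thomas process by minimum contrast against its closed-form Ripley K,

    K(r) = πr² + (1/κ)·(1 − exp(−r²/4σ²)),

and summarise the cluster geometry through the Rayleigh distribution of
offspring distances: mean distance σ√(π/2), and the radius containing F %
of offspring, Q(F, σ) = σ√(−2 ln(1 − F/100)).  μ is identified as λ̂/κ̂
because K is free of μ.  Dispersion across subregions is summarised by the
quartile coefficient of dispersion and the coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import optimize, stats
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .geometry import PointPattern, UM2_PER_MM2

__all__ = [
    "CSRResult",
    "clark_evans",
    "ripley_k",
    "ThomasModel",
    "ThomasResults",
    "fit_thomas",
    "rayleigh_summaries",
    "qcod",
    "cov",
    "gof_envelope",
    "region_dispersion_table",
]

CHI2_2DF_95 = 5.991  # chi-square(2 df) 0.95 quantile, covariance-ellipse scale


# ---------------------------------------------------------------------------
# Clark-Evans CSR test
# ---------------------------------------------------------------------------

@dataclass
class CSRResult:
    clark_evans_R: float
    p_value: float
    verdict: str  # "clustered" | "not-clustered"
    n_points: int
    z: float
    insufficient: bool = False  # n below the recommended minimum


def clark_evans(
    pattern: PointPattern, alpha: float = 0.05, min_n: int = 10
) -> CSRResult:
    """One-tailed Clark-Evans test of CSR against clustering.

    The aggregation index R is the ratio of the observed mean
    nearest-neighbour distance to its CSR expectation 0.5/√λ̂; the test uses
    the Donnelly edge-corrected expectation and variance and a normal
    approximation, rejecting for small R (clustered alternative).
    Patterns with fewer than *min_n* points are flagged ``insufficient``.
    """
    n = pattern.n
    if n < 2:
        raise ValueError("Clark-Evans test needs at least 2 points")
    tree = cKDTree(pattern.points)
    d, _ = tree.query(pattern.points, k=2)
    dbar = float(d[:, 1].mean())
    area = pattern.window.area
    perim = pattern.window.length
    # Donnelly (1978) edge-corrected null moments
    ed = 0.5 * np.sqrt(area / n) + (0.0514 + 0.041 / np.sqrt(n)) * perim / n
    var = 0.070 * area / n**2 + 0.037 * perim * np.sqrt(area / n**5)
    z = (dbar - ed) / np.sqrt(var)
    p = float(stats.norm.cdf(z))  # lower tail: clustered means small distances
    r = dbar / ed
    return CSRResult(
        clark_evans_R=r,
        p_value=p,
        verdict="clustered" if p < alpha else "not-clustered",
        n_points=n,
        z=float(z),
        insufficient=n < min_n,
    )


# ---------------------------------------------------------------------------
# Ripley's K (border correction)
# ---------------------------------------------------------------------------

def _border_distance(pattern: PointPattern) -> np.ndarray:
    pts = shapely.points(pattern.points)
    return shapely.distance(pts, pattern.window.boundary)


def ripley_k(
    pattern: PointPattern, r: np.ndarray, warn_truncate: bool = True
) -> np.ndarray:
    """Border-corrected empirical Ripley K.

    Reference points closer than r to the window edge are discarded at that
    r:  K̂(r) = |W| · Σ_{i: b_i > r} #{j ≠ i : d_ij ≤ r} / (n_valid(r)·(n−1)).
    Entries of r with no valid reference point are NaN.
    """
    n = pattern.n
    if n < 2:
        raise ValueError("Ripley K needs at least 2 points")
    r = np.asarray(r, float)
    x0, y0, x1, y1 = pattern.window.bounds
    half = min(x1 - x0, y1 - y0) / 2.0
    if warn_truncate and np.any(r > half):
        import warnings

        warnings.warn(
            "r exceeds half the window side; estimates there are NaN-prone",
            stacklevel=2,
        )
    b = _border_distance(pattern)
    dmat = squareform(pdist(pattern.points))
    np.fill_diagonal(dmat, np.inf)
    area = pattern.window.area
    out = np.empty_like(r)
    for k, rk in enumerate(r):
        valid = b > rk
        nv = int(valid.sum())
        if nv == 0:
            out[k] = np.nan
            continue
        s = np.sum(dmat[valid] <= rk)
        out[k] = area * s / (nv * (n - 1))
    return out


def thomas_k(r: np.ndarray, kappa: float, sigma: float) -> np.ndarray:
    """Closed-form Ripley K of the Thomas process (κ in μm⁻², σ in μm)."""
    r = np.asarray(r, float)
    return np.pi * r**2 + (1.0 / kappa) * (1.0 - np.exp(-(r**2) / (4.0 * sigma**2)))


# ---------------------------------------------------------------------------
# Thomas process model (statsmodels-style Model / Results pair)
# ---------------------------------------------------------------------------

class ThomasModel:
    """Thomas cluster process fitted to a point pattern by minimum contrast.

    Parameters
    ----------
    pattern : PointPattern
        The observed pattern (μm coordinates).
    r : ndarray, optional
        Contrast grid; defaults to 64 radii on (0, shorter window side / 4].
    q : float
        Contrast exponent; the objective is ∫ (K̂^q − K^q)² dr with the
        conventional q = 1/4.

    Examples
    --------
    >>> res = ThomasModel(pattern).fit()      # doctest: +SKIP
    >>> res.kappa_mm2, res.mu, res.sigma_um   # doctest: +SKIP
    """

    def __init__(self, pattern: PointPattern, r: np.ndarray | None = None, q: float = 0.25):
        if pattern.n < 10:
            raise ValueError("Thomas fitting requires at least 10 points")
        self.pattern = pattern
        x0, y0, x1, y1 = pattern.window.bounds
        rmax = min(x1 - x0, y1 - y0) / 4.0
        self.r = np.asarray(r, float) if r is not None else np.linspace(rmax / 64, rmax, 64)
        self.q = q
        self.k_emp = ripley_k(pattern, self.r, warn_truncate=False)

    def _contrast(self, log_params: np.ndarray) -> float:
        kappa, sigma = np.exp(log_params)
        kth = thomas_k(self.r, kappa, sigma)
        ok = np.isfinite(self.k_emp)
        diff = self.k_emp[ok] ** self.q - kth[ok] ** self.q
        return float(np.trapezoid(diff**2, self.r[ok]))

    def fit(self, start: tuple[float, float] | None = None) -> "ThomasResults":
        """Minimise the K-contrast over (κ, σ); μ follows as λ̂/κ̂.

        A small multi-start grid precedes a Nelder-Mead polish so the fit
        does not depend on a lucky initial guess.
        """
        lam = self.pattern.n / self.pattern.window.area  # μm⁻²
        if start is not None:
            starts = [np.log(np.asarray(start, float))]
        else:
            rmax = self.r[-1]
            starts = [
                np.log([lam / div, frac * rmax])
                for div in (5.0, 20.0, 100.0)
                for frac in (0.02, 0.08, 0.25)
            ]
        best = None
        for s0 in starts:
            res = optimize.minimize(self._contrast, s0, method="Nelder-Mead",
                                    options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000})
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.all(np.isfinite(best.x)):
            raise RuntimeError("Thomas minimum-contrast optimisation failed")
        kappa, sigma = np.exp(best.x)
        mu = lam / kappa
        x0, y0, x1, y1 = self.pattern.window.bounds
        side = min(x1 - x0, y1 - y0)
        unreliable = kappa * self.pattern.window.area < 0.5 or sigma > side / 2
        return ThomasResults(
            model=self,
            kappa_um2=float(kappa),
            mu=float(mu),
            sigma_um=float(sigma),
            contrast=float(best.fun),
            converged=bool(best.success),
            unreliable=bool(unreliable),
        )


@dataclass
class ThomasResults:
    """Fitted Thomas-process parameters and Rayleigh-derived summaries."""

    model: ThomasModel
    kappa_um2: float
    mu: float
    sigma_um: float
    contrast: float
    converged: bool
    unreliable: bool = False

    @property
    def kappa_mm2(self) -> float:
        """Parent (cluster) intensity in clusters/mm²."""
        return self.kappa_um2 * UM2_PER_MM2

    @property
    def mean_dist_um(self) -> float:
        """Mean offspring-to-center distance σ√(π/2)."""
        return rayleigh_summaries(self.sigma_um)[0]

    @property
    def radius95_um(self) -> float:
        """Radius of the circle holding 95 % of a cluster's cells."""
        return rayleigh_summaries(self.sigma_um)[1]

    @property
    def cluster_area_mm2(self) -> float:
        """Area of the 95 % cluster circle, π·Q(95, σ)², in mm²."""
        return np.pi * self.radius95_um**2 / UM2_PER_MM2

    def predicted_k(self, r: np.ndarray | None = None) -> np.ndarray:
        return thomas_k(self.model.r if r is None else r, self.kappa_um2, self.sigma_um)

    def params_dict(self) -> dict[str, float]:
        return {
            "kappa_mm2": self.kappa_mm2,
            "mu": self.mu,
            "sigma_um": self.sigma_um,
            "mean_dist_um": self.mean_dist_um,
            "radius95_um": self.radius95_um,
            "cluster_area_mm2": self.cluster_area_mm2,
        }

    def summary(self) -> str:
        lines = [
            "Thomas cluster process (minimum contrast on Ripley K)",
            f"  n points            : {self.model.pattern.n}",
            f"  window area (mm^2)  : {self.model.pattern.area_mm2:.4f}",
            f"  kappa (clusters/mm2): {self.kappa_mm2:.4f}",
            f"  mu (cells/cluster)  : {self.mu:.4f}",
            f"  sigma (um)          : {self.sigma_um:.4f}",
            f"  mean dist (um)      : {self.mean_dist_um:.4f}",
            f"  95% radius (um)     : {self.radius95_um:.4f}",
            f"  cluster area (mm^2) : {self.cluster_area_mm2:.6f}",
            f"  contrast            : {self.contrast:.6g}",
            f"  converged           : {self.converged}   unreliable: {self.unreliable}",
        ]
        return "\n".join(lines)


def fit_thomas(pattern: PointPattern, r: np.ndarray | None = None) -> ThomasResults:
    """Convenience wrapper: ``ThomasModel(pattern, r).fit()``."""
    return ThomasModel(pattern, r=r).fit()


def rayleigh_summaries(sigma: float, f_percent: float = 95.0) -> tuple[float, float]:
    """Mean offspring distance σ√(π/2) and the F % Rayleigh radius.

    Q(F, σ) = σ√(−2 ln(1 − F/100)); for F = 95 this is ≈ 2.4477 σ.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if not (0.0 < f_percent < 100.0):
        raise ValueError("F must lie strictly between 0 and 100")
    mean_dist = sigma * np.sqrt(np.pi / 2.0)
    radius = sigma * np.sqrt(-2.0 * np.log(1.0 - f_percent / 100.0))
    return float(mean_dist), float(radius)


# ---------------------------------------------------------------------------
# Dispersion statistics
# ---------------------------------------------------------------------------

def qcod(values) -> float:
    """Quartile coefficient of dispersion (Q3 − Q1)/(Q3 + Q1).

    Quartiles use the linear-interpolation rule (numpy default / R type 7).
    """
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("QCoD needs at least 2 values")
    q1, q3 = np.percentile(v, [25, 75])
    if q1 + q3 <= 0:
        raise ValueError("QCoD undefined: Q1 + Q3 is not positive")
    return float((q3 - q1) / (q3 + q1))


def cov(values) -> float:
    """Coefficient of variation sd/mean (sample SD, n − 1 denominator)."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("CoV needs at least 2 values")
    m = v.mean()
    if m == 0:
        raise ValueError("CoV undefined: mean is zero")
    return float(v.std(ddof=1) / m)


# ---------------------------------------------------------------------------
# Monte-Carlo goodness-of-fit envelope
# ---------------------------------------------------------------------------

@dataclass
class GofEnvelope:
    r: np.ndarray
    l_obs: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    p_value: float
    nsim: int


def _l_function(pattern: PointPattern, r: np.ndarray) -> np.ndarray:
    k = ripley_k(pattern, r, warn_truncate=False)
    return np.sqrt(np.maximum(k, 0.0) / np.pi)


def gof_envelope(
    pattern: PointPattern,
    fit: ThomasResults,
    nsim: int = 39,
    seed: int | None = None,
    two_stage: bool = False,
    r: np.ndarray | None = None,
) -> GofEnvelope:
    """Global Monte-Carlo envelope of L(r) = √(K/π) under the fitted model.

    *nsim* patterns are simulated from the fitted Thomas parameters in the
    observed window; the envelope is the pointwise min/max of the simulated
    L curves (a rank-1 global envelope: exact level 2/(nsim+1) two-sided,
    so nsim = 39 gives α = 0.05) and the p-value comes from the rank of the
    observed maximum deviation from the simulation mean.  With
    ``two_stage`` the model is refitted to each simulation before its curve
    is computed (the Dao-Genton adjustment for estimated parameters).
    """
    from .synthetic import sim_thomas  # local import to avoid a cycle

    if nsim < 19:
        raise ValueError("nsim must be at least 19 to resolve alpha = 0.05")
    rng = np.random.default_rng(seed)
    rr = fit.model.r if r is None else np.asarray(r, float)
    l_obs = _l_function(pattern, rr)
    curves = np.empty((nsim, rr.size))
    for i in range(nsim):
        sim = sim_thomas(
            fit.kappa_mm2, fit.mu, fit.sigma_um, pattern.window,
            seed=int(rng.integers(0, 2**31 - 1)), marker=pattern.marker,
        )
        while sim.n < 2:  # degenerate realisation: redraw
            sim = sim_thomas(
                fit.kappa_mm2, fit.mu, fit.sigma_um, pattern.window,
                seed=int(rng.integers(0, 2**31 - 1)), marker=pattern.marker,
            )
        curves[i] = _l_function(sim, rr)
        if two_stage:
            # Dao-Genton flavour: measure each simulated curve against its
            # own refitted expectation, removing estimation bias
            try:
                refit = ThomasModel(sim, r=rr).fit()
                curves[i] -= np.sqrt(np.maximum(refit.predicted_k(rr), 0.0) / np.pi)
            except (ValueError, RuntimeError):
                curves[i] = np.nan
    if two_stage:
        l_obs = l_obs - np.sqrt(np.maximum(fit.predicted_k(rr), 0.0) / np.pi)
    mean_curve = np.nanmean(curves, axis=0)
    def maxdev(c):
        d = np.abs(c - mean_curve)
        return np.nanmax(d)
    t_obs = maxdev(l_obs)
    t_sim = np.array([maxdev(c) for c in curves])
    p = (1.0 + np.sum(t_sim >= t_obs)) / (nsim + 1.0)
    return GofEnvelope(
        r=rr,
        l_obs=l_obs,
        lo=np.nanmin(curves, axis=0),
        hi=np.nanmax(curves, axis=0),
        p_value=float(p),
        nsim=nsim,
    )


# ---------------------------------------------------------------------------
# Region dispersion summary (marker x region table)
# ---------------------------------------------------------------------------

def region_dispersion_table(
    metrics: pd.DataFrame,
    group_cols: tuple[str, str] = ("marker", "region"),
    value_cols: tuple[str, ...] = ("density_mm2", "mu", "mean_dist_um", "cluster_area_mm2"),
    min_group: int = 4,
) -> pd.DataFrame:
    """QCoD (plus median) of per-subregion metrics per marker x region group.

    Groups with fewer than *min_group* subregions are retained but flagged.
    """
    rows = []
    for keys, grp in metrics.groupby(list(group_cols)):
        row = dict(zip(group_cols, keys if isinstance(keys, tuple) else (keys,)))
        row["n_subregions"] = len(grp)
        row["flagged_small"] = len(grp) < min_group
        for col in value_cols:
            vals = grp[col].dropna().to_numpy(float)
            if len(vals) >= 2 and np.percentile(vals, 25) + np.percentile(vals, 75) > 0:
                row[f"qcod_{col}"] = qcod(vals)
            else:
                row[f"qcod_{col}"] = np.nan
            row[f"median_{col}"] = float(np.median(vals)) if len(vals) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
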