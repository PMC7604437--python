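# Methods

This note documents the models, the numerical choices, and the defaults of
`spatialtme`, in the order a full run executes them. All coordinates are
micrometers in an image convention (origin top-left, y downward); public
areas are mm² and densities mm⁻².

## Coordinate frames and geometry

Cell tables (`slide_id, marker, x_um, y_um`) are grouped into one
`PointPattern` per slide × marker; the observation window defaults to the
pattern's bounding box. Per-slide 3×3 affine matrices (slide → reference,
last row (0,0,1), invertible) map patterns and polygons into a common
frame; the package applies given matrices and scores the registration by
the Dice coefficient 2|A∩B|/(|A|+|B|), but never estimates transforms.
Self-intersecting annotation rings are repaired by a zero-width buffer and
the repair is logged.

## Consensus boundary and tissue partition

The per-marker tumor annotations are rasterized into a *score map*
(default 10 μm/pixel — far below the 500 μm buffers, so the partition is
raster-insensitive; halving the resolution moves region Dice scores by
< 1 % on smooth phantoms). Each pixel holds the number of annotation
polygons containing its center. The map is Gaussian-smoothed with
σ = 50 μm *before* thresholding (the order is our choice; the boundary is
insensitive to σ in 20–100 μm on phantoms), and pixels scoring > 2.5 of 5
form the tumor mask. Connected components smaller than 1.1 mm² are
discarded (the same area bound used to exclude unreliable profile bands);
each surviving component becomes a boundary polygon, so slides with
multiple tumor islands partition naturally.

The invasive front (IF) is the foreground within `if_width/2` (default
0.5 mm) of the boundary *curve* on either side; the central tumor (CT) is
the rest of the tumor mask; normal tissue (N) is the rest of the
foreground. Points exactly on shared borders resolve by the precedence
IF > CT > N. Both the 1.0 mm and 0.5 mm IF conventions are supported via
`if_width_mm`.

Raster masks are vectorised with marching-squares contour tracing
(scikit-image) and shapely ring nesting; this replaces a concave-hull pass
over pixel groups and is exact at pixel resolution.

## Moving-window grid

A square window of 0.4 mm side moves with a 0.2 mm stride (50 % overlap);
every scanned rectangle is a *subregion*. Counting uses half-open
rectangles so a point's membership in each overlapping window is well
defined; with stride = window the windows partition the gridded area and
counts sum exactly to the number of points. Windows are labelled by the
region containing their center; windows extending beyond the foreground
are kept but flagged `partial` (their density still uses the full window
area), letting downstream consumers exclude them.

## Infiltration profiles

Band construction follows a pixel-distance scheme on the same 10 μm
raster: CT and IF pixels are grouped by Euclidean distance to the IF
*inner* boundary (the CT side), N pixels by distance to the *outer*
boundary, in 150 μm intervals. Indices are signed — 0 is the central IF
band, positive indices run toward the tumor core, negative toward normal
tissue; with a 1 mm IF the IF carries indices −3…3 (the outermost IF band
is 100 μm wide because 1000/150 is not an integer), CT starts at +4 and N
at −4. Bands below 1.1 mm² are excluded from profiles.

The 95 % confidence band per band polygon is D ± T_c·σ/√n with T_c = 1.96,
n = A/(s_l·s_w) the effective number of 0.4 mm windows in the band, and σ
the *sample* SD (n−1) of window densities of the band's tissue type across
the whole slide — the band-level variance is assumed equal to the variance
of its tissue type. The lower bound truncates at 0, and a band whose
half-width exceeds 80 % of its density is flagged unreliable.

The within-IF profile samples points every 0.2 mm by arclength along the
consensus boundary (the IF midline by construction) and assigns each IF
pixel to its nearest sample point — a Voronoi tessellation restricted to
the IF. Sections are numbered from 1 at the left-most sample point,
proceeding clockwise in the image view. Heterogeneity across sections is
tested with a Pearson chi-square against area-proportional expectations
(df = k−1); a validity flag is raised when > 20 % of expected counts fall
below 1.

## Spatial entropy

H_SC = −Σᵢ (dᵢ_int/dᵢ_ext)·pᵢ·log₂ pᵢ over marker types present in a
subregion, with dᵢ_int the mean pairwise distance within type i, dᵢ_ext
the mean distance from type-i points to all other-type points, and pᵢ the
type share. Pairwise distances are exact (subregion counts are small). A
single present type gives H_SC = 0; a singleton type contributes
d_int = 0 and hence a vanishing term (the singleton case is our
definition). The statistic reduces to Shannon entropy when d_int = d_ext
and is invariant to rigid motions and global rescaling.

## Point-process modelling

**CSR test.** The Clark–Evans aggregation index R is the observed mean
nearest-neighbour distance over its CSR expectation; the test uses the
Donnelly edge-corrected expectation and variance with a one-tailed normal
approximation (alternative: clustered, α = 0.05). Patterns with fewer
than 10 points are flagged insufficient and skipped in the pipeline.

**Ripley's K** uses the border correction: at each radius r only
reference points farther than r from the window edge contribute,
K̂(r) = |W|·Σᵢ#{j≠i: d≤r}/(n_valid·(n−1)). The estimator is verified
against a brute-force double loop to 10⁻⁹.

**Thomas fit.** `ThomasModel(pattern).fit()` minimises the contrast
∫(K̂^q − K^q)² dr with q = 1/4 over r ∈ (0, window side/4] (64 radii) in
(log κ, log σ), with a small multi-start grid before a Nelder–Mead
polish. K is μ-free, so μ is identified as λ̂/κ̂ with λ̂ = n/|W|. Under
the reference conditions (κ = 10 mm⁻², μ = 20, σ = 20 μm, 2×2 mm window)
the median relative error of each parameter over 50 replicates is below
20 %. Derived summaries use the Rayleigh distribution of offspring
distances: mean σ√(π/2), F %-radius σ√(−2 ln(1−F/100)), and the reported
"cluster area" is the 95 % circle π·Q(95,σ)². Fits with κ̂|W| < 0.5 or
σ̂ > half the window side are flagged unreliable.

**Dispersion.** QCoD = (Q₃−Q₁)/(Q₃+Q₁) with linear-interpolation
(type-7) quartiles — pinned because the estimator changes QCoD on small
samples — and CoV = sd/mean with the sample SD.

**Goodness of fit.** A global Monte-Carlo envelope of L(r) = √(K/π) from
nsim ≥ 19 simulations of the fitted model; the envelope is the pointwise
min/max (rank-1 global envelope, two-sided level 2/(nsim+1), so nsim = 39
gives α = 0.05) and the p-value is the rank of the observed maximum
deviation from the simulation mean. An optional two-stage mode refits the
model to every simulation and measures each curve against its own refit,
removing parameter-estimation bias; the plain envelope is the default.

## Cluster morphometrics

Clusters come from HDBSCAN (scikit-learn) with min cluster size 30 and
core-neighbourhood size 4. Each cluster's outline is an α-complex — the
union of Delaunay triangles with circumradius ≤ α — grown geometrically
from α = 10 μm by factors of 1.1 until it is a single polygon containing
every member ("ideal size" formalised as connectedness + coverage), capped
at the convex hull. Convexity is A_α/A_convex, circularity 4πA_α/P_α²,
and the eccentricity √(1−λ₂/λ₁) comes from the eigenvalues of the member
coordinates' sample covariance; the 95 % ellipse semi-axes are
√(λᵢ·χ²₂(0.95)) with χ²₂(0.95) = 5.991. Classification: nodular iff
convexity > 0.8 ∧ circularity > 0.5 ∧ e < 0.8; elongated iff
convexity < 0.3 ∨ circularity < 0.3 ∨ e > 0.9 (precedence: elongated);
otherwise "other". Clusters are assigned to regions by their centroid.

Note on sampling noise: the eccentricity of a genuinely isotropic sample
is not 0 but ~n^(−1/4) (the eigenvalue gap of the sample covariance scales
as √(2/n)), ≈ 0.1–0.2 at n = 10⁴; the classification thresholds are far
above this noise floor for real cluster sizes.

## Degree of colocalization

For every point of channel A, cumulative neighbour counts of both channels
are taken on circles of radius 10–100 μm (step 10); the Spearman rank
correlation ρ_AB of the two count vectors across radii is damped by the
nearest cross-channel distance: DoC_A = ρ_AB·e^(−N_AB/R_max),
R_max = 100 μm, computed symmetrically for channel B. The subject point
is excluded from its own channel's counts and included in the other's.
Points whose count vector is constant in either channel (no neighbours
within R_max) have undefined rank correlation and are assigned DoC = 0
with a flag.

Spearman operates on the *cumulative* counts deliberately: ranks are
invariant to any per-point normalisation, and the monotone cumulative form
is what makes a well-localized pair score ρ ≈ 1 — dividing by the circle
area makes the vectors unimodal in r and a 10 μm registration shift then
destroys the rank agreement. A consequence worth knowing: two jointly
monotone vectors cannot rank-anticorrelate (Chebyshev's sum inequality),
so in practice scores live in [0, 1] and segregation appears as DoC ≈ 0
(large N_AB and/or undefined gradients) rather than as negative values;
the formal [−1, 1] bound still holds.

The classification threshold is calibrated per slide: the pattern is
paired with a copy of itself shifted left by 10 μm/0.976 ≈ 10.246 μm (a
perfectly colocalized pair blurred by the registration error) and the
mean DoC of the unshifted channel is the threshold — ≈ 0.9 for clustered
patterns, with ≥ 90 % of points above 0.84. R_max = 100 μm and the 10 μm
radius step are package defaults chosen so this calibration shift lands
near e^(−0.102) ≈ 0.90; both are configurable.

Hotspots: correlated points (DoC > threshold) of both channels are pooled
and clustered with the same HDBSCAN parameters; clusters containing both
channels are *positive* hotspots. *A-dominant* (negative) hotspots pool
correlated A with non-correlated B (B ≤ threshold) and must again contain
both kinds; B-dominant is symmetric. Summaries report correlated cells
(channel points inside hotspot outlines), their percentage of the channel,
hotspot density per region (centroid assignment), and the QCoD of the DoC
scores.

## Stereology

N_V = N_A/(t + D − 2h) converts profile densities to volumetric ones,
with h = D/2 − √((D/2)² − A_crit/π) the smallest detectable spherical-cap
height. Defaults are midpoints of literature ranges for lymphocytes: section thickness
t = 4.75 μm (range 4.5–5), T-cell diameter 6.05 μm (5–7.1), B-cell
7.25 μm (5.5–9), A_crit = 10 μm². A Monte-Carlo slab simulation (10⁵
spheres) confirms the conversion recovers the true volumetric density
within 5 %.

## Synthetic data and what it does / does not show

Generators are seeded and bit-reproducible. Thomas simulation draws
parents on the window extended by 4σ so edge clusters are represented
without bias. The tumor phantom is a harmonically perturbed circle
(radius 2.5 mm in an 8×8 mm foreground) with five jittered boundary
copies standing in for consecutive sections, and per-region Poisson
marker intensities defaulting to IF : CT : N = 300 : 100 : 50 mm⁻² — the
IF-enriched infiltration structure the method is designed to detect, at
densities typical of lymphocyte markers in carcinoma sections.

The phantom validates the geometry and statistics end to end (boundary
recovery DSC > 0.95, profile peak inside the IF, hotspot recovery only
where generated), but it is piecewise-homogeneous Poisson within regions:
it does not emulate segmentation noise, staining variability between
consecutive sections, anisotropic infiltration, or the within-region
clustering of real lymphocyte patterns. Passing these tests therefore
demonstrates correctness of the estimators under their model assumptions,
not performance on real slides.

## Problem sizes

Default test and acceptance runs use desk-scale conditions: 2×2 mm
windows with ~800–900 points for fitting and DoC, a 5×5–8×8 mm phantom at
10 μm raster resolution, 50 replicates for parameter recovery and 1000
for test-size calibration. These sizes were chosen so every distributional
check has enough replication for its stated tolerance.

## Known limitations

- The consensus boundary depends mildly on the smooth-then-threshold
  order; we smooth first (documented above).
- μ of the Thomas process is identified only through λ̂/κ̂; misfit in κ
  propagates inversely into μ.
- DoC anti-correlation is not observable with cumulative count vectors
  (see above); segregation maps to scores near 0.
- Region assignment of windows, clusters and hotspots uses centers or
  centroids; objects straddling region borders are not split.
- The IF sectioning assumes a single dominant boundary ring; satellite
  islands contribute bands but not IF sections.
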