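# spatialtme

Spatial-statistics toolkit for quantifying intra- and inter-tumoral
heterogeneity of immune-cell patterns on whole-slide images (WSIs).

Digital pathology pipelines export, per immunohistochemistry marker (CD3,
CD4, CD8, CD20, FoxP3, ...), one (x, y) coordinate per detected positive
cell, plus pathologist-drawn tumor-boundary annotations. `spatialtme`
turns those exports into quantitative descriptions of the tumor
microenvironment — no pixel data required:

- **Region partition** — overlay the coregistered per-marker boundary
  annotations into a score map, threshold the smoothed map at a majority
  score (> 2.5 of 5) for the *consensus tumor boundary*, and buffer it
  ±0.5 mm into normal tissue (N), invasive front (IF) and central tumor
  (CT).
- **First-order statistics** — cell counts and densities in a moving
  0.4 mm window (0.2 mm stride); waterfall rankings and 3-D landscape
  exports.
- **Infiltration profiles** — cell density versus signed distance to the
  boundary in 150 μm bands, with 95 % confidence bands
  D ± 1.96·σ/√n, n = A/(s_l·s_w); Voronoi sectioning of the IF along its
  midline and a quadrat chi-square heterogeneity test.
- **Spatial entropy** — the distance-adjusted Shannon entropy
  H_SC = −Σᵢ (dᵢ_int/dᵢ_ext)·pᵢ·log₂ pᵢ of the multitype marker pattern
  per subregion.
- **Point-process modelling** — one-tailed Clark–Evans CSR test; Thomas
  cluster-process fits by minimum contrast against
  K(r) = πr² + (1/κ)(1 − e^(−r²/4σ²)); Rayleigh cluster summaries
  (mean offspring distance σ√(π/2), 95 % radius σ√(−2 ln 0.05)); QCoD and
  CoV dispersion tables; Monte-Carlo goodness-of-fit envelopes.
- **Cluster morphometrics** — HDBSCAN cluster detection (minPts = 30,
  K = 4), grown α-shape outlines, convexity A_α/A_convex, circularity
  4πA_α/P_α², covariance-ellipse eccentricity √(1 − λ₂/λ₁), and
  nodular / elongated classification.
- **Colocalization** — per-point degree-of-colocalization
  DoC = ρ_AB·e^(−N_AB/R_max) between marker pairs, threshold calibration
  from a shifted synthetic pair, positive and dominant (negative)
  correlation hotspots with per-region summaries.
- **Stereology** — 2D areal to 3D volumetric density conversion
  N_V = N_A/(t + D − 2h) for parameterizing downstream simulation models.

A seeded synthetic-data module (Poisson, Thomas, multitype, shifted pairs
and a full tumor *phantom* with ground-truth regions) makes the entire
workflow testable without any slide data.

## Worked example

```python
from shapely.geometry import box
import spatialtme as st

# a clustered pattern at the reference conditions:
# 10 clusters/mm^2, 20 cells/cluster, 20 um spread, 2 x 2 mm window
pattern = st.sim_thomas(10, 20, 20, box(0, 0, 2000, 2000), seed=42)

ce = st.clark_evans(pattern)
print(f"Clark-Evans R = {ce.clark_evans_R:.3f} -> {ce.verdict}")

res = st.fit_thomas(pattern)       # ThomasModel(pattern).fit()
print(res.summary())

print(f"calibrated DoC threshold: {st.calibrate_threshold(pattern):.3f}")
```

prints

```
Clark-Evans R = 0.298 -> clustered
Thomas cluster process (minimum contrast on Ripley K)
  n points            : 928
  window area (mm^2)  : 4.0000
  kappa (clusters/mm2): 11.5110
  mu (cells/cluster)  : 20.1546
  sigma (um)          : 20.3982
  mean dist (um)      : 25.5654
  95% radius (um)     : 49.9297
  cluster area (mm^2) : 0.007832
  contrast            : 94.7356
  converged           : True   unreliable: False
calibrated DoC threshold: 0.913
```

R ≪ 1 rejects complete spatial randomness in the clustered direction; the
fit recovers the generating parameters (κ = 10 mm⁻², μ = 20, σ = 20 μm)
within minimum-contrast noise; the cluster summaries say a typical cell
sits ~26 μm from its cluster center and 95 % of a cluster fits in a 50 μm
radius. The DoC threshold is the mean score of the pattern against a copy
of itself shifted by the registration error (10 μm / 0.976) — points
scoring above it are called colocalized.

## Command line

The full pipeline runs from cell tables (CSV: `slide_id, marker, x_um,
y_um`), boundary annotations (GeoJSON) and optional affine matrices
(JSON):

```bash
spatialtme simulate -o phantom --seed 1      # synthetic input bundle
spatialtme all -c phantom/config.yaml        # every stage + manifest.json
spatialtme regions -c phantom/config.yaml    # ...or one stage at a time
```

Stage outputs are plain CSV/GeoJSON: region polygons, density grids,
profiles with confidence bands, entropy records, per-subregion fits,
cluster shapes, DoC scores, hotspots and stereology conversions.

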