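# Methods

`rtdcstats` implements the statistical layer of real-time deformability
cytometry (RT-DC): per-cell morphometrics from contours, distribution
diagnostics, mixture-model sub-population detection, PCA screening,
bootstrap differential deformation, and mixed-model significance
testing. This note documents the models, the parameter choices that
matter, and the limits of what the synthetic validation shows.

## Shape and texture features

Every event is a closed pixel polygon (vertices on pixel centers,
origin top-left, `x` along the flow, `y` downward) with an optional
8-bit grayscale patch. Features:

* **Area A** — shoelace polygon area, scaled by `pixel_size²` (μm²).
  No half-pixel dilation is applied; at typical cell sizes (hundreds of
  pixels across the contour) the boundary-pixel ambiguity is well below
  a percent.
* **Volume V** — solid of revolution about the flow axis through the
  centroid. Each half of the contour (below/above the axis, obtained by
  half-plane clipping) is revolved using the exact piecewise-linear
  integral `π∮y²dx`, and the two estimates are averaged. Validated
  against the sphere and spheroid closed forms (≤1% at ≥180 vertices,
  error decreasing with vertex count).
* **Circularity / deformation** — `C = 2√(πA)/l` with `l` the perimeter
  of the *convex hull*, `D = 1 − C`. The hull prevents corrugated
  contours from inflating the perimeter. A widely printed variant of
  this formula, `2πA/l`, is dimensionally inconsistent (area over
  length); the square-root form is the one that gives `C = 1` for a
  circle and is what we implement.
* **Inertia ratio I and orientation φ** — centroidal second moments of
  the enclosed area from the closed-form polygon expressions, computed
  on the raw contour (no hull; the second moments are robust to
  pixelation). `I = Iyy/Ixx` is 1 for a circle and `(a/b)²` for an
  x-aligned ellipse. `φ = ½·atan2(2∬xy, Iyy − Ixx)` returned in
  (−π/2, π/2]; isotropic shapes return 0 by convention (the ratio is
  0/0 there). Printed versions of this formula vary in the sign of the
  denominator; our convention is fixed by the rotated-ellipse test
  (rotating the shape by θ moves φ to θ).
* **Area ratio Δ** — hull area over contour area, the convexity gate:
  modulus extraction accepts only `1.0 ≤ Δ ≤ 1.05`.
* **Symmetry Sx, Sy** — signed area imbalance of the two halves cut by
  the centroid axes, in [−1, 1].
* **Brightness B, BStD** — mean/SD of raw grayscale values whose pixel
  centers fall inside the contour (even-odd rule). No background
  correction.
* **Haralick features** — 13 classical co-occurrence statistics
  (angular second moment, contrast, correlation, variance, inverse
  difference moment, sum average/variance/entropy, entropy, difference
  variance/entropy, two information measures of correlation). The GLCM
  is symmetric, normalized, accumulated over the four unique distance-1
  offsets, restricted to pairs with *both* pixels in-mask, and gray
  values are re-binned to 16 equal-width levels by default (the matrix
  is 16×16 regardless of bit depth). The binning count is configurable;
  published pipelines rarely state theirs, so cross-study comparability
  of absolute Haralick values is limited.

## Distribution diagnostics

Sorted values are plotted against `Φ⁻¹(mᵢ)` at Filliben's
order-statistic probabilities `m₁ = 1 − 0.5^(1/n)`,
`mᵢ = (i − 0.3175)/(n + 0.365)`, `mₙ = 0.5^(1/n)` (the same positions
scipy's `probplot` uses), and the squared Pearson correlation `R²`
measures linearity. The inverse normal CDF is essential: against raw
probabilities nothing is linear. Natural log is used for the
log-normal branch; the verdict is `lognormal` iff `R²(log x) > R²(x)`.
Ties are kept (stable sort, no jitter); non-positive values skip the
log branch with an explicit flag.

Deformation-like quantities are bounded below (D = 0), and in the
small-deformation regime the data pile up near the bound, so a normal
modulus distribution maps to a right-skewed deformation distribution —
the generator reproduces this (see below), and the diagnostic calls it
log-normal for the overwhelming majority of seeds.

## Gaussian mixtures, BIC, overlap, accuracy

Event tables are modeled as `X ~ Σ wᵢ N(μᵢ, Σᵢ)` with full
covariances, fitted by EM (scikit-learn's implementation: k-means
seeding, 10 restarts, ≤500 iterations, covariance ridge 1e-6). The
stopping tolerance is 1e-4 on the change of the mean per-event
log-likelihood bound: at the event counts used here a stricter 1e-6
changes BIC values by ~0.1% and never the selected K, while costing an
order of magnitude more EM iterations. The default clustering plane is
`(A, ln D)` — log-deformation because of the log-normality above.

Model selection minimizes `BIC = −2 ln L + t ln n` over K = 1..4 with
`t = (K−1) + K·k + K·k(k+1)/2`. Events are assigned to the component
maximizing `wᵢ N(x|μᵢ, Σᵢ)` (ties → lowest index). Assignment accuracy
against ground truth is `(TP+TN)/total`, maximized over the
cluster-to-class bijection (Hungarian matching), so label permutations
are irrelevant; a single merged cluster on two equal populations scores
exactly 0.5.

Population overlap is measured on jointly z-scored data: a single
Gaussian is fitted per population (sample mean/covariance), the
region with density ≥20% of the peak is rasterized on a 512×512 grid
spanning the means ±5 pooled SDs, and overlap = (intersection area)/
(stationary population's region area) × 100. The reference population
is the stationary one, making the metric deliberately asymmetric.
Agreement with a Monte-Carlo membership oracle is within 2 percentage
points. Whether contours should use fitted or generating parameters is
ambiguous in general; sample-estimated parameters are used.

### Shrinking-separation assay

Two 1000-event populations share a mean modulus of 2.5 kPa; the first
is stationary at mean area 70 μm², the second starts at 130 μm² and
its mean drops by 5 μm² per step, sliding along the isoelasticity
lines. Per step the pipeline computes overlap, selects K by BIC, and
scores accuracy. Two generator parameters are not fixed by the assay's
published description and were set as follows:

* **sd_E = 0.25 kPa (10% CV).** A literally constant modulus makes
  `ln D` an exact function of `A`: the populations are 1-D curves, the
  2-D covariance is singular, and neither the overlap metric nor the
  GMM is defined. A small spread restores genuine 2-D extent.
* **sd_area = 5 μm².** The population lies along the curve
  `ln D = c + 1.5 ln A`; its curvature over the area spread scales with
  `(sd_area/mean_area)²`. At sd_area = 10 μm² the bend is ~0.6 SDs of
  the modulus band and BIC reliably "detects" it as a second component
  even in a single homogeneous population — an artifact of the
  generator, not of the method. At 5 μm² the bend is ~0.08 band-SDs,
  below BIC's detection threshold at n = 2000, and a homogeneous
  population is correctly assigned K = 1.

With these conditions, BIC returns K = 2 at every step with overlap
below ~35% and collapses to K = 1 beyond it (the 50%-error regime); at
~50% overlap with K = 2 supplied externally, median accuracy stays
around 0.75. Occasional K = 3 selections at low overlap are the known
random overestimation of BIC on finite samples; seed medians absorb
them.

## Standardized PCA

Features are z-scored (they mix μm², grayscale counts and
dimensionless ratios), the covariance of the standardized data is
eigendecomposed, and components are sorted by decreasing eigenvalue
with a deterministic sign convention (largest-magnitude loading entry
positive). The explained variances sum to k. The rare-sub-population
screen plants a 1–3% "small dark" cluster (lower area/volume/
brightness, distinct texture) in an 11-feature table; a linear
threshold in the (PC1, PC2) plane recovers it with ≥95% recall at the
default shift. The 11 default features (A, V, D, I, Δ, Sx, Sy, B,
BStD, first two Haralick features) are a choice, not a canon — the set
is fully configurable.

## Differential deformation

`DDⱼ = Mⱼ,Ch − Mⱼ,Res` over B ≥ 1000 bootstrap iterations, resampling
each sample with replacement at its own size (channel drawn before
reservoir, one seeded stream). The statistic M defaults to the median
and is pluggable (mean, trimmed mean, callable). The DD distribution
is approximately Gaussian by the CLT (probability-plot R² > 0.98 at
B = 5000, n ≥ 500), which is what makes it usable directly as
observations in the mixed model: each bootstrap value is treated as an
observation of its sample, with the replicate as the grouping factor.
That convention slightly understates the dependence among bootstrap
values from one sample; the per-replicate random effects absorb most of
it. Raw (not log) deformation values enter the medians. The legacy
relative deformation `RD = (Mⱼ,Ch − Mⱼ,Res)/(Mᵢ,Ch − Mᵢ,Res)` is
provided for comparison only — it collapses the contrast to one number.

## Linear mixed model

`Y = Xβ + Zu + ε` with fixed intercept and condition effect, and a
per-replicate random intercept and random condition slope, independent
by default (`correlated=True` adds their covariance; with a handful of
replicates the correlation is rarely identifiable). The null model
drops only the fixed condition effect. Both models are fitted by full
maximum likelihood (never REML — REML likelihoods are not comparable
across fixed-effect structures), and `p` comes from Wilks' theorem
with one degree of freedom.

The fitter profiles the likelihood: for fixed random-effect scale
ratios λ = τ/σ, the GLS fixed effects and the residual variance have
closed forms via the Woodbury identity on per-replicate cross-products,
leaving a 2-parameter Nelder–Mead search on log λ (3 starts, plus the
null model's optimum as an extra start for the full model, which
enforces the likelihood nesting numerically). Costs are independent of
the number of events per replicate, so 500-fold null simulations are
cheap. Agreement with statsmodels' MixedLM and lme4 (ML, independent
random effects) is verified in the test suite to ~0.01 log-likelihood
units.

Calibration: with the slope variance truly at its boundary (no
effect-by-replicate variation) the χ²(1) reference gives a type-I
error of ~5% at α = 0.05 in 500-run null simulations. When a real
random slope is present with very few replicates (≤4), the LRT is
anticonservative — the normal approximation ignores the ~R degrees of
freedom available for the slope variance; this is a property of the
method, not of the implementation, and more replicates are the remedy.
Incomplete pairing (e.g. 2 vs 3 replicates) is handled by ML without
dropping data.

## Elasticity surrogate

The hydrodynamic theory mapping (area, modulus, flow) to deformation
is out of scope; a documented closed-form surrogate stands behind the
same interface: `D = c·(Q·η/W³)·A^{3/2}/E` with Q the flow rate
(μl/s), η the effective viscosity (mPa·s), W the channel width (μm),
and `c = 0.5` absorbing units, calibrated so the reference population
(A ≈ 343 μm², E ≈ 7 kPa, 0.04 μl/s, 15 mPa·s, 20 μm channel) sits in
the small-deformation regime (median D ≈ 0.02–0.06). It has the
qualitative properties the statistics rely on — D increasing in A,
decreasing in E, vanishing as E → ∞, and mapping a normal E to a
right-skewed D — and nothing more: absolute kPa values are
self-consistent round trips, never claims about real cells. Any
callable with the same signature can replace it.

The lookup table inverts the surrogate on a grid (default 120 areas ×
240 moduli, 200 deformation levels). Deformation spans orders of
magnitude and E(D) is close to a power law, so the D grid is geometric
and interpolation is bilinear in (A, log D) on log E — round-trip error
is ≤1% on the grid interior. Queries outside the tabulated region are
invalid (NaN), never extrapolated; the Δ gate (1.0–1.05) and the
small-deformation gate (D ≤ 0.03, switchable) are applied at lookup.

## Synthetic data: what it does and does not show

All generators are pure functions of (spec, seed). Non-positive draws
of A or E are resampled, not clipped (clipping would put point mass at
the bound and distort the D distribution). Defaults encode the study
conditions: the reference population (343 ± 80 μm², 7 ± 1.2 kPa), the
assay populations above, replicate designs with deformation-scale
noise (baseline 0.03, intercept SD 0.005, slope SD 0.002, residual SD
0.01, 4+4 replicates × 100 events), and reservoir/channel pairs with a
log-normal resting shape plus an additive stress response.

Passing tests on these data show that the statistical machinery does
what it claims under its own assumptions. They do not show robustness
to what real RT-DC data add: pixelation and segmentation noise in the
contours, camera noise and illumination gradients in the patches,
non-Gaussian and discrete features (pixel-quantized lengths), drift
within a measurement, or cell-type-specific distribution shapes. The
surrogate, in particular, makes no quantitative mechanical claims.

## Numerical choices

* Polygon operations (hull, half-plane clipping) via shapely; minor
  self-touches healed with a zero-width buffer before clipping.
* GMM ties in assignment and BIC ties in selection both break to the
  lowest index; BIC selection is deterministic given the seed.
* Probability-plot R² uses the population-SD normalization (the 1/n
  convention); this cancels in the squared correlation.
* Mixed-model variance ratios are bounded to `log λ ∈ [−12, 6]` to
  keep the Woodbury factors finite; a ratio at the lower bound is an
  effective zero variance.
* Degenerate inputs fail loudly: collinear contours, constant feature
  columns (named in the error), singular covariances, constant samples
  in the probability plot, empty masks.

## Problem sizes

The shipped validation uses 10 seeds × 13 assay steps (2000 events per
fit), 20 seeds × 5000 events for the skew check, 500 null simulations
(8 replicates × 50 events) for mixed-model calibration, and B = 5000
bootstrap iterations for the DD normality check. These sizes put the
Monte-Carlo error of each aggregate well inside its decision margin;
larger runs sharpen nothing that the tests assert.
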