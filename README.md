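# rtdcstats

Statistics for real-time deformability cytometry (RT-DC) data.

RT-DC images thousands of suspended cells per second as hydrodynamic
stress deforms them inside a narrow microfluidic channel, yielding a
per-cell contour, a bright-field patch, and from them a
multi-dimensional feature vector. This package provides the
statistical layer for such data, for cell biologists and biophysicists
analyzing mechanical phenotyping experiments:

* **Shape & texture features** — projected area A, solid-of-revolution
  volume V, bounding box (Lx, Ly), convex-hull circularity
  `C = 2√(πA)/l` and deformation `D = 1 − C`, second-moment inertia
  ratio `I = Iyy/Ixx` and orientation φ, area ratio `Δ = A_hull/A`,
  symmetry ratios (Sx, Sy), brightness (B, BStD), and the 13 Haralick
  co-occurrence texture features — all from a contour polygon and an
  optional grayscale patch.
* **Distribution diagnostics** — probability-plot correlation `R²`
  against Filliben order-statistic positions, for the raw and
  log-transformed data; deformation-like bounded features typically
  come out log-normal.
* **Sub-population detection** — full-covariance Gaussian mixtures
  `X ~ Σ wᵢ N(μᵢ, Σᵢ)` fitted by EM on (A, ln D), with the component
  count selected by the minimum of `BIC = −2 ln L + t ln n`;
  20%-max-density contour overlap and bijection-maximized assignment
  accuracy quantify how far two populations can approach before
  detection fails.
* **PCA screening** — standardized principal components to surface
  rare (1–3%) sub-populations invisible in any single feature plane.
* **Differential deformation** — the bootstrap statistic
  `DDⱼ = Mⱼ,Ch − Mⱼ,Res` (channel minus reservoir medians), which
  corrects deformation for non-spherical resting shapes.
* **Significance testing** — the linear mixed model
  `Y = Xβ + Zu + ε` with per-replicate random intercept and slope,
  tested by a maximum-likelihood likelihood-ratio (Wilks χ²₁) against
  a null without the fixed effect: the replicate, not the event, is
  the unit of evidence, unlike an event-level t-test that declares any
  tiny shift significant at n ≈ 10⁵.
* **Synthetic data** — generators for parametric contours, (area,
  modulus) populations mapped through a pluggable elasticity
  surrogate, shrinking-separation assays, planted rare populations and
  replicate-structured designs, so every method is testable with known
  ground truth.

Model-fitting components follow scikit-learn conventions
(`GMMSelector`, `StandardizedPCA`, `ReplicateLMM` with
`fit`/`predict`/`transform`, `get_params`, trailing-underscore fitted
attributes) and compose with sklearn tooling; thin functional wrappers
(`select_k`, `pca_fit`, `fit_lmm`, …) cover script use. See
[docs/methods.md](docs/methods.md) for models, parameter choices and
limitations.

## Worked example

Generate a realistic cell population (area ~ N(343, 80²) μm², Young's
modulus ~ N(7, 1.2²) kPa at 0.04 μl/s, 15 mPa·s, 20 μm channel), check
which distribution family fits deformation, then detect two
overlapping sub-populations:

```python
import numpy as np
import rtdcstats as rt

pop = rt.gen_population(rt.PopulationSpec(n=5000), seed=1)
res = rt.compare_normal_lognormal(pop["D"].to_numpy())
print(pop["D"].median(), res.r2, res.r2_log, res.verdict)
# 0.0342  0.9525  0.9795  lognormal

# two 1000-event populations at 2.5 kPa, ~20% contour overlap
t1, t2, overlap = rt.paired_populations_at_overlap(20.0, seed=3)
X = np.vstack([np.column_stack([t["A"], np.log(t["D"])]) for t in (t1, t2)])
truth = np.repeat([0, 1], 1000)

est = rt.GMMSelector(k_max=4, seed=0).fit(X)
print(round(overlap, 1), est.selected_k_,
      {k: round(v, 1) for k, v in est.selection_.bic_by_k.items()})
# 19.9  2  {1: 10650.6, 2: 10598.6, 3: 10599.7, 4: 10642.8}
print(rt.assignment_accuracy(est.labels_, truth))
# 0.885
```

Even at 20% overlap the BIC minimum lands on K = 2 (10598.6, against
10650.6 for a single component) and 88.5% of events are assigned to the
correct generating population. The fitted mean areas (70.2 and
82.2 μm²) convert to equivalent spherical diameters
`d = 2√(A/π)` of 9.5 and 10.2 μm.

A command-line interface mirrors the library
(`rtdcstats simulate population`, `diagnose`, `cluster`,
`overlap-assay`, `pca`, `dd`, `lmm`, `extract`); all randomized
commands take `--seed` and write provenance comments into their output
tables.

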