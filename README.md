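# retinograph

Quantitative retinal-vessel morphometry from fundus photographs, and
population-graph prediction of coronary artery disease severity.

The retinal microvasculature shares physiology with the coronary
circulation, so quantitative biomarkers of the fundus vessels — caliber,
tortuosity, bifurcation geometry, fractal complexity — are candidate
non-invasive markers of coronary stenosis as graded by CAD-RADS (the 0–5
Coronary Artery Disease Reporting and Data System). This package implements
that analysis end to end for researchers in ophthalmic/cardiovascular image
analysis: reading manual vessel tracings, extracting the biomarkers,
building a demographic-similarity population graph over fundus images, and
classifying CAD-RADS with a GraphSAGE graph neural network against five
classical baselines, under repeated subject-grouped cross-validation.

No clinical data ships with the package. A first-class synthetic-data module
generates every input with known ground truth — Murray-law vessel trees
(d₀³ = d₁³ + d₂³), fundus-like rasters with Gaussian-profile vessels, and
labelled cohorts with planted effects — so the whole pipeline is testable
and its estimators can be validated against analytic truth.

## What it computes

- **Calibration** — a rotated ellipse fitted to six clicked optic-disc
  boundary points; pixel size = 1800 µm / (longest disc diameter in px).
- **Width** — per segment, a morphological geodesic active contour grown
  from the traced centerline with edge-stopping g = 1/(1 + α|∇(G_σ∗I)|²);
  width = trimmed mean of normal-cast edge-to-edge distances (px and µm).
- **Tortuosity** — 14 metrics per segment: arc/chord ratio τ₁ and τ₂=τ₁−1,
  total (squared) curvature ∫|κ|ds, ∫κ²ds and their per-length densities,
  turn-angle sum, smoothed-curve index, mean κ², inflection-count
  coefficients, SD of κ; κ from analytic spline derivatives.
- **Bifurcations** — α=(d₂/d₁)², β=(d₁²+d₂²)/d₀², λ=d₂/d₁, λ₁=d₁/d₀,
  λ₂=d₂/d₀ and branch angles θ=θ₁+θ₂ at every junction (d₁≥d₂).
- **Fractal dimensions** — box D_B, information D_I and correlation D_C of
  the centerline point set over dyadic scales.
- **Population graph** — image-level nodes; edge weight = [same gender] +
  [|Δage| < 5 y] ∈ {1, 2}, pairs scoring 0 unconnected.
- **Learning** — two-layer mean-aggregator GraphSAGE
  (h_v ← σ(W·[h_v ‖ mean_{u∈N(v)} h_u]), numpy implementation) vs LR, LDA,
  kNN, Gaussian NB, RBF-SVM; feature selection by CFS, CMIM, DISR, ICAP,
  Laplacian score, SVM-backward, or none.
- **Evaluation** — repeated stratified 10-fold CV grouped by subject;
  sensitivity/specificity/accuracy/AUC/F1/precision with 95% CIs (Wilson,
  Hanley–McNeil), image-wise and subject-wise (eye-averaged); McNemar paired
  tests; per-SD odds ratios from covariate-adjusted logistic regression.

## Worked example

`examples/` contains one short script per capability. Closed-form checks
(`python examples/02_morphometry.py`):

```
straight segment:  tau1=1.000000 (expect 1), total curvature tau3=0.00e+00 (expect 0)
semicircle r=50:   tau1=1.5708 (expect 1.5708), tau3=3.1416 (expect 3.1416)
Murray junction:   alpha=1.000 lam=1.000 beta=1.2599 (expect 2^(1/3)=1.2599), theta=43.6°
line point set:    D_B=0.993 D_I=0.989 D_C=0.976 (expect 1.0)
```

A semicircular vessel has arc/chord π/2 and total curvature π; a symmetric
Murray-law junction has area ratio 2^⅓; a line has fractal dimension 1 — all
recovered to the stated precision.

The population-graph classifier on a synthetic cohort with planted
demographic homophily (`python examples/04_population_graph_gnn.py`):

```
population graph: 311 image nodes, 29161 similarity edges
GraphSAGE  image-wise AUC 0.716 (95% CI 0.659–0.774), subject-wise AUC 0.737
LR         image-wise AUC 0.566 (95% CI 0.502–0.630), subject-wise AUC 0.584
```

The ~0.15 AUC margin is the information carried by the demographic graph:
the cohort's class probability rises with age and is higher for men, so
neighbourhood aggregation sees signal a per-image classifier cannot.

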