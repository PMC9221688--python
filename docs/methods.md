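# Methods

This note documents the models, conventions and numerical choices behind
`retinograph`, and what the synthetic-data experiments do and do not show.

## Data model and calibration

Vessel tracings follow the NeuronJ convention: one polyline per vessel
segment, broken at branching points, typed artery/vein (NeuronJ's
"axon"/"dendrite" names), with parent labels; segments entering the image at
the optic disc or without a visible parent are roots ("N0"). The package
defines a minimal text dialect (`tracing.py` module docstring) carrying
exactly these fields; files it writes round-trip bit-identically.
Coordinates are 0-based pixel centers, x = column, y = row; polylines are
open.

The optic disc is annotated by six clicked boundary points and fitted with
the direct least-squares conic method constrained to an ellipse
(Halir–Flusser, via `skimage.measure.EllipseModel`); six points are one more
than the conic minimum, so the fit is near-interpolating and the residual
RMS is reported for quality control. Pixel size is 1800 µm divided by the
longest disc diameter, taken as twice the fitted semi-major axis rather than
the maximum pairwise click distance — the fit smooths click error. This
1800 µm convention is a population average; per-eye disc-size variation
(±~10%) propagates directly into µm-scale widths, which is why
classification uses standardized features.

## Width measurement

Per segment: (1) the centerline is resampled at 1 px arc-length steps;
(2) a closed contour is initialized by dilating it with a 2 px disk;
(3) a morphological geodesic active contour (skimage) evolves for 100
iterations with balloon +1 and edge-stopping g = 1/(1+α|∇(G_σ∗I)|²), α=2000,
σ=2.0 px; (4) 10% of the centerline is cropped at each end (contour caps are
not vessel boundary); (5) at each interior centerline point a normal is
cast and the sub-pixel 0.5-crossings of the converged level set on both
sides give an edge-to-edge distance; (6) distances outside
median ± 2.5·1.4826·MAD are trimmed; (7) the width is the mean of the
retained distances, also in µm via the disc calibration. Contour collapse or
fewer than 5 two-sided casts yield a flagged failure, never a number.

Edge model: the converged contour localizes the inflection (maximum
gradient) lines of the blurred profile, which for a Gaussian cross-section
of FWHM w sit at ±σ_obs, σ_obs² = (w/2.3548)² + σ². The reported width
inverts this: w = 2.3548·√((m/2)² − σ²) with m the trimmed mean separation.
This is a property of the stated rendering model, not a fitted constant;
`edge_model='none'` reports the raw separation. σ was set to 2.0 px (not
smaller) because on 8-bit images the gentle interior slope of wide vessels
quantizes into a staircase whose spurious gradient minima trap the contour;
2 px of smoothing removes them while the edge model corrects the added
blur. Reliability degrades below ~3 px true width, where the profile is
dominated by blur; accuracy there is explicitly out of contract.

## Tortuosity

A parametric cubic smoothing spline (FITPACK; residual budget n·smooth²,
i.e. `smooth` is the tolerated RMS deviation in px, default 0 =
interpolating) is resampled at uniform arc length and signed curvature is
taken from analytic spline derivatives, κ = (x′y″−y′x″)/(x′²+y′²)^{3/2}.
The 14 metrics are listed with formulas in `TortuosityVector`. Four of them
(smooth tortuosity index, CAIAR index, tortuosity coefficients 01/02) exist
in the literature by name with under-specified definitions; the operational
choices here — arc/chord of a 2 px-RMS smoothed curve; mean κ²;
(n_inflections+1)·τ₂ and (n_inflections+1)·τ₃/L_c — are documented
interpretations. Inflections are sign changes of signed κ with a relative
dead band (10⁻³ of the profile peak) so near-straight stretches do not
flicker. Scale behavior follows dimensional analysis: τ₁, τ₂, τ₉, τ₁₀, τ₁₂
are scale-free, τ₃ is scale-free, τ₄, τ₅, τ₇, τ₁₃, τ₁₄ scale as 1/L and τ₆,
τ₈, τ₁₁ as 1/L² — each is property-tested.

## Bifurcations

Daughters are relabelled so d₁ ≥ d₂, putting the asymmetry ratio α=(d₂/d₁)²
and bifurcation index λ=d₂/d₁ in (0,1]. The area ratio is β=(d₁²+d₂²)/d₀²
(a dimensionless ratio of lumen areas; minimum-work branching predicts
β=2^⅓ for a symmetric Murray junction). Branch angles are measured against
the parent's incoming tangent continued through the junction, with end
directions estimated from 5 resampled points to resist click jitter, and
θ ≡ θ₁+θ₂ by construction.

## Fractal dimensions

Box counting runs over dyadic box sizes 2, 4, 8, … px up to min(image)/4 on
a grid anchored at the point cloud's bounding box. D_B is the OLS slope of
log N(ε) vs log(1/ε); D_I the slope of Σp·log p vs log ε; D_C the
Grassberger–Procaccia slope of log C(ε) vs log ε with C the pair fraction
within ε (k-d tree pair counts). Scales occupying fewer than 5 boxes are
dropped from the box/information regressions to avoid saturation at coarse
scales (all retained if fewer than two survive); per-dimension R² is
attached. These are regression estimates on a finite scale range: a
degree-6 Sierpinski set reads ~1.56–1.59 against the similarity dimension
1.585, and re-gridding noise under rotation is ~±0.05 — tolerances the tests
reflect. Artery-only, vein-only and combined variants are all computed and
the feature schema picks which enter the vector.

## Feature schema and standardization

Features are named `type_metric_stat` / `variant_dim`. The default schema is
the fully transparent 190-vector: {max, mean, median, min} × {width,
τ₁..τ₁₄, α, β, λ, λ₁, λ₂, θ, θ₁, θ₂} × {artery, vein} + {D_B, D_I, D_C} ×
{artery, vein}. A documented `paper96` option produces a 96-vector (four
stats over width and seven junction metrics per type, mean-only
tortuosities, D_B/D_I per type); a 96-biomarker count admits several
decompositions and this one is a choice, not asserted ground truth. Missing
biomarkers (e.g. no vein junction traced) are explicit NaN, never silent 0.
Standardization z-scores with training-row statistics only, imputes the
training median, and maps zero-variance features to 0 with a warning; the
fitted parameters are reusable on test rows, and a leakage test perturbs a
test row and asserts the transform unchanged.

## Population graph and GraphSAGE

Nodes are fundus images with their feature vectors; for two subjects the
similarity score is [same gender] + [|Δage| < 5 years] (strict inequality),
pairs scoring 0 stay unconnected, and two images of one subject are linked
with weight 2 (the rule trivially yields it; a flag severs these edges).
Whether the published model consumed the 1-vs-2 weights or only edge
presence is not recoverable; the default aggregator ignores weights and
`use_edge_weights` enables a weighted mean.

GraphSAGE is implemented in numpy: L layers of
h_v ← relu(W·[h_v ‖ mean_{u∈N(v)} h_u]) (isolated nodes aggregate a zero
vector), a linear head with sigmoid, weighted cross-entropy on training
nodes only, Adam (lr 10⁻³, weight decay 10⁻⁴), dropout 0.5 on hidden
activations, 300 epochs, one seed for everything. Training is transductive:
messages flow over the full graph, the loss sees only masked nodes — test
*features* are legitimately visible in a population graph, test labels never
are (asserted by mutating them). Defaults n_layers=2, hidden 64. Early
stopping on a held-out slice of training nodes is available
(`val_fraction`>0) but off by default: at cohorts of a few hundred images
the validation slice is ~20 nodes and stopping on it proved far noisier than
a fixed epoch budget. With n_layers=0 the model is exactly a logistic
regression on the node features (tested to agree with scikit-learn's within
0.02 AUC). The "readout" of the architecture is the per-node linear head —
the task is node-level classification, not graph-level.

## Feature selection

CFS: best-first forward search on merit k·r̄_cf/√(k+k(k−1)·r̄_ff) with
absolute Pearson correlations, stopping after 5 non-improving expansions
(subset sized by the search itself). CMIM greedily maximizes
min_s I(f;y|s); DISR maximizes Σ_s I({f,s};y)/H(f,s); ICAP maximizes
I(f;y) − Σ_s max(0, I(f;s)−I(f;s|y)). Mutual information uses 5-bin
quantile discretization — deterministic and adequate at n≈200–400.
Laplacian score (unsupervised) uses a 5-NN heat-kernel graph, lower is
better. SVMB is recursive backward elimination over a linear-kernel SVM
(scikit-learn RFE), returning survivors ordered by final |coefficient|.
All selectors see training rows only.

## Evaluation

Folds are stratified by class and grouped by subject, so the two eyes of one
subject never straddle train/test — stricter than plain stratification and
possibly stricter than the original protocol, but it removes a
within-subject leakage path that inflates AUC. Each repeat reshuffles with a
derived seed; every image is predicted exactly once per repeat; the number
of repeats defaults to 10. Subject-wise results average each subject's
available eye probabilities. Metric CIs: Wilson score for proportions,
Hanley–McNeil for AUC (Mann–Whitney rank estimate), seeded percentile
bootstrap for F1 (not a plain proportion). Threshold 0.5 for the
thresholded metrics. McNemar on discordant counts uses the exact binomial
below b+c=25 and the continuity-corrected χ² above; b=c=0 reports p=1 with
a degeneracy flag. Association analysis fits binomial GLMs (IRLS) of the
label on the standardized biomarker plus covariates — adjustment model 1:
age, gender; model 2: + systolic blood pressure, heart rate, diabetes, BMI,
smoking — reporting per-SD odds ratios with Wald 95% CIs; separation or
non-convergence yields a flagged result with no OR.

## Synthetic data: what it emulates, and what it does not

The tree generator grows binary trees whose radii satisfy Murray's law
exactly, with bifurcation index λ~U(0.7,1), total branch angle θ~U(30°,90°)
split asymmetrically, sinusoidal centerline perturbation scaled by
`tortuosity_amp`, and recorded truth for every downstream estimand. The
rasterizer renders Gaussian cross-sections with FWHM = true width (how
defocused vessels blur, and it gives the active contour a well-defined
edge), a bright optic-disc ellipse, and additive Gaussian noise, to 8-bit
RGB with vessel contrast strongest in green.

The cohort generator mirrors the study conditions of a ~145-subject
CCTA+fundoscopy population: CAD-RADS class probabilities
(55,15,37,20,13,5)/145, 78/145 both-eyes probability, age 58.5±12,
58% male, and covariate moments (BMI 25.3±4.7, SBP 131±18.5, HR 72±12,
~17% diabetes, ~10% current smokers). A latent severity s~N(0,1) maps to
CAD-RADS through ordered-probit thresholds at those class quantiles;
age (r=0.45) and male gender rise with s, as do intervention flags. Feature
vectors are multivariate normal with left/right eyes correlated at ρ=0.7;
planted effects shift named features by effect·s SD — defaults of ±0.8 SD on
arterial width (narrower), arterial/venous branch angle (wider) and fractal
dimension (lower), the biomarker families reported as CAD-associated.
Marginals are normal by decision; the real biomarker distributions are not
published. The homophily variant makes class probability rise with age and
gender (male) so demographic neighbourhoods carry label signal beyond weak
own-image features; its slopes were chosen so the neighbourhood signal
clearly dominates (oracle: neighbour-mean features AUC ≈0.75 vs own ≈0.58).

Passing on these cohorts demonstrates correctness of the machinery —
estimator consistency against ground truth, leak-free evaluation, null
calibration, recoverability of planted effects — not clinical performance:
real fundus images have pathology, uneven illumination, crossing vessels
and annotation error that the generator deliberately omits (photorealism
and pathology rendering are non-goals).

## Problem sizes and runtime choices

Tests and the validation suite use sizes a laptop handles in minutes:
width recovery on 50 vessels rendered on 96×220 px frames; learning-stack
checks on cohorts of ~300 images with 10-fold CV and one repeat; OR
coverage with 200 simulations at n=2000. Larger cohorts and repeat counts
are plain parameters.

## Known limitations

- Width is an isotropic-Gaussian-profile instrument; real vessels with
  central light reflex or adjacent parallel vessels will bias it.
- Junction metrics require measured widths for parent and both daughters;
  junctions with failed width measurements are skipped, which can bias
  per-image junction statistics toward well-imaged vessels.
- The CFS best-first search is exact only in the greedy-beam sense; very
  correlated feature blocks may admit better subsets.
- The GraphSAGE implementation is CPU numpy; it is sized for
  population-graph cohorts (hundreds to a few thousand nodes), not large
  graphs.
- Fractal estimates depend on the scale range; comparing values across
  image resolutions requires identical scale policies.
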