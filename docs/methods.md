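# Methods

This note documents the models implemented in `mammoseg`, the parameter
choices and their rationale, the numerical schemes, what the synthetic
phantoms do and do not emulate, and the known limitations.

## Image model and preprocessing

A mammogram is modeled as a piecewise-smooth tissue image multiplied by
a slowly varying, strictly positive bias field and corrupted by additive
noise. All computation is double precision on the 0–255 scale after
min–max normalization; arrays are row-major with 0-based pixel-center
coordinates.

Breast extraction thresholds the normalized image at `roi_threshold`
(default 5), applies one binary opening (3×3) to break thin chains of
supra-threshold background noise, keeps the largest 8-connected
component, and fills holes. Without the opening, heavy additive noise
can percolate the background into the breast component; with it, the
extracted region is stable across all perturbation conditions.

## MICO bias correction

Energy: `E(M, C, b) = Σ_k ∫_ROI M_k^q (I − C_k b)² dΩ`, with the bias
`b = Σ_m w_m B_m` constrained to 2-D polynomials of total degree ≤ 3
(10 basis functions on [−1, 1]-rescaled coordinates). Minimization is
exact alternating descent: crisp (q = 1) or fuzzy-c-means-style (q > 1)
membership updates, weighted-mean class updates
`C_k = Σ b I M_k^q W / Σ b² M_k^q W`, and the normal equations
`A w = V` with `A[m,n] = Σ B_m B_n (Σ_k C_k² M_k^q) W`,
`V[m] = Σ B_m I (Σ_k C_k M_k^q) W`, where `W` is the breast-ROI
indicator. Each step minimizes the energy exactly in its block, so the
energy trace is non-increasing (tested). The scale ambiguity `C_k·b =
(sC_k)(b/s)` is resolved by rescaling `b` to unit ROI mean after every
bias update.

**Class-mean initialization.** Means are initialized evenly spaced
between the minimum and maximum ROI intensity, not at evenly spaced
quantiles. With a quantile initialization every mean starts inside the
dominant fibroglandular mode (a tumor occupies only a few percent of
the breast), and the alternating descent converges to a local minimum
in which the spare classes quantize the tissue continuum and the bias
field soaks up the residual — we verified on phantoms that the
ground-truth configuration has strictly lower energy than that local
minimum, i.e. the failure is optimization, not the model. Anchoring the
extreme classes at the intensity extremes lets the bright class contract
onto the tumor; bias-recovery correlation on battery phantoms then
reaches ≈ 0.95 and the bright-class mask alone outlines the tumor.

**Gradient-masked fitting weights.** The weight field `W` is the breast
ROI minus the top 10% of ROI pixels by (lightly smoothed) gradient
magnitude. Mixed boundary pixels violate the piecewise-constant model;
in particular a blurred tumor rim forms a wide intensity bridge between
tissue and tumor levels that otherwise drags the bright class mean down
the bridge until it swallows bright tissue, corrupting the bias fit
with it. Masking edges from the fitting sums (memberships and output
labels still cover the whole ROI) is established practice in bias-field
estimation and removed exactly this failure mode under the blur
perturbation. The alternating updates remain exact block minimizers of
the energy with this fixed weight field, so the descent property is
untouched.

Defaults (conventional settings for this model family): `iterNum` 20,
`N_region` 3, `q` 1, basis order 3, early stop at relative energy
decrease < 1e−6. The corrected image is `I_bc = I / clip(b, 0.1, 10)`:
the polynomial extrapolates arbitrarily outside the ROI (it can cross
zero there), and an unclamped division produces huge background values
that distort every later dynamic-range-based quantity.

## Global segmentation

Two level sets μ1, μ2 partition the breast into brightest / middle /
darkest regions through products of Heaviside functions. We use the
arctan Heaviside `H_ε(z) = ½(1 + (2/π) atan(z/ε))` with ε = 1 and its
exact derivative as the Dirac.

Evolution is explicit Euler with, per iteration:

* data force `−Σ_i (I − C_i b)² ∂M_i/∂μ_j` plus `ν·κ(μ_j)` with
  ν = 0.001·255² — the multiplicative residual `(I − C_i b)²` is the
  form consistent with the kernel-smoothed bias update
  `b = K∗(I ΣC_i M_i) / K∗(ΣC_i² M_i)` and the weighted mean update;
* **velocity normalization**: the bracket is divided by its 99th
  percentile magnitude and clipped to [−1, 1]. This is a pure
  reparametrization of evolution time (steady states unchanged) that
  makes the nominal time step 0.1 stable for squared 0–255 residuals
  (≈ 6.5·10⁴ raw) and — because the percentile, unlike the maximum —
  is insensitive to impulse-noise outliers, keeps the front moving
  under salt-and-pepper corruption;
* **extension to all level sets**: the data velocity is multiplied by
  `|∇φ|` rather than `δ_ε(φ)`, the standard acceleration for
  region-based flows; with the distance regularizer keeping `|∇φ| ≈ 1`
  this is a uniform speedup of the front rather than a change of model;
* **double-well distance regularization**: the flow
  `div((p′(s)/s − 1)∇φ) + Δφ` of the potential with wells at
  `|∇φ| = 0` and `1`. The naive single-well flow `Δφ − κ` is singular
  where `|∇φ| → 0` (the ridge of any signed distance map) and blows up
  an explicit scheme; the double-well diffusion rate is bounded;
* class means refreshed from the **crisp** region indicators: the
  arctan Heaviside has heavy tails, and smoothed-weighted means let the
  large far field contaminate every class mean, which biases fronts by
  about half a pixel;
* re-initialization every 25 iterations (below).

The same choices drive the two-phase distance-regularized Chan–Vese
evolution (`evolve_drcv`), with crisp interior/exterior means and the
data term oriented so regions matching the interior mean grow. The
global mask is `S_g = [I_bc ≥ T_otsu] ∧ {level-set interior}` with the
Otsu threshold computed inside the breast ROI, honoring both the
thresholding rule and the contour evolution.

## Re-initialization

Sussman flow `∂φ/∂τ = S(φ₀)(1 − |∇φ|)` with Godunov upwinding and the
smoothed sign `S = φ₀/√(φ₀² + 1)`, plus the Russo–Smereka subcell fix:
cells with a sign change to a 4-neighbor are relaxed toward their
initial subcell distance `D = φ₀/|∇φ₀|` instead. The fix matters: plain
upwind re-initialization can displace the zero crossing by up to a
pixel and, in particular, pushes freshly flipped one-pixel slivers back
across zero — which visibly stalled front convergence before the fix. A
signed distance map is a fixed point; `{φ > 0}` is preserved to
sub-pixel accuracy (tested on random smooth fields).

## Localized refinement (LAC then LIF)

Both stages replace global region means by local fitting fields
`f1 = K∗(H I)/K∗H`, `f2 = K∗((1−H) I)/K∗(1−H)` with a Gaussian window
K of σ = rad/2 truncated at 2σ (default rad 7, the middle of the
conventional 5–9 range).

Two refinements of the textbook scheme proved necessary:

* **Plateau margin.** The fitting weights exclude a band of 2 level-set
  units around the front (interior weight `H(φ − 2)`, exterior
  `H(−φ − 2)`). On blurred edges the half-transition rim otherwise
  enters both averages, pulls the implied decision level
  `(f1 + f2)/2` below the true edge midlevel, and walks the contour
  outward down the rim; with the margin, f1 and f2 estimate the two
  plateaus and the front settles on the half-level of the edge.
* **Local contrast normalization.** The force is
  `((I − f2)² − (I − f1)²) / ((f1 − f2)² + τ²)`, clipped to [−1, 1],
  with τ = 5% of the dynamic range. The raw quadratic force scales
  with the square of local brightness, so under a strong multiplicative
  bias the front crawls on the dim side of a tumor; the dimensionless
  form moves at the same rate wherever local contrast exists, which is
  precisely the bias-invariance the localized model is meant to
  deliver (tested: a 0.3–1.7 intensity ramp that breaks global
  Chan–Vese to Dice < 0.9 leaves localized evolution above 0.97).

LAC: `∂φ/∂t = δ_ε(φ)[F + α κ(φ)]` on a signed distance map, α = 0.01,
Δt = 0.1, re-initialization every 50 iterations.

LIF: the same force on a *selective-binary* representation: every 10
iterations φ is replaced by `4·G_{σφ}∗sign(φ)`. One such pass smooths
the boundary at scale σφ but also displaces a radius-R feature inward
by ≈ σφ²/(2R) (curvature flow); the cadence and the LIF time step
(2.0 on the ±4-amplitude representation) are balanced so the data force
re-anchors the boundary between passes. Applying the pass every
iteration would erode any clinically sized tumor faster than the banded
force can recover — this is why the regularization is periodic. The ±4
amplitude makes `δ_ε` ≈ 25× weaker in the far field than at the front,
confining the evolution to the current boundary instead of letting it
re-segment bright patches elsewhere.

σφ is a physical smoothing scale and follows the image scale: the
default 4 corresponds to full-resolution 1024×1024 mammograms; the
256×256 phantom battery uses σφ = 2, the phantoms' own edge width
(tumor rims are hard discs blurred with a σ = 2 Gaussian). Smoothing
below the edge scale under-regularizes (noise wiggles persist); far
above it, the per-pass curvature displacement σφ²/(2R) erodes
radius-10 tumors.

The refined mask is `S_r = [φ ≥ 0]` (zero-set pixels count as
foreground), intersected with the breast ROI.

## Panoptic instance stage

Per 8-connected component of `S_r`: Euclidean distance transform D
(distance to background; an isolated pixel has D = 1), markers =
h-maxima of D (h = 0.3·max D, minimum separation 5 px, plateau maxima
collapse to centroids, deterministic raster/height ordering),
marker-controlled watershed of −D restricted to the component,
morphological regularization (hole fill, open/close with a radius-1
disc, fragments < 25% of the largest dropped) **clipped to the parent
component with uncovered pixels reassigned to the nearest surviving
instance**, saddle-depth merging, and a minimum-area filter (τ = 30 px;
filtered pixels leave the semantic channel too).

The clipping/reassignment step is what makes the stage exactly
semantic-preserving: the union of instances equals the input mask pixel
for pixel (the identity reported by the acceptance script). The
standalone `morph_regularize` keeps the literal hole-filling behavior
for API users who want it.

**Merging rule.** Adjacent instances merge when the bottleneck saddle
height of D on their shared ridge is ≥ `depth_ratio` × the smaller of
their two distance peaks, iterated to a fixed point, lowest id first.
The default is depth_ratio = 0.7: two radius-10 discs with centers
16 px apart (saddle 6, peaks 10, ratio 0.6) remain two instances, while
artificial splits whose ridge runs near a peak are undone. A ratio of
0.5 would merge that canonical dumbbell, which contradicts the
marker-extraction behavior on the same shape; 0.7 keeps the two rules
consistent.

## Evaluation

DSC and IoU by pixel counting, with two empty masks scoring 1.0 so
perfect negatives are not penalized; quartiles by linear interpolation
between order statistics (IQR depends on this convention); two-sided
paired t with n−1 df; textbook Holm step-down for the two-metric
family (the literal symmetric-max variant is exposed alongside for
comparison but is not used for inference); percentile bootstrap of the
mean difference with a seeded generator, reported next to the normal
z-interval; panoptic matching at IoU > 0.5 (provably unique), with
SQ/RQ/PQ pooled over images by accumulating TP/FP/FN.

## Synthetic phantoms

A phantom is a half-disc breast silhouette on a dark background; tissue
at level 90 with band-passed Gaussian texture (σ 8 minus σ 32,
amplitude 12); 1–3 tumors at level 200 with erf-profiled rims (hard
discs blurred at σ = 2, so the half-level sits exactly on the true
boundary); a random order-2 polynomial bias of relative amplitude 0.3,
positive and unit-mean over the breast; additive Gaussian noise σ = 5;
clipping to [0, 255]. Ground truth (semantic mask, per-tumor instance
map with nearest-center assignment in overlaps, bias field) refers to
the pre-bias, pre-noise scene and is exact by construction. The texture
is band-passed deliberately: low-pass texture has most of its power at
image scale and aliases into the polynomial bias subspace, making the
"true" bias unidentifiable for any method — a property of the phantom,
not of an estimator.

The standard battery is 20 fixed seeds (0–19) at 256×256 with 1–3
tumors (cycling by seed), a 0.25 touching probability, and the noise
and bias levels above. Perturbation magnitudes for the robustness
harness: Gaussian noise σ = 10, salt & pepper density 0.02, contrast
factor 0.5, rotation 15°, Gaussian blur σ = 2 — realistic QA-level
corruptions, fixed once.

What the phantoms do **not** emulate: anatomical ductal/fibroglandular
structure, pectoral muscle, spiculated or non-convex mass shapes,
scanner-specific noise models, and the 1024×1024 resolution of clinical
films. Passing the battery therefore demonstrates correctness of the
algorithms under controlled inhomogeneity, weak boundaries, touching
instances and standard corruptions — not clinical-grade accuracy.

## Problem sizes and operating points

The battery runs at 256×256 with the reduced-iteration operating point
(`fast_config`: 120 multiphase, 100 LAC, 200 LIF iterations, σφ = 2),
mirroring the method's low-cost operating point; the library defaults
(300 LAC / 800 LIF, σφ = 4) correspond to the high-precision setting at
full resolution. Level-set unit tests use 64–96 px analytic phantoms
where oracles (disc masks, planar fields, known curvature 1/R) are
exact.

## Known limitations

* The three-region global model assumes exactly one "brighter than
  dense tissue" class; multifocal disease with very different mass
  intensities may split across classes.
* The LIF smoothing bridges concavities narrower than σφ (touching
  tumors keep a slightly rounded neck); the instance stage compensates
  by splitting on the distance transform.
* The saddle-depth merging rule is a declared design choice; the
  "correct" merge criterion for clinical instances is not derivable
  from first principles.
* Holm adjustment treats the two metric families as the only
  comparisons; per-image tests are not corrected.
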