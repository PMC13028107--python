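# mammoseg

Training-free segmentation of tumors in dense-breast mammograms, with
panoptic-style tumor instance analysis.

Dense breast tissue makes mass segmentation hard for threshold- and
edge-based methods: a smooth multiplicative bias field b(x, y) distorts
intensities across the film, tumor boundaries are weak and blurred, and
several masses can abut one another inside a single bright region.
`mammoseg` implements a classical, fully deterministic pipeline that
attacks each of these in turn — no training data required:

1. **Preprocessing** — min–max normalization to [0, 255] and breast-region
   extraction (threshold I > 5, largest 8-connected component, hole
   filling), removing film labels and background.
2. **MICO bias correction** — models the image as `I ≈ Σ_k M_k C_k b`
   with crisp memberships `M_k`, class means `C_k`, and a bias field `b`
   in the span of order-3 2-D polynomials, and minimizes
   `E(M, C, b) = Σ_k ∫ M_k^q (I − C_k b)² dΩ` by exact alternating
   descent. Output: the bias-corrected image `I_bc = I / (b + ε)` and an
   initial 3-class tissue map `S0`.
3. **Global segmentation** — a three-region model driven by two
   coupled level-set functions (regions `M1 = H(μ1)H(μ2)`,
   `M2 = H(μ1)(1 − H(μ2))`, `M3 = 1 − H(μ1)`) with distance-regularized
   evolution, combined with Otsu thresholding of `I_bc` inside the
   breast: `S_g = [I_bc ≥ T] ∧ {μ1, μ2 > 0}`. A two-phase
   distance-regularized Chan–Vese evolution is also provided.
4. **Localized refinement** — localized active contours (LAC) followed by
   local-image-fitting (LIF) evolution: the global means c1, c2 are
   replaced by Gaussian-window fields f1, f2 around the contour, so the
   front tracks local contrast even where residual intensity drift
   defeats global statistics. Output: the refined mask `S_r`.
5. **Panoptic instance stage** — connected components of `S_r`, Euclidean
   distance transform, h-maxima markers, marker-controlled watershed,
   morphological regularization, saddle-depth merging of shallow splits,
   and a minimum-size filter, yielding the pair
   `P(x, y) = (S_r(x, y), ID(x, y))`. By construction the union of
   instances equals the semantic mask pixel for pixel.

Evaluation utilities cover DSC `2|G∩S|/(|G|+|S|)`, IoU `|G∩S|/|G∪S|`,
mean/SD/median/IQR summaries, the paired t statistic
`t = d̄/(s_d/√n)` with Holm–Bonferroni adjustment, seeded percentile-
bootstrap confidence intervals, and panoptic quality
`PQ = SQ × RQ` with IoU > 0.5 instance matching.

A synthetic phantom generator produces mammogram-like images with exact
ground truth (breast silhouette, band-passed tissue texture, soft-edged
tumors, known polynomial bias, noise) plus a perturbation harness
(Gaussian noise, salt & pepper, contrast reduction, rotation, blur), so
the whole pipeline is testable without any clinical data.

## Worked example

```sh
python examples/segment_phantom.py
```

prints (seed-0 phantom, two tumors):

```
global-stage mask  Dice = 0.9847
refined mask       Dice = 0.9875
instances found    = 2 (truth 2)
panoptic quality   SQ = 0.9751  RQ = 1.0000  PQ = 0.9751
```

The refined mask agrees with the soft-edged ground truth to within about
one boundary pixel (Dice ≈ 0.99); RQ = 1 means both tumors were found
exactly once, and SQ is their mean pixel overlap. The other scripts in
`examples/` demonstrate bias-field recovery, watershed splitting of
touching tumors, batch evaluation with statistics, and perturbation
robustness.

A thin CLI wraps the same library calls:

```sh
mammoseg phantom --battery --out phantoms/
mammoseg segment phantoms/phantom_000.png --out out/ --save-intermediates
mammoseg evaluate --pred out/ --truth phantoms/ --out report.csv
```

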