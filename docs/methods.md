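# Methods

This note documents the models, numerical choices, and defaults behind
`abruptcut`, and what the synthetic experiments do and do not establish.

## Coordinates and conventions

All rasters use 0-based `(row, col)` indices with pixel centers at integer
coordinates and the row axis pointing down. Freeman codes are numbered
counter-clockwise in conventional x/y axes (x = col, y = −row): 0 = east,
2 = north, 4 = west, 6 = south. A contour that is counter-clockwise in x/y
therefore appears clockwise on screen. Masks are PNGs with foreground
> 127; in memory they are arrays of {0, 1}.

## Boundary tracing

Masks are first reduced to their largest 8-connected component with
interior holes filled (the contraction stage assumes a simply connected
lesion). Tracing is Moore-neighbor following from the scan-order-minimal
(topmost, then leftmost) pixel, scanning each Moore neighborhood clockwise
on screen from the backtrack neighbor. Two non-textbook details:

* **Stopping.** The classic rule (stop on re-entering the start with the
  initial backtrack) can fail because the artificial initial state may be
  transient. We stop when the start pixel is revisited with *any*
  previously seen backtrack direction and trim the transient prefix; the
  walk state has then provably recurred, so the cycle is closed.
* **Inner corners.** A diagonal move cuts the corner past a pixel whose
  only background contact is diagonal; that pixel is a boundary pixel
  (8-neighbor definition), so the tracer routes through it with two
  4-connected moves. With this, the traced point set equals the
  brute-force boundary set {foreground pixels with a background
  8-neighbor} on every test shape. Pixels on one-pixel-wide spurs can
  appear twice per pass; set-level completeness is the guaranteed
  invariant.

## Level-set border contraction

The border is embedded as the zero level of the signed Euclidean distance
φ (negative inside; computed from two distance transforms with a half-pixel
correction so the zero level sits on the midline between foreground and
background pixel centers). Inward motion at speed 1 is the Hamilton–Jacobi
equation φ_t − ‖∇φ‖ = 0, solved with the first-order Osher–Sethian upwind
scheme (one-sided differences switched per sign, edge values replicated),
dt = 0.5 against the CFL bound. The upwind switch realizes the entropy
condition: fronts annihilate instead of crossing, so the contracted curve
is simple even past concavities with curvature radius < L, where the
Lagrangian pointwise offset (implemented as `naive_normal_offset`, with the
inward normal fixed geometrically by choosing the smaller-area candidate)
self-intersects.

Reinitialization runs every ⌈L/5⌉ time units. It rebuilds φ as the signed
distance to the *sub-pixel* current front (marching-squares contour,
densified to 0.5 px, queried through a k-d tree); re-running the binary
distance transform instead would re-quantize the front to half-pixel
positions each time and accumulate error.

Because the speed is constant, the entropy solution at time L coincides
with the iso-curve of the inside distance transform at depth L. That
equivalence is used two ways: `contract_border(..., method="distance")` is
a fast path, and the distance-transform iso-curve is the independent oracle
that the time-stepped scheme is tested against (symmetric Hausdorff
distance < 1.5 px on random blobs; < 1 px radius error on analytic disks).
Zero level sets are extracted with marching squares; if a contraction
splits the lesion into several loops, all are returned with a warning and
the annulus uses their union.

Degenerate inputs: an empty or all-foreground mask, dt outside (0, 0.5],
and contraction distances at or beyond the lesion inradius raise errors;
the over-contraction error names the maximal feasible distance.

## Peripheral patch layer and features

The annulus between the original border and the border contracted by
L = 2r is tiled with circular patches of radius r whose centers lie on the
mid-curve (the iso-curve of φ at depth r) at arc-length spacing r, so each
patch is tangent to both borders and consecutive patches overlap by ≥ 50%.
A pixel belongs to a patch when its unit cell overlaps the circle (center
distance ≤ r + ½); this closes the rasterization gap at the annulus edges
and makes the patch union cover ≥ 95% of annulus pixels at spacing r.
Patches are clipped to the annulus so lesion-interior and background
texture cannot contaminate the statistics; patches with fewer than 9
usable pixels are dropped, and fewer than 4 surviving patches is an error
(lesion too small for that radius).

Per channel the statistics are: GLCM homogeneity on values quantized to 32
uniform levels over [0, 255], with a single offset (Δx, Δy) = (1, 0),
symmetrized and normalized (the matrix is deliberately rotation-variant; no
direction averaging); and mean and population standard deviation (ddof = 0)
of the raw values. HSV channels come from the standard RGB→HSV transform
with H rescaled to [0, 255] so all channels share one quantizer; circular
statistics for hue are not used — a known limitation. Aggregates per
channel, in fixed order: mean and min of homogeneity, of patch means, and
of patch stds. All GLCM settings are exposed in the configuration.

## Classifiers and evaluation

Features are standardized (z-score) inside every model pipeline. The
single-hidden-layer perceptron uses one ReLU layer as wide as the input;
the multi-hidden-layer network uses 4 ReLU layers of 4 nodes with a softmax
output over the two classes. Both train full-batch with Adam at learning
rate 0.001, at most 1000 epochs, stopping when the inter-epoch loss
improvement stays below 1e-4 (for 10 consecutive epochs); plain
momentum-free gradient descent at this learning rate does not converge in
1000 epochs and is available via `solver="sgd"`. A fit that ends as a
constant single-class predictor on its own training data (a dead-ReLU
failure mode of the narrow net, ~6% of fits) is retrained with a
deterministically reseeded initialization, up to 5 restarts. The SVM uses
a polynomial kernel of degree 3, `gamma="scale"`, coef0 = 0, and a large
box constraint C = 1e6 (effectively hard margin, honoring a "box constraint
inf" configuration; the one-class "outlier fraction" option that sometimes
accompanies it has no coherent two-class meaning and is ignored). No class
reweighting by default.

Evaluation is stratified 10-fold cross-validation repeated 10 times, every
fold split and every model seed derived from one master seed. Metrics are
averaged per fold (not pooled): precision and recall are macro over the two
classes, sensitivity is malignant-class recall, specificity benign-class
recall, and F1 the harmonic mean of the per-fold macro precision and
recall. Per-fold confusion matrices are retained in the report so every
mean is recomputable.

## Synthetic lesions

The generator renders what the feature extractor is designed to measure,
nothing more. A lesion is a star-convex blob ρ(θ) = R(1 + Σ aₖcos(kθ+φₖ))
(harmonics k = 2…7, total amplitude = `irregularity`), filled with
correlated brown pigment (Gaussian-smoothed noise, default correlation
scale 3 px, palette base (128, 84, 60) ± (38, 28, 20)) on light skin
(206, 176, 156), plus i.i.d. Gaussian pixel noise (default sd 4). The mask
is exactly the blob support — single component, hole-free, star-convex.

The border transition carries the entire class signal and is centered 2 px
inside the mask border (a segmentation boundary encloses the pigment
cutoff; a transition exactly on the mask edge would be invisible to
annulus-clipped patches):

* **Abrupt (malignant-like):** the pigment terminates over ≤ 1 px along a
  contiguous arc covering an `abrupt_fraction` of the perimeter (cohort
  jitter 0.08–0.9, mirroring the clinical picture of cutoff in a subset of
  border octants), on a ragged line (angular noise, sd 1.5 px, ~2°
  correlation — a smooth analytic cutoff would be invisible to the single
  horizontal GLCM offset wherever the border runs horizontally); the rest
  of the perimeter fades gradually.
* **Gradual (benign-like):** an erf-shaped fade of length `edge_width`
  (jitter 8–28 px) that reaches skin at the mask border, so the fade
  occupies the peripheral band itself.

Class-neutral nuisances, identical in distribution for both classes: small
dark peripheral globules (Poisson mean 3, radius 2–4 px) that create
locally sharp spots, and 5% symmetric diagnostic label noise (borderline
melanocytic lesions carry disputed labels in real cohorts; the generated
morphology in `specs` remains the ground truth). Per-lesion jitter of
size (base radius 78–95 px), irregularity (0.08–0.2), texture scale
(2.5–3.5 px), and noise sd (3–5) provides cohort heterogeneity; the
nuisance magnitudes were chosen so that the edge-profile effect is
detectable at the study sizes used (50 + 50 lesions for the
group contrast; a 100 + 100 cohort for classification). The feasibility
invariant `base_radius·(1−irregularity) > 60 px` keeps every patch radius
up to 15 px usable.

What passing tests show — and what they do not: the synthetic cohort
validates that the pipeline's peripheral features measure border
abruptness specifically (interiors are matched), that the level-set
contraction is numerically correct, and that the evaluation protocol is
sound. It does not emulate hair, rulers, bubbles, specular highlights,
multi-lobed lesions, or photometric variation between clinics, so
performance numbers on it say nothing about accuracy on real dermoscopy
archives.

## Problem sizes

Defaults keep every computation desk-scale: 256×256 images, lesions of
radius ≈ 85 px, full-grid level-set updates (no narrow band — correctness
first at these sizes), cohorts of 200 lesions, and 10×10-fold
cross-validation; a full synthetic pipeline run fits comfortably in a few
minutes on one CPU.
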