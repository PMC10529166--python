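# Methods

This note records the models, parameter choices and numerical decisions
behind `woundmetric`, and what the synthetic test substrate does and
does not establish about real clinical photographs.

## Wound ROI segmentation

The segmentation stage assumes the wound is a colour-coherent region
(possibly composed of several distinct tissue colours) surrounded by
skin of a different colour, and that the user can draw a scribble that
stays inside the wound and crosses its tissue zones.

**Superpixels.** SLIC over-segmentation (scikit-image) in CIELAB with a
Gaussian pre-blur of width σ. Operating variables and defaults:

| parameter | default | meaning |
|---|---|---|
| `n_segments` | 100 | requested superpixel count; a grid study over N ∈ {50, 100, 200} × σ ∈ {1, 3, 5} found (100, 3) best on this protocol |
| `sigma` | 3 px | pre-blur width; suppresses sensor noise before clustering |
| `compactness` | 10 | colour-vs-proximity weight; standard SLIC practice |
| `max_iter` | 10 | k-means iteration cap |
| `enforce_connectivity` | on | orphan fragments relabelled into neighbours |

Under-segmented images can be re-run with the retry counts
{150, 200, 300} (`RETRY_N_SEGMENTS`); no automatic failure detector is
provided because no reliable criterion exists — the retry list is a
user-facing escape hatch. `suggest_params` additionally supports a
polynomial model mapping image megapixels to (N, σ), clipped to the
explored ranges N ∈ [50, 300], σ ∈ [1, 5]; with no fitted
coefficients it returns the grid-study optimum (100, 3).

**Scribble-seeded merging.** Every superpixel touched by the 1-px
rasterised scribble becomes a seed. The seeds' mean CIELAB colours form
a set of *frozen colour prototypes*; a neighbouring superpixel on the
adjacency graph is admitted when its mean colour lies within
`merge_threshold` (default 25 CIELAB units) of the nearest prototype.
Growth proceeds in rounds, in superpixel-id order, until a round admits
nothing; the wound mask is the union of admitted superpixels (never a
fraction of one) and the contour traces its largest 4-connected
component.

Two design points deserve justification:

* *Multiple frozen prototypes rather than one running mean.* A wound
  bed mixes very different colours (dark eschar, yellow slough, red
  granulation). A single pooled mean sits in the middle of colour
  space, roughly equidistant from every tissue **and** from skin, so no
  threshold separates them. Per-seed prototypes keep each tissue's
  admission decision local. Freezing the prototypes (no update on
  admission) prevents boundary-straddling superpixels from drifting a
  prototype toward the skin tone — with running means we observed
  occasional catastrophic floods into the background — and makes the
  admitted set, hence the wound area, provably non-decreasing in the
  threshold.
* *Threshold 25.* Within-tissue colour scatter under realistic sensor
  noise is a few CIELAB units; the closest tissue-to-skin distance in
  the default palette is ≈ 30. The default sits between the two.

Determinism: fixed SLIC grid initialisation, ordered frontier
processing, no randomness anywhere in the stage.

## Marker calibration and planimetry

A blue 2 cm × 2 cm square (4 cm²) in the wound plane calibrates pixels
to physical units. Pipeline: RGB→HSV (hue in degrees), threshold to the
blue window hue ∈ [200°, 260°], sat ∈ [0.35, 1], val ∈ [0.20, 1];
connected components ≥ 400 px; per component the outer contour is
simplified by Douglas–Peucker to 4 vertices (tolerance from 2% of the
perimeter, relaxed stepwise to 5% before rejecting the candidate), and
the surviving candidate minimising
|quad_area − component_area| / component_area is selected — the shape
closest to its own quadrilateral approximation.

**Corner refinement.** Rasterised contours staircase along tilted
edges, and Douglas–Peucker vertices can sit several pixels inside the
true corners (we measured up to 13% area error at 85° tilt on a 60-px
marker). Each accepted quadrilateral is therefore refined by fitting a
total-least-squares line to the contour points of each edge (trimming
15% at both ends to drop corner rounding) and intersecting adjacent
lines. After refinement the scale error across the tested size/tilt
sweep is below 1%.

**Placement QC.** `proportionality` = min side / max side (≥ 0.8
required); `asymmetry` = max of the relative length mismatches of the
two opposite-side pairs (≤ 0.2 allowed). Asymmetry is exactly zero for
any parallelogram — so in-plane rotation is free — and grows
monotonically with perspective foreshortening, which is the failure
mode that biases the scale. No homography rectification is applied to
an accepted marker: the intended protocol is to re-photograph when the
marker fails QC, not to correct a skewed capture. The scale is
`4 / quad_area_px` (cm²/px) and the wound area is the ROI pixel count
times the scale.

## Tracing-agreement metrics

With reference area R, test area T, overlap O: FNR = 100(R−O)/R,
FPR = 100(T−O)/R, RV = 100(T−R)/R. RV is kept signed with ARV = |RV|
reported alongside. Jaccard and Dice are included for comparability
with the wider segmentation literature. Conventions for edge cases:

* R = 0 and T = 0 (both raters call full epithelialization): the pair
  is **not comparable**; no metrics are emitted.
* R = 0, T > 0: FNR and RV are undefined; the pair is flagged
  *degenerate* and FPR is reported against T (so it stays a bounded
  percentage rather than ∞).
* ARV can be 0 for disjoint tracings of equal area; it measures area
  disagreement only, not boundary placement — FNR/FPR carry that
  information.

**ICC.** `icc_absolute_agreement` implements ICC(2,1) — two-way random
effects, absolute agreement, single measurement — from the mean-squares
decomposition
`(MSR − MSE) / (MSR + (k−1) MSE + k (MSC − MSE)/n)`.
The absolute-agreement variant is chosen because systematic offsets
between measurement methods must count against reliability in a
method-comparison setting. Cancellation in the residual sum of squares
is snapped to zero (relative 1e-12) so identical columns return exactly
1.0; a table with zero between-row variance returns NaN with a warning.
The implementation is cross-checked against `pingouin.intraclass_corr`
in the test suite.

## Tissue classification

Preprocessing mirrors the capture protocol: pixels outside the ROI are
set to black, the ROI bounding box is cropped, the crop is resized to
200 × 200 (bilinear for the image, nearest-neighbour for the label
raster so labels stay integral), and the result is cut into the
non-overlapping 40 × 40 grid of 5 × 5-pixel patches. A patch takes the
majority non-background label of its cell; cells over 50% background
are dropped. Augmentation adds a horizontal flip and a mild zoom
(factor ∈ [0.9, 1.1], resampled back to 5 × 5) per training patch.
The 80/20 split is stratified by tissue class and assigned at the
source-image level (whole scenes on one side) so near-duplicate patches
never leak across the split; a greedy per-class-deficit assignment
keeps each class's train fraction as close to 0.8 as scene granularity
allows, exact to ±1 example when scenes are singletons.

**Model.** At 5 × 5-patch scale, colour is the dominant signal — which
matches the clinical rationale that tissue proportions are judged by
colour. The classifier is correspondingly compact: two valid-padding
3 × 3 convolutions (3→8, 8→16 channels, ReLU) reduce a patch to a
16-vector, followed by the head flatten → dense(32, ReLU) →
dropout(rate 0.3) → dense(softmax). Forward and backward passes are
hand-written in numpy (the whole network is ~3k parameters, far below
the scale where a deep-learning framework earns its complexity), with
He-normal initialisation, plain mini-batch SGD (learning rate 0.05,
batch 64), at most 120 epochs, and early stopping on a held-out 10% of
the training set (patience 10, best-validation weights restored).
Everything — initialisation, shuffles, dropout draws — derives from one
seed, so training is bit-reproducible. Divergence (non-finite loss)
raises immediately with the epoch index.

The size branch of the combined objective J = Σ(Ls + Lt) is a
deterministic thresholding of the measured area into small / medium /
large (defaults 5 and 20 cm², left-closed boundaries, configurable):
there is no plausible training signal for wound size inside a 5 × 5
patch, so learning it would be theatre. Its cross-entropy Ls is still
implemented and tested as a function, and `combined_objective` sums
both terms.

Evaluation reports per-class precision/recall/F1 with supports, the
unweighted macro average, overall accuracy and the raw confusion
matrix; a class absent from the test set yields NaN recall with a
warning rather than a silent 0.

## Synthetic scenes

`scene_synthesis` renders what the capture protocol expects to see: a
wound blob (an ellipse radially perturbed by 4 random harmonics,
amplitude = `boundary_roughness`) filled with concentric tissue zones —
necrotic core, slough ring, granulation rim, band edges placed at
empirical quantiles of the radial coordinate so realised pixel
fractions match the requested `tissue_mix` — on a skin-toned
background, plus the blue square marker under configurable in-plane
rotation and homography. Default palette (RGB): necrotic (40, 30, 30),
slough (200, 180, 90), granulated (180, 60, 60), skin (220, 180, 160),
marker hue 225°; chosen to be separable under the default HSV gates
while remaining in the plausible range for each tissue. Illumination is
a global gain; sensor noise is additive Gaussian (default sd 5 of 255),
clipped to [0, 255].

Two seeds keep concerns separate: `shape_seed` drives geometry (the
boundary harmonics), `seed` drives only sensor noise — so scenes
differing only in `seed` share identical ground-truth masks and marker
corners. `sample_scene_specs` draws varied batches (placement, radii,
roughness, Dirichlet-distributed tissue mixes, marker tilt) from one
batch seed. The marker polygon is rasterised with a half-pixel shift so
the covered pixel count equals the quadrilateral's continuous area
(an axis-aligned square of side s covers exactly s² pixels), making
`true_scale_cm2_per_px = 4 / quad_area` exact rather than biased by a
one-pixel rim. `default_scribble` draws the stroke a clinician would:
across the wound bed along the centre row, inset 5% from the wound
margin, so it crosses all tissue zones without touching skin.

**What the synthetic substrate does not show.** Scenes are flat-lit,
lens-undistorted, specular-free, with near-elliptical wounds and
piecewise-constant tissue colours. Passing the recovery suites
demonstrates that the algorithms are correct and well-calibrated on
their stated model of the input — not that the pipeline meets any
particular accuracy on clinical photographs, where tissue colour
overlaps, wet surfaces glare, and markers bend. The clinical numbers
in the literature come from private datasets and are out of scope here.

## Problem sizes in the test and acceptance runs

Scenes are 256 × 256 (430 × 430 for the marker size/tilt sweep, 512 ×
512 for the resolution-invariance check); segmentation recovery uses 20
scenes; classifier recovery trains on 24 scenes and tests on 6 held-out
scenes across 5 seeds with up to 250 patches per scene; ICC recovery
uses 500 simulated wounds × 3 raters. These sizes give stable medians
while keeping the full suite fast on a single CPU.

## Known limitations

* The scribble must cross every tissue zone it should capture; a
  scribble confined to one zone segments only colour-similar regions.
* Marker scale is taken from the raw quadrilateral; captures that pass
  QC with mild perspective (asymmetry just under 0.2) carry a
  corresponding small area bias rather than being rectified.
* The classifier is colour-driven by construction; it will confound
  tissues whose colours genuinely overlap (e.g. dark granulation vs
  eschar under poor lighting).
* On synthetic scenes all three tissue classes are classified at
  near-ceiling F1, so which class ranks "easiest" is decided by a
  handful of zone-boundary patches and varies with the seed batch;
  the clinical observation that dark necrotic tissue is the most
  reliably identified class transfers to this substrate only as a
  weak tendency.
* Hue wraparound in the HSV gate is unsupported (irrelevant for blue).
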