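# Methods

This note documents the models, parameter choices and numerical
conventions behind `complexion`, and what the synthetic-data experiments
do and do not establish.

## Color model

All analysis happens in CIELAB.  Camera RGB (8-bit, scaled to [0, 1]) is
mapped through CIEXYZ with the D65 primaries matrix

```
[X Y Z]^T = 100 · M · [R G B]^T,   M = [[0.4124 0.3576 0.1805],
                                        [0.2126 0.7152 0.0722],
                                        [0.0193 0.1192 0.9505]]
```

and then to L\*a\*b\* with the standard piecewise companding
f(t) = t^(1/3) for t > (6/29)³, linear otherwise, against the reference
white (Xn, Yn, Zn) = (95.047, 100, 108.883).  The matrix is applied to
RGB **as is** (`assume_linear_rgb=True`): the acquisition model treats
camera output as linear, and no sRGB gamma decoding is performed unless
requested.  Luminance (L\*) and chromaticity (a\*, b\*) are deliberately
orthogonal axes of the analysis: bases live in (a\*, b\*), gloss in L\*.

Skin detection uses log-opponent chromaticity with ℓ(x) = log(x + 1):
I = (ℓR + ℓG + ℓB)/3, Rg = ℓR − ℓG, By = ℓB − (ℓR + ℓG)/2.  The +1
offset keeps the channels finite at zero; the exact LO dialect is this
module's own convention.

## Skin detection

Two branches, both fit on the input image alone (no training corpus):

* **Histogram branch** — a `histogram_bins`² (default 64²) histogram over
  (I, By), Gaussian-smoothed with `smoothing_sigma` = 2 bins, thresholded
  at `density_threshold` = 0.1 *relative to the peak*; surviving bins are
  grouped into connected components (color modes).
* **Mixture branch** — a diagonal-covariance Gaussian mixture with
  `gmm_components` = 5 over (I, Rg, By).  Five components because a morbid
  face carries at least four color populations (basic skin, morbid skin,
  background, lips/artifacts); intensity is included because log-opponent
  chroma is noise-dominated for dark pixels, and without it dark backdrop
  noise bleeds into skin modes.

A mode (histogram component or mixture component) is classified as
**background** when its pixels are over-represented, relative to chance,
in a thin frame (3% of the short side, minimum 2 px) around the image
border.  This encodes the frontal-portrait prior: the backdrop always
touches the frame, facial skin never does.  It replaces any rule based on
comparing mode densities, which is not identifiable — a tight backdrop can
out-peak diffuse skin, and a skin color split across two modes defeats
any single-mode selection.  All non-background modes are skin; the two
branches are fused with OR by default (detection-favoring; AND available).
The mouth region is removed as a rectangle (lip chromaticity overlaps
skin, so color cannot separate it; boxes come from fixture ground truth
or an external detector).  Finally pixels in the darkest `low_tail` and
brightest `high_tail` L\*-quantiles (1%/1%) are dropped; this is what
removes moles, hair and specular glints.

On the default synthetic cohort the detector reaches median IoU ≈ 0.99
(minimum ≈ 0.93) against ground-truth masks.

## Fuzzy c-means and the two-level base construction

FCM is the standard alternating scheme (fuzzifier m = 2, tolerance 1e-5 on
the objective, ≤ 300 iterations, seeded random membership initialization);
centers are returned lexicographically sorted so runs are deterministic
and order-independent.  A point coincident with a center splits its
membership equally among the coincident centers.

A class's chromaticity base is built in two clustering levels on (a\*, b\*)
only (luminance is added later as sub-bins):

1. per image, FCM with c = 2 gives a dominant and subdominant
   chromaticity, ordered by hard member count;
2. per class, both centers of every image are pooled (2N points) and
   clustered again with c = 2; the cluster with the greater number of
   members becomes the base.

**Member-count convention.**  Because each image contributes exactly one
point to each side of the dichotomy, hard counts tie at N:N whenever the
second-level split aligns with the dominant/subdominant dichotomy — the
generic case.  `largest_cluster` therefore breaks hard-count ties by the
larger *fuzzy cardinality* (column sum of the membership matrix), which
favors the tighter cluster; the tighter cluster is the one shared across
subjects (the class color), while basic skin tones scatter.  Remaining
ties fall back to the lexicographically first center.  This convention is
what makes the two-level construction recover a class color that is the
minor pixel cluster in every single image.

The single-level baseline (per-image dominant centers averaged) is kept
for comparison.  Under the minor-cluster regime (class color at 35% of
pixels, basic tones scattered with σ = 6) the two-level base lands within
a median ΔE_ab ≈ 1.4 of the planted chromaticity while the baseline
drifts ≈ 15 units to basic skin.  Note that the corresponding *peak-bin
classification* accuracies do not separate the two methods on synthetic
cohorts: the baseline's bias moves the decision boundaries together with
the mild subjects' pixel mass, so its classification error largely
cancels.  The base-error metric is the clean readout of the mechanism.

## Complexion histogram

Pixel assignment is two-stage: nearest base by Euclidean distance in
(a\*, b\*), then a luminance sub-bin by L\* (clamped to the binning range,
so normalization stays exact).  Layouts:

| layout | range | interval | aggregate bins | length |
|---|---|---|---|---|
| preliminary | 0–100 | 10 | no | 40 |
| refined (default) | 25–95 | 14 | yes | 24 |
| sweep endpoints | 25–95 | 35 / 1 | yes | 12 / 284 |

The refined range follows from the denoising step: after tail removal,
extreme luminance is absent, so bins outside [25, 95] would be dead
weight.  Normalized histograms have aggregate bins summing to 1 and
sub-bins summing to 1; they are proportions and are *not* rescaled per
dimension before classification (rescaling would destroy the
color-proportion semantics).

Five facial regions are segmented from the skin mask: morphological
closing (square element, ~3% of bounding-box height, min 3), bounding
rectangle, fixed proportional split — forehead rows [0, 0.33), mid rows
[0.33, 0.75) with left cheek cols [0, 0.35), nose [0.35, 0.65), right
cheek [0.65, 1), jaw rows [0.75, 1) — each block intersected with the
original mask.  The split fractions are this package's choice; only the
mechanism (close → bounding box → proportional split) is prescribed.
Regional histograms are scaled by weights (0.3, 0.3, 0.1, 0.1, 0.2) and
concatenated to 120 dimensions; with weights summing to 1 the result has
unit total aggregate mass, so no renormalization is applied.

## Recognition

One-vs-one RBF-SVM (scikit-learn `SVC`), 15 pairwise models for six
classes.  (C, γ) are selected by stratified inner cross-validation on the
training set over powers of two, C ∈ 2⁻⁸..2¹⁵ and γ ∈ 2⁻⁸..2⁸ (step 1 by
default); ties prefer the smaller C, then the smaller γ.  Voting ties at
prediction time resolve through the underlying decision values with labels
encoded in canonical class order — a slightly different convention from a
pure canonical-order rule, noted here for exactness.

Leave-one-out evaluation is leakage-free by construction: for each fold
the four bases are rebuilt from the training subjects only and **all**
features are re-extracted under those bases before training.  Per-image
pixel-level FCM depends only on that image and is cached across folds.
An optimistic protocol (`paper_protocol=True`), in which a fold counts as
correct if *any* grid point classifies the held-out subject correctly, is
implemented for comparison but never used for reported numbers.
Metrics: per-class one-vs-all precision/recall, micro (sample-pooled) and
macro (class-averaged) aggregates, F with β = 1; empty denominators give 0
with a warning.

## Degree ranking

*Color degree*: the subject's own-base proportion in the 4-bin
chromaticity histogram, min-max normalized within the predicted class.
White and black carry no chromaticity base, hence no color degree.
*Gloss degree*: score = Σ wⱼ hⱼ over the K-bin luminance histogram with
wⱼ = (bin-center L\*)/100 — the minimal weighting satisfying
"higher luminance, larger weight" (any non-decreasing weights are
accepted) — min-max normalized over the whole cohort.  A constant group
maps to 0.5.  For region-fused features the region blocks are summed into
one whole-face histogram first.

## Synthetic faces: what they emulate, and what they do not

A fixture is an ellipse (≈ 55% of a 96×96 frame) of skin pixels drawn in
Lab and rendered through the analytic Lab→RGB inverse (generation fails
if > 1% of samples leave the RGB gamut), on a dark bluish backdrop, with
a lip ellipse of skin-overlapping chromaticity inside the mouth box, plus
near-black moles and hair strands.  Skin chromaticity is a two-component
mixture: the class color (normal (14,16), cyan (0,4), red (26,16),
yellow (12,32); pairwise ≥ 10 ΔE_ab apart) with weight `minor_fraction`
(default 0.65), and the subject's basic tone, drawn per subject around
(14, 16) (σ = 3 by default) and clamped to a gamut-safe box.  White and
black reuse the normal chromaticity and differ only in mean L\*
(65 / 42 vs 56–62 for the chromatic classes, pixel σ = 6).  Degree
gradients sweep `minor_fraction` over [0.35, 0.9] and mean L\* over ±4
linearly across a class's subjects, so true rankings are known.

Deliberate omissions: facial geometry and landmarks, texture, specular
reflection, illumination gradients, camera gamma and white-balance error,
and ethnic-scale skin-tone diversity.  Passing tests therefore show that
the pipeline recovers planted structure under controlled mixture noise —
not that it handles real clinical photographs; the original study's
accuracies on clinical data are not reproducible without that data.
Two structural facts about the generator matter when reading results:
the normal class's color-degree gradient is unidentifiable by
construction (its class color *is* basic skin), so color-degree recovery
is scored on cyan/red/yellow; and the white class is generated with low
chroma (pale skin is desaturated), which keeps its bright pixels inside
the RGB gamut.

## Problem sizes and reproducibility

Reported experiments use: the 122-subject cohort with the study's class
counts (24/15/18/24/21/20) for recognition; 20 images/class × 20
replicates for base recovery in the test suite (8 × 12 in the acceptance
script); 12 subjects/class gradient cohorts for degree recovery; a
power-of-four subgrid of the (C, γ) search range with 3 inner folds for
grid search in experiments (the full step-1 grid is the library default).
Every random draw descends from a single master seed via seed sequences;
re-running any experiment with the same seed is bit-reproducible.

## Known limitations

* The skin detector's background rule assumes the subject does not touch
  the image border; tightly cropped faces would need the AND fusion rule
  or external masks.
* Mouth boxes are inputs (ground truth or an external detector); no
  detector is bundled.
* The degree rankings are unsupervised orderings; they are validated
  against planted synthetic gradients, not against expert judgments.
* Base construction assumes each class's morbid chromaticity is shared
  across subjects while basic skin varies; if the converse held, the
  fuzzy-cardinality tie-break would favor the wrong cluster.
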