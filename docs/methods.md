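# Methods

## The measurement model

A detached rice panicle imaged on black light-absorbing fabric is a
bright object on a near-black background. The package estimates the grain
number per panicle (GN) from pixel statistics of the binarised panicle,
not from instance segmentation. The premise: each grain contributes a
roughly constant number of foreground pixels, so the covered area — and,
more weakly, skeleton length and boundary length — is close to linear in
the grain count. Grain-to-grain contact, the failure mode of
component-based counters, perturbs the covered area only at the contact
zones, which is why a regression on coverage stays accurate on clustered
panicles.

The pipeline only applies to panicles whose primary branches have been
manually spread (Shape B) or detached (Shape C); naturally tangled
panicles (Shape A) are out of scope — flattened 2-D imaging cannot see
into a 3-D tangle, and no 2-D feature fixes that.

### Preprocessing

1. Grayscale by ITU-R 601 luma (0.299 R + 0.587 G + 0.114 B), rounded.
2. Otsu threshold over levels 0–255: the threshold maximises between-class
   variance of the histogram (lowest level on ties); foreground is
   `gray > t`. A constant image is rejected (`degenerate histogram`). An
   `invert` flag supports bright-background setups.
3. Denoising: connected components (8-connected by default, configurable)
   with area `>= denoise_min_area` are kept; default 1000 px. At scanner
   resolution fabric speckle is < 100 px and a panicle is > 100 000 px,
   so the boundary case is far from both populations; the inclusive
   comparison is a determinism convention.
4. Stem removal: the denoised mask is eroded `erode_iterations` times and
   dilated `dilate_iterations` times (default 3 each) with a disk
   structuring element in a `disk_diameter`² window (default 5×5 — the
   21-pixel disc, corners excluded, i.e. pixels within radius + 0.5 of
   the centre). This opening erases structures thinner than the
   accumulated element width (~13 px): the stem (5–10 px), but not grains
   (30–50 px). The residual (denoised AND NOT opened) is size-filtered at
   `stem_min_area` (default 200 px) to drop grain-boundary shavings; what
   survives is the stem mask, which is subtracted as a set difference
   (masks stay binary throughout). By construction the stem-free mask and
   stem mask are disjoint and both subsets of the denoised mask.
5. The stem-free mask gates the original RGB image for inspection.

All iteration semantics are "apply the same element n times"; erosion and
dilation treat out-of-image pixels as background.

### Features

With `S_im = H × W` the size of the original image and `N_x` the
foreground pixel count of the corresponding binary image:

    CD = N_cd / S_im    (coverage: the stem-free mask itself)
    Sk = N_sk / S_im    (skeleton: topology-preserving thinning)
    Co = N_co / S_im    (contour: foreground pixels with a background
                         4-neighbour; image border counts as background)

Counts are taken per primary branch (connected component) and summed.
Because 8-connected components are Chebyshev-separated and both thinning
and the boundary test are 3×3-local, the per-branch sum equals the
whole-mask count; the code asserts this and keeps the per-branch table
for diagnostics. Thinning uses `skimage.morphology.thin`, which matches
a reference Zhang–Suen implementation on the test fixtures; skeleton
counts are treated as implementation-defined up to endpoint handling, and
only subset/count properties are relied on.

Each feature is min–max normalised with training-set extremes
(`CD′ = (CD − CD_min)/(CD_max − CD_min)`, same for Sk′, Co′). Extremes
are fitted per group (subspecies × device × shape), matching the
per-group counting models; a degenerate range (max = min) refuses to fit.
Validation values may fall outside [0, 1] and are logged, not clamped.

### Counting models

Ordinary least squares (numpy `lstsq`, rank-checked) of grain counts on
any subset of {CD′, Sk′, Co′} plus an intercept. The univariate CD′
model is the recommended default; the multivariate model adds little on
clean data. Predictions are rounded half-away-from-zero; the reported
count is clamped at 0, but R²/RMSE are computed on raw predictions so
that clamping cannot flatter the fit. Accuracy is the mean over images of
`(1 − |pred − truth|/truth) × 100` — this metric is isolated in one
function (`evaluate_model`) because other definitions (exact-match rate)
exist in the literature. R² is NaN when the truth set has zero variance.

`printed_models()` carries the eight published multivariate models
verbatim (coefficients, intercepts, train/validation R²/RMSE). Their
normalisation extremes were never published, so they serve as worked
examples and cross-device reference points rather than as deployable
predictors.

### Baselines

`count_components` (the naive counter) and `erosion_split_count`
(erode-then-count). Both undercount touching grains: erosion cannot
separate grains fused over a wide front, and a component eroded away
entirely vanishes from the count. They exist to quantify that failure.

## The synthetic generator

`SyntheticSpec` defaults describe a full-resolution scanner frame:
2480×3507 px, grains 30–50 px wide (sampled i.i.d. per grain) with
aspect ratio 3.5 (Indica, "long and slender") or 2.2 (Japonica) ±10%,
stems 5–10 px wide (one width per image), fabric speckles < 100 px,
background level 12 (sd 3), grain levels 140–230. Counts default to
60–220 per image in dataset generation, ~14 grains per branch.

Layout: branches are packed left-to-right into horizontal rows whose
pitch guarantees rows cannot interact; each branch has a gently waving
rachis (amplitude 0.25 grain-widths, wavelength 18 grain-widths), with
grains placed along it at alternating tilts of 20–50°. Consecutive
grains either keep an exact-footprint gap (disjointness guaranteed by
x-extent bookkeeping) or, with probability `overlap_prob` (default 0.5),
are pulled together until they demonstrably touch (pixel-verified). So
`overlap_prob=0` yields pairwise-disjoint grains — component counting is
then exact, a calibration point for the baselines — and `overlap_prob=1`
yields one connected blob per branch. If the frame cannot hold the
requested grains, rendering fails with `placement overflow` rather than
silently violating the overlap contract.

Shape B draws a main stem through the branch bases plus a bare peduncle
tail (0.2–0.7 of the frame height); Shape C scatters 1–3 detached stem
segments in free rows, since cut stems typically lie in the scanned frame
too. Ground truth: `grain_mask` (grains only), `stem_mask` (stem
structures), `rachis_mask` (visible branch axes — part of the branch, not
the stem), per-grain ellipse parameters, and the exact count. The rachis
is rendered at stem width; the preprocessing opening removes it together
with the stem, which is intended — visible rachis between grains is a
thin structure by construction.

`at_scale(s)` shrinks every length by `s` and every area by `s²`, and
`PreprocessConfig.at_scale` does the same for the area filters while
scaling opening iterations linearly (min 1, the 5×5 disk kept as the
smallest useful element). Experiments in the tests and the acceptance
script run at quarter scale (620×877) so a 260-image experiment takes
about two minutes on one CPU; the geometry (grain/stem/speckle pixel
ratios) is preserved by construction.

What the generator does **not** emulate: illumination gradients and
specular highlights, awns as a systematic confounder (available as an
option, off by default), grain-size correlation within a panicle beyond
the shared sampling range, out-of-focus blur, and real branch
architecture (grains sit directly on the rachis rather than on
pedicels). Passing tests therefore demonstrate the pipeline's arithmetic
and its robustness to touching grains, speckle and stems — not
performance on any particular real scanner or cultivar, which requires
refitting the regression on real counted panicles.

## Numerical and design choices

- Otsu is computed by vectorised cumulative moments; the exhaustive
  256-level search serves as the test oracle. Ties take the lowest level.
- Component connectivity defaults to 8 (diagonal touching merges);
  4-connectivity is available everywhere.
- The area filter keeps components **at** the threshold (>=).
- Rounding of predictions: half away from zero, witnessed in a test
  (0.5 → 1); banker's rounding would bias even counts.
- Normalisation extremes come from the training split only; applying a
  model to images outside the training range is flagged in logs.
- Problem sizes: acceptance-level experiments use a 160/100 split at
  quarter scale, matching the published train/validation proportions per
  group (160/100 scanner Shape B) at a frame size that keeps a full run
  in minutes; unit tests use 64×64 masks and few-grain renders.

## Known limitations

- The published models cannot be applied to new images without their
  (unpublished) normalisation extremes; they are kept as printed.
- The stem isolator assumes stem width < opening width < grain width; at
  aggressive down-scaling (below ~0.15) grains approach the element size
  and the margin collapses.
- Accuracy depends on grain-size variance averaging out across a panicle;
  panicles with few grains (< ~30) carry proportionally larger error.
- `erosion_split_count` is deliberately naive (no distance-transform
  markers); it represents the baseline it quantifies, not the state of
  the art in touching-kernel separation.
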