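# Methods

This note records the algorithmic conventions the package commits to, the
reasoning behind the genuinely open design choices, what the synthetic data
does and does not emulate, and the known limitations.

## Image model

All images enter as 2-D grayscale grids of float intensities in [0, 1],
row-major, origin top-left, 0-based (row, column) indexing. Multi-channel
inputs are collapsed with ITU-R BT.709 luminance weights
(0.2125 R + 0.7154 G + 0.0721 B), the scientific-imaging convention; alpha
channels are dropped. Resizing is plain bilinear interpolation with
pixel-center alignment and no anti-aliasing prefilter — simple, exactly
reproducible, and adequate at the modest downscale factors these pipelines
use (e.g. 1280×720 → 352×240). Extractors that need discrete intensity
levels (LBP, GLCM) quantize internally: LBP rounds to 8-bit levels, GLCM
bins [0, 1] uniformly into `levels` bins. Corrupt files are logged and
skipped rather than aborting the batch; a run only fails if *no* image
decodes.

## HOG

Gradients are centered differences with the (−1, 0, +1) kernel (one-sided
at borders); orientation is folded to [0°, 180°) unless
`signed_gradients=True`. Cell histograms use magnitude-weighted *bilinear*
voting between the two orientation bins whose centers bracket the pixel's
orientation (bin centers at (k + ½)·width, circular wrap), so each cell's
histogram mass equals the sum of its pixels' gradient magnitudes exactly —
a property the tests assert. Hard assignment would be cheaper but is badly
behaved at bin edges.

Blocks of `block_size`×`block_size` cells step by `block_stride` cells;
incomplete trailing cells are discarded (floor division). Each block's
concatenated histograms are normalized with an ε = 1e−12 guard; the default
norm is L2-Hys (L2, clip at 0.2, renormalize), with plain L2 available.
The defaults — 9 bins, 8×8-pixel cells, 3×3-cell blocks, stride 1 — are the
standard configuration for this descriptor family and give
⌊240/8 − 3⌋+1 = 28 by ⌊352/8 − 3⌋+1 = 42 block positions, hence
28·42·3²·9 = 95,256 features for a 352×240 image. A constant image yields
the all-zero vector (the ε guard never promotes empty blocks).

## LBP

For each pixel, P = 8 neighbors are sampled on a circle of radius R = 1
starting at angle 0 along +columns and proceeding counter-clockwise;
off-lattice positions are bilinearly interpolated (nearest-neighbor
sampling would break rotation invariance) and borders use edge-replicated
padding, so the output is exactly one code per pixel (n·m features). Bit k
is set iff neighbor ≥ center: ties count as 1, which pins the
constant-image code at all-ones. The ≥ comparison tolerates 1e−7 absolute
error on the 0–255 quantized scale so that bilinear weights summing to 1
only up to float rounding cannot flip a tie bit.

Variants are post-hoc code maps, applied via a lookup table over all 2^P
raw codes: `rotation_invariant` takes the minimum over cyclic bit
rotations, `uniform` maps codes with more than two 0/1 transitions to the
single label P+1 and uniform codes to their popcount, and
`rotation_invariant_uniform` composes the two. The default output is the
flattened code image, not a histogram — all variants therefore share the
n·m output length (84,480 at 352×240).

## GLCM / Haralick

Offsets use matrix coordinates with 90° pointing up: 0° → (0, +d),
45° → (−d, +d), 90° → (−d, 0), 135° → (−d, −d). This is stated explicitly
because libraries disagree (some measure the angle with +row downward; the
test suite maps conventions when cross-checking against scikit-image).
Pairs are counted ordered, symmetrized by adding the transpose, and
normalized per (distance, angle) slice. Six properties are computed per
slice — contrast ΣP(i,j)(i−j)², dissimilarity ΣP|i−j|, homogeneity
ΣP/(1+(i−j)²), ASM ΣP², energy √ASM, and correlation via marginal
means/SDs. Correlation of a zero-variance slice (constant image) is
*defined* as 1 so degenerate inputs stay finite. The feature output is the
property vector (property-major, then distance, then angle); emitting raw
256² matrices per image would dwarf every other descriptor, but the raw
array remains available through `compute_glcm`.

## Hessian eigenvalue maps

The image is smoothed by a Gaussian of scale σ (reflect boundary, kernel
truncated at 4σ) and second derivatives are taken as finite differences of
the smoothed image (smooth-then-differentiate) — equivalent to
Gaussian-derivative kernels at these scales and much easier to verify
against finite-difference oracles. Eigenvalues come from the symmetric 2×2
closed form λ = (Hrr+Hcc)/2 ± √(((Hrr−Hcc)/2)² + Hrc²), which matches a
general eigensolver to 1e−12 and conserves the trace exactly. The default
output is the two eigenvalue maps (λ₁ then λ₂, 2nm features) because the
eigenvalues, unlike the raw components, are rotation-invariant topology
descriptors; component maps (3nm) are available via `output="components"`.

## Canny

Gaussian smoothing (reflect), centered-difference gradients, non-maximum
suppression with the orientation quantized to four sectors and a ≥
comparison against the two discrete neighbors along the sector (the tie
rule keeps deterministic one-pixel ridges on plateaus), then hysteresis:
strong pixels (≥ high) seed edges, weak survivors (≥ low) are kept iff
8-connected to a seed. Thresholds default to 0.1/0.2 on the
gradient-magnitude scale of a [0, 1] image; `use_quantiles=True` reads them
as quantiles of the nonzero magnitudes, which travels better across image
types. Raising the low threshold provably never adds edge pixels, and every
emitted component contains a strong seed — both are asserted in tests.

## Post-processing

Normalization is a per-column z-score with the *population* SD; columns
with zero variance become all-zero rather than NaN. This directly addresses
the motivating problem: descriptor families live on wildly different value
scales, and distance-based classifiers would otherwise be dominated by
whichever family has the largest units.

PCA mean-centers only (scaling is normalization's job; the two remain
separate, composable steps, applied normalize → PCA when both are enabled)
and keeps `min(n_rows, n_cols)` components by default, computed by a thin
SVD so the tall-and-wide regime (hundreds of rows, ~10⁵ columns) remains
tractable. Component signs are fixed so each axis's largest-magnitude
loading is positive; without this, serialized outputs would differ between
runs on sign-ambiguous axes. Values are kept at full precision in memory —
the `decimals` setting rounds (half-even) only at serialization time, so
PCA and classification never see display rounding.

## Orchestration and determinism

One "processor" task per image file (load → optional resize → all selected
extractors) is a pure function of the file bytes and the configuration, so
tasks may run on any worker. Results are keyed by image id and assembled in
lexicographic order regardless of completion order; consequently every
output format is byte-identical for any `njob`, which the suite checks
including the xlsx writer (whose embedded timestamps are pinned for this
purpose). SQL output is an embedded SQLite file — the most portable reading
of a "SQL" export. Recommended `njob` is at most the number of physical
cores.

## Evaluation protocol

Stratified k-fold (k = 10 default) with per-fold class counts differing by
at most one within each class; all randomness (fold shuffling, stochastic
classifiers) derives from one user seed. Accuracy is the *pooled* fraction
of correctly predicted images across held-out folds (not the mean of
per-fold accuracies; the two differ only under unequal fold sizes, and
pooling is the literal "percentage of correctly predicted images").
mAcc is the maximum over the classifier panel. The panel holds six members
— SVM, nearest neighbor, decision tree, Gaussian naive Bayes, logistic
regression, random forest — with scikit-learn default hyperparameters. A
stratified 70/30 holdout path is provided alongside CV, with pooled
confusion counts, sensitivity and specificity per classifier.

## Synthetic data

The fixture generator produces analytic patterns (constant, ramp, step
edge, 8×8 checkerboard, seeded Gaussian noise) for the extractors' corner
cases, and a two-class texture set: seeded white noise smoothed by a
strongly anisotropic Gaussian (σ = 0.5 along one axis, 6 along the other)
at two orientations, min-max rescaled to [0, 1]. The classes differ in
orientation and co-occurrence structure — precisely what HOG and GLCM
measure — so the end-to-end study (84 images, 42 per class, 256×256,
HOG+GLCM → normalize → PCA → six-classifier 10-fold CV) reaches mAcc ≥ 0.95
by construction, with perfect holdout sensitivity and specificity for the
best classifier. Everything is deterministic under the seed.

What this does *not* show: synthetic oriented noise has none of the
illumination variation, compression artifacts, anatomy or class overlap of
real clinical or texture-database imagery, so the end-to-end numbers
validate the *pipeline mechanics and protocol*, not expected accuracy on
real data. Problem sizes in the test suite (84 images of 256×256; 574×2000
matrices for the default-component check) were chosen as the smallest
scales that exercise every code path meaningfully.

## Known limitations

- Binary classification only; no multi-class protocol, ROC/AUC, or
  hyperparameter search.
- No multi-scale descriptors (HOG pyramids, Frangi vesselness, LBP
  histograms at multiple radii).
- The per-pixel LBP/HEM/CAN outputs assume a common image size across the
  collection (enforce via `target_size`); merging rejects mismatched
  lengths rather than padding.
- DICOM and video inputs are out of scope; frames must be exported to
  ordinary raster files first.
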