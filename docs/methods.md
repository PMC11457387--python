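# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic fixtures do and do not
emulate, and the numerical conventions that matter when reproducing results.

## Problem setting and class order

Patches of hematoxylin–eosin (H&E) slides are classified into six classes
with a fixed global order: 0 artifact-free tissue, 1 blood, 2 blur, 3 air
bubbles, 4 damaged tissue, 5 folded tissue. The artifact-free class is the
*positive* class everywhere (sensitivity, thresholds, binary labels): the
costly error in quality control is discarding diagnostically relevant
tissue, so the pipeline is tuned to retain it. In binary experts the label
convention is 1 = artifact-free, 0 = artifact, and the expert's softmax
index 0 is therefore the artifact probability.

## Pre-processing

* **Foreground.** RGB thumbnails (default downsample d = 32) are converted
  to HSV and Otsu-thresholded on the value channel; tissue is the side
  *below* the threshold (darker than the white slide background). The
  polarity is a package convention; d = 32 trades resolution for speed and
  the mask is re-interpolated to patch cells by exact area fractions, so the
  grid does not inherit the thumbnail quantization.
* **Grid.** Uniform, non-overlapping stride s = patch size (default 224).
  Cells not fully inside the slide are dropped (no padding). Cells with
  tissue coverage below `min_tissue` (default 0.1) are skipped; the default
  only removes near-empty border cells, matching the intent that essentially
  every foreground patch is evaluated.
* **Labels.** A patch takes artifact class k when its window overlaps the
  class-k annotation mask on at least 70% of its area (inclusive at exactly
  0.70). If two classes both clear the threshold the *lowest* class code
  wins; annotation overlaps are rare and the tie-break only needs to be
  deterministic.

## Classifiers and training recipe

A classifier is a backbone φ plus a three-layer fully connected head
(embed → 512 → 128 → k by default) with dropout 0.2 between the FC layers
and a softmax output. Inputs are standardized with the ImageNet channel
mean/std.

Training uses cross-entropy, SGD with momentum 0.9 from learning rate 0.01,
reduce-on-plateau scheduling (factor 0.1, patience 5 — the plateau details
are package defaults), batch size 128, early stopping with patience 20 on
validation loss, and the checkpoint at minimum validation loss. Geometric
augmentation (rotations restricted to multiples of 90° and horizontal /
vertical flips, avoiding interpolation choices) is redrawn every epoch.
Training is a pure function of the seed on one device.

Three backbones are registered:

* `tiny_test_cnn` — the runnable backbone: a 4×4 average-pool stem followed
  by three 3×3 conv blocks (8, 16, 32 channels, max-pool between, global
  average pool; embedding width 32), implemented on the package's own numpy
  engine (im2col convolution, inverted dropout, momentum SGD). It trains on
  a CPU in seconds to minutes, which is all the linearly separable fixtures
  require.
* `mobilenet_v3_large`, `vit_tiny` — per-layer parameter tables of the
  published architectures, used for exact parameter accounting. The
  MobileNetV3-Large feature extractor has 2,971,952 trainable parameters;
  with the 960→512→128→2 head (557,954) a binary expert totals 3,529,906
  (3.53 M) and a five-expert mixture 17.65 M. ViT-Tiny/16's headless encoder
  has 5,524,416 parameters; its printed sizes are consistent with a
  *single-linear* head (5.53 M at six classes, 27.62 M for five binary
  models), not with the three-layer head arithmetic — both readings are kept
  and neither is forced. These backbones refuse inference because no
  pretrained weights ship with the package.

## Mixture of experts and thresholding

Five binary experts (one per artifact) are fused by the maximum of their
artifact probabilities: `p_artifact = max_i P_i`, `p_afree = 1 − max_i P_i`
(equivalently the minimum of the experts' artifact-free probabilities — an
exact identity, asserted in tests). The patch is artifact-free iff
`p_afree ≥ t_s` (inclusive); otherwise it takes the class code of the
expert attaining the maximum, ties to the lowest code. The fused
distribution retains no other class information, so the maximizing expert
is the only consistent choice for the artifact label.

`t_s` is learned on validation scores. Candidate thresholds are the unique
observed scores plus 0 (the same discretization a ROC sweep uses). Two
criteria ship: the default **sensitivity floor** (target 0.98) returns the
largest candidate whose TPR on the selection set still meets the target —
maximal specificity subject to the floor, always attainable because t = 0
gives TPR 1 — and **max-F1** returns the F1-maximizing candidate (ties to
the larger threshold). The selection reports achieved TPR/FPR and the
trapezoidal AUC.

The multiclass rule is analogous: artifact-free iff `p_0 ≥ t_s`, otherwise
the argmax over the five artifact probabilities, even when `p_0` is the
overall maximum.

## Post-processing

* **Segmentation map.** One cell per grid position (`grid[y/s, x/s] = k`),
  i.e. the stride-downscaled reading of matrix filling; a full-resolution
  rendering is only a display concern. Cells never predicted (outside
  foreground) hold the sentinel −1, distinguishing "not evaluated" from
  artifact-free; duplicates are last-write-wins with a warning.
* **QC report.** `Per_k = N_k / N_tot · 100%` and `ρ = N_0 / N_tot` over
  *evaluated* cells only (background cells are excluded from `N_tot`).
  Decision: accept iff `ρ ≥ τ`; τ defaults to 0.5 (an explicitly tunable
  operating point — no canonical value exists). An empty foreground yields
  ρ = 0 and discard, with a warning.
* **RoI mask.** Binarize (1 iff class 0), then morphological closing with a
  square structuring element of side 2r + 1 (default radius 1 cell) to fill
  small artifact holes; out-of-grid cells never carve the result
  (`mode="ignore"`). Radius 0 is pure binarization.
* **Refined slide.** The mask is upsampled by nearest neighbor to level-0
  size and multiplied into the image. Retained pixels are bit-identical to
  the input; masked-out pixels are 0 by default (the algebra of the
  Hadamard product) or 255 for tools that expect white backgrounds.

## Synthetic fixtures

The generators emulate just enough structure for every stage to be
testable: class 0 is a pink/purple field with nuclei-like ellipses; blood
is red-dominant blobs; blur is literally a low-pass rendering of the class-0
texture for the same seed, slightly washed out; air bubbles are a bright
ring with a dark rim on a pale interior; damage is desaturated, fragmented
texture; folds are globally darkened tissue with a dark high-contrast band.
The eosin palette is deliberately dark enough that the HSV value channel is
bimodal against the white background — with a brighter palette Otsu locks
onto the nuclei instead of the tissue and foreground extraction degenerates.
Slides are a centered tissue rectangle covering `tissue_fraction` of a white
canvas with artifact rectangles painted over it; ground-truth masks are
exactly those rectangles intersected with tissue (overlaps allowed; a
rasterized single-label view resolves them by highest class code).

Every generator is a pure function of its arguments including the seed.

What they do *not* emulate: stain variation between laboratories, scanner
optics, pen markings, tissue morphology, or any within-class diversity
beyond seeded noise. Passing tests therefore demonstrate that the
*machinery* (labeling rules, fusion, thresholds, reconstruction, reporting)
is correct, not that any particular backbone generalizes to real H&E data.

Oracle experts — test doubles that read the ground truth and emit artifact
probability 1 inside their class's regions under the same 70% rule — close
the loop: with them the pipeline's RoI mask must reproduce the
ground-truth rasterization exactly (dice = 1 at closing radius 0). The
noisy variant flips a fraction (5% in tests) of patch-level labels to a
random other class, modeling uniformly corrupted experts at the bundle
level.

## Numerical conventions and degenerate inputs

* Coordinates are (x, y) = (column, row), 0-based, half-open windows.
* Argmax ties always break toward the lowest index / class code.
* Threshold comparisons (`p_afree ≥ t_s`, overlap ≥ 0.70, `ρ ≥ τ`,
  score ≥ t in ROC sweeps) are inclusive.
* Dice of two empty masks is 1 (no-disagreement convention).
* Metrics with empty denominators are reported as NaN rather than raised.
* Softmax is computed with max-subtraction; probability rows sum to 1
  within 1e-6 end to end.

## Problem sizes used in the test suite

Tests run entirely on synthetic data at desk scale: slides up to
2240×2240 px (10×10 patch cells), training sets up to 400 patches/class for
the trainability check, and 10,000 random quintuples for the fusion oracle.
These sizes make the full suite complete in a few minutes on one CPU while
still exercising every code path; none of the checks become more informative
at larger n because the properties verified (exact recovery, conservation,
monotonicity, closed forms) are size-independent.

## Known limitations

* No pretrained large backbones: MobileNetV3-Large / ViT-Tiny are
  parameter-accounting references only, and the runnable `tiny_test_cnn` is
  far below state-of-the-art capacity for real histology.
* Slides are read fully into memory (fine for desk-scale TIFF/PNG; no
  pyramidal lazy reader).
* No color normalization or stain augmentation; annotation input is
  mask-based only (polygons must be rasterized upstream).
* The usability threshold τ and the RoI closing radius are operating-point
  choices the user must own; defaults are sensible, not validated against
  clinical judgment.
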