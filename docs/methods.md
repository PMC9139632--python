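# Methods

## Problem setting and model

The package targets detection and segmentation of brain metastases on
contrast-enhanced T1 MRI volumes resampled to a common grid
(0.195 × 0.195 mm in-plane, 1 mm slices in the clinical protocol; thick
slices are linearly resampled). Metastases are hyperintense, frequently
sub-0.1 cc, and vastly outnumbered by healthy tissue, so the pipeline is
built around three ideas: overlapping patches (small windows at half-window
stride so every structure is seen in several spatial contexts), 2.5D input
(five consecutive axial slices as channels, giving through-plane context
without 3D convolutions), and class-balanced patch training.

All volumes use the axis order (slice z, row y, col x), 0-based indices and
half-open windows. Resampled extents use round-half-up on the physical
extent so lesion volumes are reproducible. Volumes read from NIfTI are
reoriented to the closest canonical orientation; the original affine is
kept for write-back.

## Preprocessing

* **Bias correction.** `n4` delegates to SimpleITK's N4 filter on a 4×
  shrunken grid; `polynomial` fits a degree-2 polynomial to the
  log-intensities of bright voxels by least squares and divides by the
  exponential of the fit (unit geometric mean over the mask). Both modes
  estimate the field only on voxels above 10% of the 99.5th percentile —
  near-zero air voxels carry enormous negative log-intensities and would
  otherwise dominate the fit.
* **Intensity scaling.** The protocol's scaling range is stated ambiguously
  ("0.5–0.95%"); read literally it would discard over 99% of the dynamic
  range, so the package interprets it as percentile clipping at the 0.5th
  and 99.5th percentiles of the nonzero voxels followed by an affine map to
  [0, 1]. Both bounds are configurable (`preprocess.lower_pct/upper_pct`).
  Percentiles are computed over nonzero voxels only so background air does
  not compress the tissue histogram.
* **Gamma.** `v ** gamma` on [0, 1] intensities. Random gamma (default
  range 0.8–1.2) is a training-time augmentation; inference uses γ = 1.

## Patch engine

Windows of `patch.size` (default 128) slide at `patch.stride` (default 64).
When the stride does not divide `extent − patch`, a flush border window at
`extent − patch` is appended so coverage is total (irrelevant on
1024/128/64 grids, required at phantom sizes). The 5-slice stack replicates
edge slices at the z boundaries rather than padding with zeros, which would
fabricate zero-signal anatomy. A patch is classified *tumor* iff its
reference-slice label crop contains foreground — the network's target is
the reference slice only. Merging weights all covering windows equally
(pure arithmetic mean), with no Gaussian window weighting; cutting a fixed
map into patches and merging reproduces it exactly, which the tests assert.

## Network and optimization

The 2D U-Net (5 input channels, default depth 4 with 64 base filters) uses
two 3×3 convolutions per level with batch normalization applied *before*
the ELU activation, 2×2 max pooling, nearest-neighbour upsampling with a
1×1 channel-reducing convolution, skip concatenation, and a 1×1 output
convolution with a sigmoid. Layers are implemented directly in numpy with
explicit forward/backward passes (im2col convolutions); every backward pass
is validated against central finite differences in the test suite. The
patch size must be divisible by 2^depth.

Optimization is Adam with L2 regularization added to the weight gradients
(β = 1e−5), initial learning rate 1e−4, halved when the validation metric
has not improved for more than 2 epochs, up to 30 epochs, batch 256. Where
the protocol leaves choices open the defaults are:

* **Loss**: dice + binary cross-entropy (`dice_bce`), the standard choice
  under extreme foreground imbalance; `bce` and `dice` are selectable. The
  Dice term is computed over the whole batch so all-background patches do
  not produce degenerate per-sample gradients.
* **Plateau metric**: validation loss.
* **Train/validation split**: patient-level, 80/20 by seed.
* **Augmentation**: horizontal/vertical flips, rotations uniform in ±15°
  (labels resampled nearest-neighbour to stay binary), Gaussian blur on the
  image channels only, random gamma; each applied independently with a
  configurable probability. Augmentation never changes a patch's class.
* **Balancing**: once per run (not per batch): healthy windows are
  undersampled uniformly without replacement via a single streaming
  reservoir pass (so the full patch stream never has to reside in memory);
  tumor windows are resampled with replacement up to the per-class target
  (default 30,000).

Checkpoints are written as `.npz` weights plus a JSON sidecar recording
architecture, training configuration and seed; training history as CSV.

## Inference and post-processing

Sliding-window prediction uses eval-mode batch-norm statistics and the same
grid and preprocessing as training. The averaged probability map is
thresholded at 0.5 (the midpoint of the sigmoid output; configurable), and
connected components are extracted under 26-connectivity — small lesions
spanning ~5 slices should not fragment across diagonal voxel contacts.
Components with volume strictly below 0.02 cc are rejected; the rule is
applied to predictions (not to ground truth), with the threshold exposed as
a flag. 526 voxels at the reference spacing (3.8025e−5 cc each) sit just
above this cut.

## Metrics

* **Detection**: a ground-truth lesion is detected iff ≥ 1 predicted
  component shares ≥ 1 voxel with it (an IoU criterion is available but the
  overlap rule is the default — any stricter cut would need a threshold the
  protocol does not define). One predicted blob may validate several
  lesions; a predicted component overlapping no lesion is a false positive
  attributed to its patient. `tp + fn = |GT lesions|` is asserted on every
  evaluation.
* **DICE** uses the both-empty = 1, empty-vs-nonempty = 0 conventions.
* **Dilation** uses a physical sphere honouring anisotropic spacing (a
  voxel joins the structuring element iff its center lies within the radius
  in mm: 3 mm ≈ 15.4 in-plane voxels and 3 axial voxels at the reference
  grid), implemented through the exact Euclidean distance transform and
  verified against explicit offset enumeration.
* **HD95** is directed (prediction → ground truth) as defined, with a
  symmetric variant behind a flag; percentiles use linear interpolation
  between order statistics. Undetected lesions are reported with dice 0 and
  excluded from the HD95 aggregate.
* **Per-lesion locality**: each lesion is scored against the predicted
  foreground inside its bounding box expanded by the 3 mm margin, so one
  lesion's error cannot pollute a neighbour's score. Volume-bin reports
  (> 0.1, ≤ 0.1, 0.08–0.1, 0.06–0.08, 0.04–0.06, 0.02–0.04 cc) give both
  per-lesion-averaged metrics; the per-lesion table allows pooled
  recomputation.

## Phantom generator

Each phantom is a bright brain ellipsoid with a skull rim on a dark
background. Hyperintense ellipsoidal lesions (default contrast 1.8× tissue,
soft Gaussian edge) are placed without overlap inside the brain; volumes
are drawn from a two-component log-uniform mixture weighted so 58.2% of
draws fall below 0.1 cc, spanning 0.004–1.2 cc. Bright curvilinear
vessel-like tubes get the same intensity range and act as genuine
false-positive bait; they keep a 1 mm margin from lesions so ground truth
stays unambiguous. A smooth multiplicative bias field (superposed
low-frequency cosines, normalized to [1−a, 1+a]) and additive Gaussian
noise complete the image. Everything is deterministic per seed.

The default grid is 40 × 256 × 256 at (1, 0.78, 0.78) mm — the same
field-of-view logic as the clinical 1024-pixel slice with 16× fewer
in-plane voxels; the full-scale grid is available through the spec. The
generator does **not** model MR physics (no pulse sequences, coil profiles,
partial-volume effects beyond the soft lesion edge, or anatomical
structure), so passing phantom tests demonstrates the pipeline's mechanics
and bookkeeping, not clinical accuracy.

## Scaled end-to-end study

`run_phantom_study` chains the full pipeline under fixed study conditions:
8 training + 2 test phantoms at 40 × 256 × 256, high-contrast (2.5×) and
low-noise (σ = 2%) lesions, patch 64 at stride 32 (keeping the
half-window-overlap rule on 256-pixel slices), U-Net depth 3 with 8 base
filters, 600 patches per class, 5 epochs of Adam at 1e−3, batch 32. These
sizes are the package's CPU-scale study configuration; they trade model
capacity for runtime, which is appropriate because the study's purpose is
verifying the pipeline, not maximizing accuracy. Note that the generator
also plants lesions below the 0.02 cc rejection threshold, which are
therefore undetectable by construction; recovery claims are made for
lesions ≥ 0.04 cc.

## Numerical choices and degenerate inputs

* Probability-map values outside [0, 1] and uncovered pixels are hard
  errors in the merge step.
* Constant volumes return all zeros (with a warning) from intensity
  scaling; all-zero volumes are rejected by bias correction.
* The rejection rule uses strict `< min_volume_cc`, so a component exactly
  at the threshold is kept.
* Dilation and HD95 use a 1e−9 mm tolerance against the distance transform
  to make voxel membership at the exact radius bit-stable.
* Reservoir sampling makes balancing O(target) in memory and exactly
  uniform; selections are reproducible per seed but depend on stream order.

## Known limitations

* The numpy U-Net is single-threaded aside from BLAS matmuls; it is meant
  for CPU-scale studies and testing, not full-scale clinical training.
* DICOM reading supports single-series directories with uniform spacing
  and orientation; DICOM-RT export and inter-sequence registration are out
  of scope.
* Detection uses voxel-overlap matching; centroid-distance matching is not
  implemented.
* Phantom realism limits: no skull-stripping stage, no real vessel
  topology, no multi-sequence (T2/FLAIR/black-blood) images.
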