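# Methods

`lucent` implements a two-stage approach to detecting radiolucent foreign
body aspiration (FBA) on chest CT: segment the tracheobronchial lumen in
3D, render the segmented airway surface from a ring of virtual cameras,
and classify the rendered views per patient. Because a radiolucent foreign
body (food, plant matter) has soft-tissue density and no radiopaque
signature, the detectable evidence is *morphological*: an obstructed
bronchus truncates the segmentable airway distal to the plug. Everything
here — including the data — runs from scratch on one CPU.

## The synthetic airway phantom

No public FBA imaging cohort exists, so the package generates its own
study conditions as parametric phantoms (`lucent.phantom`).

**Geometry.** A binary branching tree: a trachea of radius 8 mm descends
cranio-caudally, and each generation splits in two with a branching
half-angle of 35° ± 10° jitter, child/parent radius ratio 0.78 (close to
the Murray's-law value 2^(−1/3) ≈ 0.794 for symmetric bifurcations),
segment length 3.2 × radius, and the branching plane rolled 90° per
generation so the tree spreads in 3D. Four generations below the trachea
at the default 128³ voxels / 1 mm isotropic spacing keep the tree well
inside the volume while leaving the distal branches thin (≈ 3 mm radius)
— small enough that truncations are subtle but resolvable.

**Appearance.** Segments are rasterized as capsules (cylinders with
hemispherical caps) into a Hounsfield-unit volume: lumen −1000 HU (air),
a 1-voxel wall at −100 HU, parenchyma background −820 HU. The clean
volume is blurred with a Gaussian point-spread function (σ 0.7 voxels)
and corrupted with additive Gaussian noise (SD 30 HU). All four HU
classes sit inside the standard chest window [−1000, +400] HU, so the
preprocessing clip is exercised non-trivially.

**Planting a foreign body.** An FBA phantom receives a soft-tissue plug
(+40 HU) occupying 3–8 mm of one bronchus, sited in generation 2 or 3.
The airway distal to the plug collapses: distal lumen reverts to
parenchyma density and the ground-truth mask is truncated at the plug.
Two choices deserve comment:

* *Distal collapse in the image, not only the mask.* Collapsing the
  distal lumen to parenchyma keeps image and label consistent (a
  segmentation network can otherwise be asked to ignore visible air) and
  mirrors the post-obstructive atelectasis that accompanies real
  obstruction.
* *No terminal-generation plugs by default.* A plug in the last
  generation truncates only a few millimetres of a ≈ 3 mm stub — below
  the raster and render resolution of the phantom, i.e. a positive case
  with no recoverable signal by construction. The site range is
  configurable (`PhantomSpec.plug_generations`).

Every artifact is a pure function of the phantom parameters and a seed;
cohort records
derive per-record seeds from the cohort seed with a counter-based scheme
so any single phantom is independently reproducible.

**What the phantom does not emulate:** lobar anatomy and lung boundaries,
cartilage rings, respiratory motion, scanner-specific noise spectra,
non-airway mediastinal structures, and the radiographic diversity of real
foreign bodies. Tests passing on phantoms therefore demonstrate that the
pipeline's machinery — preprocessing, losses, training loops, rendering,
aggregation, statistics — is correct and recovers planted signal under
controlled conditions; they say nothing about clinical accuracy on real
CT, which requires real cohorts and full-scale training.

## Preprocessing

Fixed order (`lucent.preprocess`): resample to 1.0 mm isotropic spacing
(trilinear for intensities, nearest-neighbour for masks) → clip to
[−1000, +400] HU and min-max normalize to [0, 1] → center-crop or
zero-pad to 128³ about the airway-mask centroid (padding value 0.0 = air
in the normalized domain) → Gaussian smooth with σ = 1.0 in voxel units
(equivalently mm after resampling). Smoothing is applied last, on the
normalized cropped volume, and is the only non-idempotent step. 2D
projection images destined for the classifier get an additional Z-score
normalization whose constants default to training-set render statistics
(stored in the run configuration); a pretrained color backbone would use
its pretraining-corpus statistics instead.

## Segmentation network

`lucent.segnet` implements an encoder–decoder with skip connections:
per level, two 3×3×3 convolutions + batch normalization + ReLU
(optionally residual with 1×1×1 projection shortcuts), 2×2×2 max-pool
downsampling, transposed-convolution upsampling, concatenated symmetric
skips, squeeze-and-excitation channel attention in decoder blocks
(global pool → bottleneck MLP → sigmoid gate — the concrete realization
chosen for "channel-wise attention"), and a final 1×1×1 convolution with
sigmoid. The training loss is the voxel-wise focal loss

    L = −α_t (1 − p_t)^γ log(p_t),   p_t = p if y = 1 else 1 − p,
                                     α_t = α on airway, 1 − α on background,

with γ = 2.0 and α = 0.25; probabilities are clamped to
[1e−7, 1 − 1e−7] before the logarithm. A Dice-loss additive term is not
used. Inference thresholds the probability field (strict `>`, so a
threshold of 1.0 yields an empty mask) and by default keeps only the
largest 26-connected component, a post-filter added here to stabilize
meshing.

Desk-scale defaults: depth 2, 8 base channels, 32³ airway-centred crops,
Adam at 3e−3, ~8 epochs over 20 phantoms (minutes on one CPU; held-out
Dice ≈ 0.97). Deeper configurations (depth 3–5, up to 128³ inputs) are
expressible through `SegNetConfig` but not exercised in tests. The 3D
augmentation menu — axis flips, ±15° in-plane rotations, additive
Gaussian noise (SD 0.02 in normalized units), ±15% brightness/contrast,
optional elastic deformation — is applied online to training samples
only.

All network layers are implemented in NumPy with hand-written
reverse-mode gradients (`lucent.nn`), validated against central finite
differences in float64 (`tests/test_nn.py`). Training is therefore
CPU-only and bit-deterministic given a seed.

## Rendering

`lucent.render` converts a binary mask to a triangulated surface with
marching cubes at iso-level 0.5 (vertices in mm; the mask is zero-padded
by one voxel first so border-touching surfaces close watertight). Twelve
virtual cameras sit on a 150 mm ring about the cranio-caudal axis at 0°
elevation, 30° apart, looking at the mesh centroid with a fixed +z
up-vector; 6-view ablation halves the ring density. Projection is
orthographic — patient-to-patient scale comparability is the point of a
fixed frame — with the frame half-extent defaulting to the camera radius
(auto-scaling with a notice if the mesh exceeds it; pipeline runs pin a
cohort-constant 70 mm half-frame instead). Shading is flat Lambertian
with a headlight (intensity = 0.1 + 0.9·|n·view|), orientation-agnostic
so mesh winding cannot flip brightness. Rasterization is a pure-NumPy
z-buffer with barycentric interpolation: deterministic to the bit, no
GPU or window system involved. Rotating the mesh +30° about the vertical
axis reproduces the neighbouring camera's image exactly up to
rasterization of off-grid vertices (mean absolute difference < 0.01).

## Multi-view classifier

Each rendered view passes through a residual 2D CNN
(`lucent.classifier`); per-view SoftMax probabilities are averaged
arithmetically over the patient's full view set, and the patient is
called FBA when the mean FBA probability strictly exceeds 0.5 (a tie at
exactly 0.5 resolves to NFBA, favouring specificity). Two backbones:

* `resnet18` — the standard four-stage (64–512 channel) residual
  layout with global average pooling and a 256-unit dense head, dropout
  0.5, SoftMax. Pretrained weights are optional and never required; the
  package runs offline and raises a clear error if they are requested.
* `tiny_resnet` — the CPU test variant: one 3×3 stem (8 channels), two
  residual stages (16, 32 channels, stride 2), a further 2× max-pool,
  and a **flattened** 8×-downsampled feature map into the same
  256-unit head. The flatten (rather than GAP) is deliberate: the
  truncation signature is positional — a branch missing at a particular
  image location — and a from-scratch network of this size cannot afford
  to re-encode position into channels, which is what GAP would require.

Training follows a fixed recipe: focal loss (γ = 2.0, α = 0.25 on FBA),
Adam (1e−4 default; 1e−3 at desk scale), mini-batches of 16 patients
stratified 1:1 (majority class without replacement until exhausted,
minority oversampled with replacement), learning rate ×0.1 after 5
consecutive epochs without relative validation-loss improvement ≥ 1e−4,
early stop after 10, and final weights from the best validation-F1 epoch
(earliest on ties). Within each patient-balanced batch the optimizer
steps on shuffled 32-view chunks: the classifier is per-view, so
view-level steps are the natural granularity, and they give the short
desk-scale runs enough optimization steps to calibrate probabilities,
not merely rank patients. Batch-norm running statistics use momentum
0.2 for the same short-run reason. A leakage guard asserts that no
patient id appears in more than one of train/validation/test at every
fit.

2D augmentation (random affine within ±10%, circular occlusion,
brightness/contrast jitter ±15%, dropout of 1–2 of the 12 views) is
implemented and configurable, but phantom-regime training disables it by
default, for two phantom-specific reasons: a masked-out circle *is* the
positive-class phenotype in a phantom (occlusion on a control patient's
views injects label noise), and phantom renders are geometrically
standardized by construction, so affine perturbations model variation
the data-generating process does not contain while erasing the
positional signal the tiny head relies on. On real, heterogeneous CT
renders the menu serves its usual regularizing purpose.

## Segmentation metrics

`lucent.segmetrics` reports DSC, VOE, |RVD| (signed RVD as a secondary
field), voxel precision, FNR, FPR, mean IoU (mean of foreground and
background IoU, as a fraction), and ASSD. Surfaces are foreground voxels
with at least one background 6-neighbour (array border counts as
background), voxel centers scaled by spacing; ASSD averages
nearest-neighbour distances symmetrically via k-d trees. FPR uses the
full-grid background count as its denominator — the standard definition;
restricted-denominator variants exist but are not well defined without a
region-of-interest convention. Degenerate cases are explicit: two empty
masks count as perfect agreement (with a warning); an empty reference
with a non-empty prediction makes RVD undefined and raises. All metrics
are checked against exhaustive brute-force references to 1e−10 relative
tolerance on random mask pairs.

## Evaluation statistics

`lucent.evalstats` implements the patient-level apparatus: confusion
counts; accuracy/precision/recall/F1 (percentages; harmonic-mean F1;
undefined ratios return `None`, never a silent zero; display rounding to
one decimal with full precision retained internally); rank-based AUC
with midrank tie handling; DeLong's test for correlated AUCs via midrank
structural components with a two-sided normal p (identical score vectors
return p = 1); McNemar's test — exact two-sided binomial below 25
discordant pairs, continuity-corrected χ² above; percentile bootstrap
95% CIs for F1 with 1000 patient-level resamples (degenerate resamples
redrawn and counted); and stratified patient-level k-fold assignment
(k = 5, seeded, per-fold class counts within one patient of the
stratified ideal — backed by scikit-learn's `StratifiedKFold`). The
DeLong implementation is validated against a 10 000-rep paired
sign-flip permutation oracle; McNemar against closed forms; AUC against
exhaustive pair counting and scikit-learn.

## Pipeline and ablation presets

`lucent.pipeline.run` chains phantom → preprocess → (optional
segmentation training) → render → classify → evaluate under one seeded
`RunConfig`; every stage writes artifacts plus a `.done` marker under
the run directory, and the run record carries a config hash so outputs
are traceable. Four presets reproduce the pipeline variants by
configuration alone: `raw_slices` (classify the middle 12 axial slices
of the preprocessed volume — the slice count keeps architectural parity
with the 12 views; no rendering, no augmentation), `mask_no_aug`
(12 views, augmentation off), `views6` (6 views, augmentation on), and
`full12` (the complete pipeline). `ablation_suite` runs all four on
identical folds and seeds.

## Problem sizes and determinism

Desk-scale runs use: 20 + 5 phantoms for segmentation (8 epochs, 32³
crops, ≈ 2 minutes), a 40/40-patient cohort with 12 views at 64×64 for
classification (24/24 train, 8/8 validation, 8/8 test; ≤ 30 epochs,
≈ 3 minutes), chosen so the full suite and the acceptance script run
comfortably on a single CPU. The rendering contract (12 views, 224×224,
150 mm) is exercised at full resolution. All randomness flows from
explicit seeds through `numpy.random.Generator`; repeated runs are
bit-identical for rendering and floating-point-identical for training on
the same platform.

## Known limitations

* Phantom realism is deliberately minimal (see above); reported recovery
  numbers characterize the easy synthetic regime, not clinical
  performance.
* The focal weighting α = 0.25 on positives depresses absolute
  probabilities; with mean aggregation and the fixed 0.5 threshold this
  makes patient-level calls sensitive to under-training (ranking, i.e.
  AUC, is far more robust). The training recipe above is sized so
  probabilities saturate; halving the step budget degrades accuracy
  before it degrades AUC.
* Full-volume segmentation inference at 128³ favours airway-centred
  crops; tiled inference is possible but not optimized.
* The `resnet18` backbone is constructible and trainable but not
  exercised end-to-end in tests (CPU cost); its stem max-pool uses a
  2×2 window rather than the conventional 3×3/stride-2 (the pooling
  layer carries no parameters).
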