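# Methods

## Model

The segmenter is a prototypical few-shot model specialized to a single
merged foreground class (all tumor sub-region labels 1/2/4 collapsed to 1).
One episode consists of a support set of C·K (image, mask) slice pairs and a
query set; support and query slices come from the same scan at different
slice indices, and only slices containing foreground are ever sampled — the
overwhelmingly empty background slices of a brain scan carry no signal for a
foreground prototype and would dominate the sampling otherwise.

A shared encoder maps each slice to a 256-channel feature grid at 1/8 of the
input resolution. The foreground prototype is the masked average of support
feature vectors (masks are nearest-neighbour-downsampled to the feature
grid, which avoids interpolating binary data). Query pixels are scored with
the negated scaled cosine R = −α·cos(χ, ρ), α = 20; scores are bilinearly
upsampled to mask resolution and converted to probabilities by
M = 1 − σ(R − β) with a single learnable scalar β. The decision surface is
therefore "cosine similarity to the prototype exceeds a learned margin":
pixels at R = β sit exactly at probability 0.5, which is also the
binarization threshold at inference.

Losses: a per-pixel-mean binary cross-entropy with class weights 1.0
(foreground) and 0.2 (background), plus a prototype alignment term with
weight λ = 1 that pools a prototype from the *query* features under the
predicted query mask (binarized at 0.5) and requires it to segment the
support slices. Both normalizers are per-pixel means: a per-episode loss
cannot meaningfully be normalized by dataset size, and the alignment term's
definition is explicitly 1/XY. Alignment with hard (binarized) rather than
probability-weighted masks was chosen because it mirrors how the prototype
is formed from hard support masks; if the binarized predicted mask is empty
(common in the first iterations) the term is 0, since a masked average over
an empty set is undefined.

Optimization: SGD, momentum 0.9, batch size 1 (one episode), learning rate
1e-3 multiplied by 0.97 every 1000 iterations, decoupled L2 weight decay
5e-4. β is initialized at −α/2 = −10, centered between the perfect-match
score (−α) and the orthogonal score (0); it trains jointly with the encoder.
Probabilities are clamped to [1e-7, 1−1e-7] inside the cross-entropy.

## Encoder

The pipeline depends only on the output contract — 256 channels, spatial
stride 8, deterministic in evaluation — and encoders are pluggable behind
it. The default is a compact 4-layer convolutional net (3→16→32→64 with
stride-2 3×3 kernels and ReLU, then a 1×1 projection to 256 channels),
He-initialized from a seed. It is small enough to train end-to-end on one
CPU in minutes, which is what makes the episodic loop testable; a deeper
pretrained backbone can be registered for full-scale experiments without
touching the prototype, loss or evaluation code. The model is implemented
on a minimal bundled reverse-mode autodiff engine (`protoseg.autodiff`)
whose gradients are verified against central finite differences in the test
suite.

## Preprocessing

Order: clip → resample → crop → binarize → standardize.

1. **Intensity clipping** removes the brightest tail: with fraction f
   (default 0.005), the threshold is the (k+1)-th largest voxel value,
   k = ⌊f·n⌋, so exactly k voxels are clipped when values are distinct.
   Upper tail only; idempotent.
2. **Slice resampling** to exactly 21 slices (linear interpolation for
   intensities, nearest slice for labels so the label set is closed).
   Twenty-one is chosen so that a C-shot K-way episode batch is C·K + 21,
   consistent with the encoder batch sizes 22/26/31/46/71 across the six
   standard shot/way configurations.
3. **ROI crop**, in-plane only, to the bounding box of the labeled
   foreground over all slices plus an 8-voxel margin (clamped to the grid).
   The margin keeps boundary context; cropping before resizing means the
   tumor occupies a consistent fraction of the standardized frame.
4. **Label merging** 1/2/4 → 1.
5. **Standardization**: bilinear resize to 256×256 (nearest for masks),
   min-max normalization to [0,1] using the **volume-wide** intensity range
   (a constant volume maps to zeros), channel replication ×3.

Volume-wide rather than per-slice normalization is load-bearing. Episodic
training only ever draws foreground-bearing query slices, so the model
receives no gradient from tumor-free slices; at inference, however, every
slice of the query scan is segmented. Per-slice min-max stretches the
brain tissue of a tumor-free slice up to full brightness — an intensity
regime the model never trained on — and produces whole-brain false
positives there. Keeping all slices on the scan's common intensity scale
places tumor-free tissue exactly in the background regime the training
episodes cover.

Training-time augmentation applies one affine transform per slice
(probability 0.5; rotation ±15°, translation ±10 px, shear ±10°, uniform)
identically to image and mask, re-binarizing the mask; it replaces the
slice rather than duplicating it. The training loop applies it to every
sampled episode; a slice whose mask would lose all its foreground under
the transform keeps its original (the masked average is undefined on an
empty mask).

## Synthetic data

The generator emulates T2-weighted tumor scans: a bright brain ellipsoid on
a zero background, a smaller brighter tumor ellipsoid with per-case
jittered center, radii and mean intensity, concentric label shells
(4 innermost, then 1, then 2) to exercise label merging, additive Gaussian
noise, intensities clipped at 0 and stored as float32. Defaults: 150
slices, 240×240 grid, tumor radii 8–18% of each dimension, tumor intensity
180±20 vs background 80±15, noise sd 10 — a clearly separable foreground,
matching the regime in which a single bright-tissue prototype is a
reasonable model. It does not emulate MRI physics (bias fields, partial
volume, motion), multi-modality, or non-ellipsoidal or multi-focal tumors;
passing tests therefore demonstrate that the pipeline's mechanics and
optimization work, not that the model segments real scans at any particular
accuracy. Per-case seeds are derived deterministically and output NIfTI
files are bitwise reproducible (uncompressed .nii for that reason).

## Evaluation

The support slice is the median foreground-bearing slice index
(deterministic; a seeded draw from the middle third of the foreground range
is available for replication-style runs). One prototype from that slice
segments every slice of the query stack; predictions are binarized at 0.5
and metrics are pooled over the volume in 3-D, then averaged across cases.
Empty-vs-empty pairs score Dice = IoU = 1; precision is recorded as missing
when nothing is predicted. Dice and IoU satisfy dice = 2·iou/(1 + iou),
which the suite checks on random masks. k-fold cross-validation partitions
cases into k disjoint validation folds, trains per fold and reports
mean/sd/max of Dice, IoU and precision.

## Problem sizes

Desk-scale runs use synthetic volumes of 60 slices at 96×96 (the
standardization step maps every case to 21×3×256×256 regardless, so the raw
grid only changes generation cost), 20 training + 4 held-out cases, and
2000 training iterations — the configuration of the end-to-end test and
the worked example in the README. Full-scale settings (150×240×240 inputs,
50 000 iterations) are the library defaults for `SynthConfig` and
`TrainConfig`.

## Known limitations

- A single prototype assumes a homogeneous foreground; multi-focal or
  strongly heterogeneous tumors would need prototype clustering.
- The compact encoder is untested beyond the synthetic regime; real-scan
  accuracy requires a pretrained backbone plugged into the contract.
- "Ways" multiply support count only — with one merged class there are no
  additional semantic classes to discriminate.
- Precision is undefined (missing) for empty predictions rather than
  imputed.
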