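# Methods

## Model

The classifier treats a template-aligned 3D volume as a bag of overlapping
cubic patches. A convolutional encoder whose receptive field is capped at a
chosen patch size s scores every patch with a shared (translation-
equivariant) function; a separate point-wise network over patch-center
coordinates produces a gate value per patch position; the image-level
response is the gate-normalized sum of gated patch responses. All layers
after the encoder stem have stride 1, so the patch grid spacing (jump) is
fixed at 4 voxels and s is controlled purely by how many 3³ convolutions
the residual blocks contain: s = 9 + 8k, k ∈ {0, 1, 2, 4, 6} for the five
shipped encoders (s ∈ {9, 17, 25, 41, 57}).

Assumptions worth stating explicitly:

- **Template alignment.** Inputs are assumed affinely registered to one
  common grid; voxel indices are the only coordinate system used (the NIfTI
  affine is carried through to outputs but never consumed by the model).
  The gating branch is meaningful only under this assumption — it encodes
  *where in template space* discriminative patches consistently sit.
- **Valid padding throughout.** Every patch response corresponds to a
  complete patch inside the crop; no border voxel is fabricated. The cost
  is a smaller output grid, accepted to keep the bag-of-patches semantics
  exact.
- **Single binary label per image.** The loss is a balanced, label-smoothed
  binary cross-entropy; no voxel-level supervision exists anywhere in the
  pipeline.

## Architecture details left open by the general recipe, and how they were fixed

- Residual blocks: two convolutions per block (1³ by default, upgraded to
  3³ front to back to reach the target receptive field), each followed by
  instance normalization; ReLU after the first; identity shortcut, spatially
  center-cropped to match valid-padding shrinkage and passed through a
  point-wise projection when the channel count changes; ReLU after the add.
- The classifier is one point-wise linear layer (256 → 1) with bias.
- The position embedding ends with a ReLU before the gate network; the gate
  network applies ReLU only after its first layer, then channel-means its
  16 maps and applies the sigmoid. Neither gating network uses
  normalization layers.
- Instance normalization statistics are computed per image per channel with
  float64 accumulators (values remain float32). This makes the statistics
  independent of memory traversal order, which is what lets translation
  equivariance hold to ~1e-6 instead of ~1e-4.

## Coordinates

The coordinate grid assigns channel c at voxel index i the value
2i/(n_c − 1) − 1, normalized over the **full template extent** before any
crop; crops slice the grid without renormalizing. This is the mechanism that
makes the gate translation-*dependent* while the patch branch stays
translation-equivariant: cropping shifts the coordinates seen at each patch
center by a constant 2δ/(n − 1). Patch centers sit at offset + index·jump
per axis, from the standard receptive-field recurrence (jump′ = jump·stride,
rf′ = rf + (k − 1)·jump, offset′ = offset + ((k − 1)/2 − p)·jump). With the
shipped stacks all offsets are integral; the linear-interpolation path for
fractional centers exists and is unit-tested but not exercised by shipped
geometry.

## Objective

L_total = L_cls + λ·L_ent with λ = 0.01.

- L_cls = −β·y_LS·log ŷ − (1 − β)·(1 − y_LS)·log(1 − ŷ), with smoothed
  targets y_LS ∈ {0.1, 0.9} and β = (#negatives)/(#total) computed on the
  training split of each fold only. Batch reduction is the mean. With
  β = 0.5 and unsmoothed targets this is exactly half the standard BCE.
- L_ent = −H(G), the negative mean binary entropy of the gate map. Because
  G is a function of coordinates alone, L_ent has exactly zero gradient on
  the encoder and classifier parameters; this is structural, asserted by an
  autodiff probe in the tests rather than enforced by masking.
- All logarithms clamp probabilities at 1e-12; gate-normalized pooling
  raises a degenerate-gate error when Σg ≤ 1e-8.

## Training procedure

Adam (betas 0.9/0.999, eps 1e-8), learning rate warmed up linearly over 5
epochs then cosine-annealed to zero; one random crop per sample per epoch
during training, center crop for validation and test; early stopping on the
validation balanced smoothed cross-entropy *without* the entropy term; the
best-validation checkpoint is returned. Stratified k-fold cross-validation
carves an inner validation split (20%, at least one sample per class) from
each training portion; ACC/AUROC are reported on the held-out fold. Every
stochastic choice (init, folds, crops, shuffling) derives from the run
seed; two runs with one seed produce identical trajectories.

Reference scale: 200 epochs, peak 1e-4, patience 30 (intended for cohorts
of hundreds of full-resolution scans). Desk scale
(`TrainConfig.phantom_scale()`, used by the examples and the acceptance
suite): 60 epochs, peak 3e-3, patience 30, 44³ crops of 48³ phantoms.
The higher peak rate compensates for the far smaller number of optimizer
steps per epoch. The patience is kept at the reference value deliberately:
on phantom tasks the loss sits at the trivial-prediction plateau (≈0.347
= ln 2/2 for balanced classes) for the first 15–25 epochs while the
encoder and the gate co-adapt — the gate can only localize once patch
responses carry signal, and patch responses only become class-relevant
where the gate concentrates. A patience shorter than the plateau stops
training inside it and yields a chance-level model.

## The phantom generator

`PhantomConfig` defaults define the study condition: 48³ grid, 50 subjects
per class, one shared unit-variance smooth background (Gaussian-filtered
white noise, σ = 3) representing the common template anatomy, a per-subject
smooth deviation at sd 0.3 representing residual anatomical variability
after affine alignment, sensor noise sd 0.05, and additive spheres of
radius 5 at amplitude 0.5: one lesion at the fixed template position
(30, 18, 24) in positives only, plus 8 distractors at uniform random
positions in **both** classes. Lesion and distractors are deliberately
identical in appearance, so patch appearance alone carries only the weak
count signal (9 spheres vs 8) and position is the essential cue — the
regime in which gated pooling should beat mean pooling. Distractor
placement is identically distributed in both classes, so distractors
cannot leak label information. Each subject index yields a matched pair (same background
deviation, noise and distractors; lesion added to the positive), which
makes the class difference's support exactly the lesion mask and is
convenient for exact-support tests.

What the phantoms do **not** emulate: real neuroanatomy, atrophy as
deformation rather than intensity change, multi-site intensity effects,
registration error. Passing phantom tests demonstrates that the
architecture, geometry, losses and training loop implement the intended
algorithm and that position-based gating recovers a position-consistent
signal at desk scale — not that any particular clinical accuracy would be
attained on real cohorts.

Localization is quantified as the fraction of total gate mass on patches
whose receptive-field footprint overlaps the true lesion mask; a uniform
gate scores the chance baseline (the fraction of overlapping patches,
≈0.12 under the default geometry).

## Numerical and design choices

- float32 is the canonical precision on disk and in memory; loss and
  metric reductions use float64.
- Whole-image normalization (mean 0, sd 1) precedes cropping, so intensity
  statistics do not depend on the sampled crop; constant images are
  rejected rather than silently zeroed.
- Accuracy threshold is 0.5 on the posterior; AUROC is the Mann–Whitney
  rank statistic with tie averaging.
- Checkpoints are a flat npz parameter archive plus a JSON sidecar
  (encoder spec, gating mode, build seed) — enough to rebuild the exact
  model without pickle.
- Overlay exports place each patch-grid value at its patch-center voxel,
  interpolate linearly between centers, fill 0 outside the patch-center
  hull, and ship an explicit validity mask plus the (rf, jump, offset,
  crop origin) record needed to regenerate them bit-exactly.

## Known limitations

- Isotropic kernels, strides and crops only; no dilated or even-sized
  kernels.
- The numpy network trains comfortably at phantom scale (~0.15 s per
  sample forward+backward for the s=9 encoder on 44³ crops, single CPU)
  but is not intended for full-resolution cohorts; there is no GPU path.
- `feature_gate` and `fixed_gate` modes are exercised by tests at
  mechanical level; the shipped end-to-end comparisons are
  `position_gate` vs `gap`.
- Five-fold cross-validation on phantoms multiplies training cost
  accordingly; the examples therefore demonstrate single splits, and
  `cross_validate` is covered by short-schedule tests.
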