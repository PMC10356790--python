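# patchbag

Bag-of-3D-patches networks with coordinate-driven gating, for weakly
supervised lesion localization and image-level classification of
template-aligned volumetric images (e.g. structural brain MRI registered to
a common template).

## The problem

In many neuroimaging classification problems only image-level labels exist
(diseased / healthy), yet the disease signature occupies a small,
anatomically consistent region — most patches of a patient's scan are
indistinguishable from a control's. Treating the whole image as a *bag* of
unlabeled 3D patch *instances* (multiple-instance learning) raises two
coupled questions: how should per-patch scores be aggregated into one
image-level decision, and can the aggregation itself reveal *where* the
discriminative changes sit, without any voxel-level annotation?

## The model

Two branches consume a normalized, cropped volume **X** and its patch-center
coordinates:

- **Patch-level prediction branch.** An encoder E^s_φ with a deliberately
  limited receptive field (BagNet-style: a 5³/stride-2 convolution stem,
  3³/stride-2 max pooling, then four residual blocks of 32/64/128/256
  channels, all valid padding) yields features X̂ ∈ ℝ^(w×h×d×256); a
  point-wise linear classifier C_ψ turns each feature vector into a scalar
  patch response x̃_ijk. The family of patch sizes is s ∈ {9, 17, 25, 41, 57}:
  every 3³ convolution after the stem adds 8 voxels of receptive field
  (kernel growth 2 × grid spacing 4), i.e. s = 9 + 8k for k = 0, 1, 2, 4, 6.

- **Position-based gating branch.** The full-resolution Cartesian
  coordinate grid **I** (three channels, normalized to [−1, 1] over the
  template extent) is subsampled at the patch centers — the same crop and
  layer geometry as the encoder — giving the position indicator **I′**. A
  point-wise MLP (embedding 3→128→256, gate 256→128→16, channel mean,
  sigmoid) maps each patch-center coordinate to a gate value g_ijk ∈ [0, 1].
  Because it sees coordinates only, the gate map is identical for every
  subject: it encodes where discriminative patches *consistently* appear in
  template space.

Aggregation multiplies the two: patch-level class evidence
e_ijk = g_ijk · x̃_ijk, pooled as

    z = Σ e_ijk / Σ g_ijk ,     ŷ = sigmoid(z)

so the amount of gated tissue never changes the scale of the response
(constant gates reduce exactly to global average pooling). Training
minimizes a balanced, label-smoothed cross-entropy
(targets {0.1, 0.9}, class weight β = negative-class frequency) plus
λ = 0.01 times a gate-entropy term −H(**G**) that keeps region exploration
open early; by construction the entropy term can only move the gating
parameters. Optimization is Adam with linear warm-up and cosine decay,
mini-batches of 4, random 44³ crops for augmentation (center crops at
evaluation), early stopping on validation loss, and stratified k-fold
cross-validation. Baselines are selectable per run: plain mean pooling
(`gap`), a feature-driven gate (`feature_gate`), or a user-supplied fixed
map (`fixed_gate`).

The network, its layers (3D convolution, max pooling, instance
normalization), reverse-mode autodiff, He initialization and Adam are
implemented in numpy inside the package (`patchbag.nn`); gradients are
verified against finite differences in the test suite, and the analytic
receptive-field calculus is cross-checked by an independent
gradient-support oracle.

## Worked example

Real cohorts with voxel-level ground truth are rarely available, so the
package ships a phantom generator: template-aligned 48³ volumes sharing one
smooth background, where positives carry an additive lesion sphere at a
fixed template position and *both* classes carry distractor spheres of
identical appearance at random positions — patch appearance alone is nearly
uninformative; position is the discriminative cue.

```bash
python examples/03_train_position_gate.py
```

```
train 64 / val 16 / test 20; 60 epochs, peak lr 0.003, crop (44, 44, 44)
position_gate  stopped at epoch 59, best val loss 0.2206, held-out ACC 0.95 AUROC 1.00
               gate localization 0.71 vs uniform baseline 0.12 (fraction of gate mass on lesion-overlapping patches)
gap            stopped at epoch 52, best val loss 0.2944, held-out ACC 0.80 AUROC 0.94
```

The coordinate-gated model separates held-out subjects essentially
perfectly and places 71% of its gate mass on patches overlapping the true
lesion (chance: 12%), while the mean-pooling baseline — blind to position —
is left exploiting the weak sphere-count signal. The other example scripts
print the receptive-field table for all five encoders
(`01_receptive_field_arithmetic.py`), the cohort's class-contrast anatomy
(`02_generate_phantom_cohort.py`), and per-subject gate/evidence NIfTI
overlays whose evidence re-aggregates exactly to the recorded image-level
response (`04_evidence_maps.py`).

A thin CLI wraps the same library calls:

```bash
patchbag simulate --config cohort.yaml     # phantom cohort + manifest
patchbag train    --config run.yaml        # cross-validated training
patchbag evaluate --checkpoint run/fold0 --manifest cohort/manifest.csv
patchbag explain  --checkpoint run/fold0 --volume subj.nii --out maps/
patchbag geometry --patch-size 17 --oracle # rf / jump / offset / extents
```

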