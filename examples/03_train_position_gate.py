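"""Train a position-gate model against the mean-pooling baseline.

Runs the full desk-scale study condition: the default 2 x 50 phantom
cohort and the 60-epoch warm-up + cosine schedule.  Both models share the
seed, data, and schedule — the only difference is the pooling:
coordinate-gated versus plain mean.  Expect roughly five minutes on one
CPU; the trained position-gate checkpoint is saved for the evidence-map
example.

Note the characteristic trajectory: the loss sits at the trivial-prediction
plateau (~0.35) for the first 15-25 epochs while encoder and gate
co-adapt, then drops.  Early stopping must outlast that plateau.
"""

import numpy as np
from sklearn.model_selection import train_test_split

import patchbag as pb

cfg = pb.PhantomConfig(seed=7)
volumes, mask = pb.generate_cohort(cfg)
labels = np.array([v.label for v in volumes])

idx = np.arange(len(volumes))
trainval, test = train_test_split(idx, test_size=0.2, stratify=labels, random_state=7)
tr, va = train_test_split(
    trainval, test_size=0.2, stratify=labels[trainval], random_state=7
)
tc = pb.TrainConfig.phantom_scale(seed=7)
print(f"train {len(tr)} / val {len(va)} / test {len(test)}; "
      f"{tc.max_epochs} epochs, peak lr {tc.peak_lr}, crop {tc.crop_size}")

for mode in ("position_gate", "gap"):
    res = pb.train_fold(
        [volumes[i] for i in tr],
        [volumes[i] for i in va],
        {"spec": pb.EncoderSpec(patch_size=9), "gating_mode": mode},
        tc,
    )
    scores = pb.predict_scores(
        res.state, [volumes[i] for i in test], crop_size=tc.crop_size
    )
    acc, auroc = pb.evaluate(scores, labels[test])
    print(f"{mode:14s} stopped at epoch {res.epoch_stopped:2d}, "
          f"best val loss {res.best_val_loss:.4f}, held-out ACC {acc:.2f} "
          f"AUROC {auroc:.2f}")
    if mode == "position_gate":
        pb.save_checkpoint(res.state, "scratch/position_gate_ckpt")
        layers = res.state.spec.layer_geoms()
        crop = pb.sample_crop(cfg.extent, tc.crop_size, mode="center")
        ind = pb.extract_position_indicator(
            pb.make_coordinate_grid(cfg.extent).crop(crop.origin, crop.size), layers
        )
        g = pb.gate_forward(res.state, ind)
        loc = pb.localization_score(g, mask, layers, crop_origin=crop.origin)
        uni = pb.localization_score(
            np.ones_like(g.values), mask, layers, crop_origin=crop.origin
        )
        print(f"               gate localization {loc:.2f} vs uniform baseline "
              f"{uni:.2f} (fraction of gate mass on lesion-overlapping patches)")

print()
print("The gated model separates the classes (AUROC near 1) while the")
print("mean-pooling baseline, blind to position, is left with the weak")
print("sphere-count signal; the localization line shows the trained gate")
print("concentrating far above chance on the planted lesion region.")
print("Checkpoint written to scratch/position_gate_ckpt.{npz,json}.")
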