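"""Schedule, early stopping, determinism, folds, and transfer."""

import math

import numpy as np
import pytest

import patchbag as pb


def _tiny_train_cfg(**kw):
    base = dict(
        max_epochs=3,
        warmup_epochs=1,
        peak_lr=1e-3,
        batch_size=4,
        patience=5,
        lam=0.01,
        seed=3,
        crop_size=None,
    )
    base.update(kw)
    return pb.TrainConfig(**base)


# --------------------------------------------------------------------------
# learning-rate schedule


def test_lr_schedule_warmup_and_cosine_shape():
    cfg = pb.TrainConfig(seed=0)  # paper-scale: 200 epochs, 5 warmup, 1e-4 peak
    assert pb.lr_schedule(4, cfg) == pytest.approx(1e-4)
    assert pb.lr_schedule(0, cfg) == pytest.approx(1e-4 / 5)
    # cosine midpoint: warmup + half the remaining span
    mid = 5 + (200 - 5) // 2
    assert pb.lr_schedule(mid, cfg) == pytest.approx(1e-4 / 2, rel=0.02)
    assert pb.lr_schedule(199, cfg) < 1e-7
    with pytest.raises(ValueError):
        pb.lr_schedule(200, cfg)
    with pytest.raises(ValueError):
        pb.lr_schedule(-1, cfg)


def test_lr_schedule_continuous_and_nonnegative():
    cfg = pb.TrainConfig(max_epochs=50, warmup_epochs=5, peak_lr=1e-3, seed=0)
    lrs = [pb.lr_schedule(e, cfg) for e in range(50)]
    assert all(lr >= 0 for lr in lrs)
    # boundary: last warmup epoch hits the peak, first cosine epoch equals it
    assert lrs[4] == pytest.approx(1e-3)
    assert lrs[5] == pytest.approx(1e-3)
    assert max(abs(b - a) for a, b in zip(lrs, lrs[1:])) < 2.1e-4


# --------------------------------------------------------------------------
# train_fold mechanics (tiny cohorts; the substantive end-to-end recovery run
# lives in the acceptance suite)


@pytest.fixture(scope="module")
def tiny_split():
    cfg = pb.PhantomConfig(
        extent=(32, 32, 32),
        n_per_class=12,
        lesion_center=(20, 12, 16),
        lesion_radius=4,
        n_distractors=2,
        seed=11,
    )
    vols, mask = pb.generate_cohort(cfg)
    return vols[:8], vols[8:12], mask


def test_two_runs_same_seed_identical_trajectories(tiny_split):
    train, val, _ = tiny_split
    model_cfg = {"spec": pb.EncoderSpec(9), "gating_mode": "position_gate"}
    r1 = pb.train_fold(train, val, model_cfg, _tiny_train_cfg())
    r2 = pb.train_fold(train, val, model_cfg, _tiny_train_cfg())
    assert [h["train_loss"] for h in r1.history] == [h["train_loss"] for h in r2.history]
    assert [h["val_loss"] for h in r1.history] == [h["val_loss"] for h in r2.history]


def test_best_checkpoint_tracks_minimum_val_loss(tiny_split):
    train, val, _ = tiny_split
    res = pb.train_fold(
        train, val, {"spec": pb.EncoderSpec(9), "gating_mode": "gap"}, _tiny_train_cfg()
    )
    assert res.best_val_loss == pytest.approx(min(h["val_loss"] for h in res.history))


def test_patience_zero_stops_at_first_non_improvement(tiny_split):
    train, val, _ = tiny_split
    res = pb.train_fold(
        train,
        val,
        {"spec": pb.EncoderSpec(9), "gating_mode": "gap"},
        _tiny_train_cfg(max_epochs=20, patience=0),
    )
    vals = [h["val_loss"] for h in res.history]
    if len(vals) < 20:  # stopped early: the last epoch failed to improve
        assert vals[-1] >= min(vals[:-1])
        assert all(v < min(vals[:i]) if i else True for i, v in enumerate(vals[:-1]))


def test_single_class_training_split_rejected(tiny_split):
    train, val, _ = tiny_split
    pos_only = [v for v in train + val if v.label == 1]
    with pytest.raises(ValueError, match="both classes"):
        pb.train_fold(pos_only, val, {"spec": pb.EncoderSpec(9)}, _tiny_train_cfg())


def test_constant_fixed_gate_matches_gap_trajectories(tiny_split):
    """With a constant gate map the normalized gated pool reduces to plain
    mean pooling, so training is behaviorally identical to gap mode."""
    train, val, _ = tiny_split
    ext = pb.output_extent((32, 32, 32), pb.EncoderSpec(9).layer_geoms())
    fixed = np.full(ext, 0.7, np.float32)
    cfg = _tiny_train_cfg(max_epochs=2, warmup_epochs=1)
    r_gap = pb.train_fold(
        train, val, {"spec": pb.EncoderSpec(9), "gating_mode": "gap"}, cfg
    )
    r_fix = pb.train_fold(
        train,
        val,
        {"spec": pb.EncoderSpec(9), "gating_mode": "fixed_gate", "fixed_gate": fixed},
        cfg,
    )
    for ha, hb in zip(r_gap.history, r_fix.history):
        assert abs(ha["train_loss"] - hb["train_loss"]) < 1e-6
        assert abs(ha["val_loss"] - hb["val_loss"]) < 1e-6


def test_cross_validate_partition_and_stratification(tiny_split):
    train, val, _ = tiny_split
    vols = train + val  # 12 samples, 6 per class
    cfg = _tiny_train_cfg(max_epochs=2, warmup_epochs=1, folds=3)
    results = pb.cross_validate(vols, {"spec": pb.EncoderSpec(9), "gating_mode": "gap"}, cfg)
    assert len(results) == 3
    assert {r.fold_index for r in results} == {0, 1, 2}
    summary = pb.summarize_folds(results)
    assert set(summary) == {"acc_mean", "acc_sd", "auroc_mean", "auroc_sd"}
    with pytest.raises(ValueError, match="at least"):
        pb.cross_validate(vols[:4], {"spec": pb.EncoderSpec(9)}, _tiny_train_cfg(folds=5))


def test_transfer_copies_parameters_and_rejects_mismatch(tiny_split, rng):
    train, val, _ = tiny_split
    res = pb.train_fold(
        train,
        val,
        {"spec": pb.EncoderSpec(9), "gating_mode": "position_gate"},
        _tiny_train_cfg(max_epochs=2, warmup_epochs=1),
    )
    target = pb.transfer_init(res.state)
    x = rng.standard_normal((32, 32, 32)).astype(np.float32)
    np.testing.assert_array_equal(
        pb.patch_responses(target, x).values, pb.patch_responses(res.state, x).values
    )
    with pytest.raises(ValueError, match="mismatch"):
        pb.transfer_init(res.state, spec=pb.EncoderSpec(17))
    with pytest.raises(ValueError, match="mismatch"):
        pb.transfer_init(res.state, gating_mode="gap")


def test_transfer_starts_closer_than_fresh_init(tiny_split):
    """A model trained on task A scores unseen same-template subjects better
    than an untrained He init — the premise of the transfer protocol."""
    train, val, _ = tiny_split
    trained = pb.train_fold(
        train,
        val,
        {"spec": pb.EncoderSpec(9), "gating_mode": "position_gate"},
        _tiny_train_cfg(max_epochs=8, warmup_epochs=2, peak_lr=3e-3),
    )
    cfg_b = pb.PhantomConfig(
        extent=(32, 32, 32),
        n_per_class=12,
        lesion_center=(20, 12, 16),
        lesion_radius=4,
        n_distractors=2,
        seed=11,
    )
    task_b, _ = pb.generate_cohort(cfg_b)
    task_b = task_b[12:]  # subjects unseen during task-A training
    labels = [v.label for v in task_b]
    transferred = pb.transfer_init(trained.state)
    fresh = pb.build_model(pb.EncoderSpec(9), "position_gate", seed=3)
    beta_cfg = pb.LossConfig(beta=0.5)
    loss_t = pb.classification_loss(pb.predict_scores(transferred, task_b), labels, beta_cfg)
    loss_f = pb.classification_loss(pb.predict_scores(fresh, task_b), labels, beta_cfg)
    assert loss_t <= loss_f
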