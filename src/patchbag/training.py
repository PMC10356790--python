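"""End-to-end optimization: schedule, early stopping, cross-validation, transfer.

The recipe: Adam, learning rate warmed up linearly from 0 to the peak over
the first ``warmup_epochs`` epochs and then cosine-annealed to ~0 at
``max_epochs``; mini-batches of 4; early stopping on the validation
balanced label-smoothed cross-entropy (no entropy term) with a patience
counter; one fresh random crop per sample per training epoch, center crops
for validation and test.  beta (the negative-class frequency) is computed
on the training split only.

Every stochastic choice — parameter init, fold assignment, crop sampling,
shuffling — derives from the run seed, so two runs with the same seed
produce identical loss trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .geometry import CoordinateGrid, extract_position_indicator, make_coordinate_grid
from .io_volumes import CropSpec, Volume, crop, normalize, sample_crop
from .model import EncoderSpec, ModelState, build_model
from .pooling_losses import (
    LossConfig,
    compute_beta,
    evaluate,
    t_classification_loss,
    t_gate_entropy,
)
from . import nn
from ._forward import forward_sample

__all__ = [
    "TrainConfig",
    "FoldResult",
    "lr_schedule",
    "train_fold",
    "cross_validate",
    "summarize_folds",
    "transfer_init",
    "predict_scores",
]


@dataclass
class TrainConfig:
    max_epochs: int = 200
    warmup_epochs: int = 5
    peak_lr: float = 1e-4
    batch_size: int = 4
    patience: int = 30
    lam: float = 0.01
    seed: int = 0
    folds: int = 5
    crop_size: tuple[int, int, int] | None = None  # None: use full volumes, no aug

    def __post_init__(self):
        if not (0 < self.warmup_epochs < self.max_epochs):
            raise ValueError("need 0 < warmup_epochs < max_epochs")
        if min(self.peak_lr, self.batch_size, self.patience + 1, self.folds) <= 0:
            raise ValueError("config values must be positive")

    @classmethod
    def phantom_scale(cls, seed: int = 0, **overrides) -> "TrainConfig":
        """The desk-scale schedule for the default 48^3 phantom cohorts.

        Same shape as the full recipe (Adam, 5-epoch linear warm-up, cosine
        decay, batch 4, early stopping with patience 30, lambda 0.01) with
        the epoch budget and peak learning rate adapted to the small
        from-scratch regime: 60 epochs at peak 3e-3, 44^3 training crops.
        The patience is kept at the full recipe's absolute value because the
        plateau in which the encoder and gate co-adapt lasts on the order of
        twenty epochs regardless of the total budget; a shorter patience
        stops training inside it.
        """
        base = dict(
            max_epochs=60,
            warmup_epochs=5,
            peak_lr=3e-3,
            batch_size=4,
            patience=30,
            lam=0.01,
            seed=seed,
            crop_size=(44, 44, 44),
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class FoldResult:
    fold_index: int
    best_val_loss: float
    state: ModelState
    epoch_stopped: int
    history: list[dict] = field(default_factory=list)
    metrics: dict = field(default_factory=dict)


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Linear warm-up to the peak, then cosine decay to zero."""
    if not 0 <= epoch < cfg.max_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.max_epochs})")
    if epoch < cfg.warmup_epochs:
        return cfg.peak_lr * (epoch + 1) / cfg.warmup_epochs
    span = cfg.max_epochs - cfg.warmup_epochs
    return cfg.peak_lr * 0.5 * (1.0 + math.cos(math.pi * (epoch - cfg.warmup_epochs) / span))


def _prepare(volumes: Sequence[Volume]) -> list[Volume]:
    """Whole-image standardization, once, before any cropping."""
    return [normalize(v) for v in volumes]


def _cropped_sample(
    v: Volume, grid: CoordinateGrid, spec: CropSpec | None, layers
) -> tuple[np.ndarray, "object"]:
    if spec is None:
        data, sub = v.data, grid
    else:
        data = crop(v, spec).data
        sub = grid.crop(spec.origin, spec.size)
    return data, extract_position_indicator(sub, layers)


def _snapshot(state: ModelState) -> dict:
    return {
        bn: {k: t.data.copy() for k, t in params.items()}
        for bn, params in state.branches().items()
    }


def _restore(state: ModelState, snap: dict) -> None:
    for bn, params in state.branches().items():
        for k, t in params.items():
            t.data = snap[bn][k].copy()


def predict_scores(
    state: ModelState, volumes: Sequence[Volume], crop_size=None, prepared: bool = False
) -> np.ndarray:
    """Posterior probabilities with center crops (the evaluation protocol)."""
    vols = list(volumes) if prepared else _prepare(volumes)
    layers = state.spec.layer_geoms()
    grid = make_coordinate_grid(vols[0].extent)
    spec = (
        None
        if crop_size is None
        else sample_crop(vols[0].extent, crop_size, mode="center")
    )
    scores = []
    for v in vols:
        data, ind = _cropped_sample(v, grid, spec, layers)
        out = forward_sample(state, data, ind)
        scores.append(out["y_hat"].item())
    return np.asarray(scores)


def train_fold(
    train_set: Sequence[Volume],
    val_set: Sequence[Volume],
    model_cfg: dict,
    cfg: TrainConfig,
    fold_index: int = 0,
    init_state: ModelState | None = None,
) -> FoldResult:
    """Optimize one model on one train/val split; return the best checkpoint.

    ``model_cfg`` holds ``spec`` (an :class:`EncoderSpec` or patch size),
    ``gating_mode`` and optionally ``fixed_gate``.
    """
    train_labels = [int(v.label) for v in train_set]
    val_labels = [int(v.label) for v in val_set]
    if len(set(train_labels)) < 2:
        raise ValueError("training split must contain both classes")

    spec = model_cfg.get("spec", EncoderSpec())
    if isinstance(spec, int):
        spec = EncoderSpec(patch_size=spec)
    gating_mode = model_cfg.get("gating_mode", "position_gate")
    if init_state is not None:
        state = transfer_init(init_state, gating_mode=gating_mode, spec=spec)
    else:
        state = build_model(
            spec,
            gating_mode=gating_mode,
            seed=cfg.seed,
            fixed_gate=model_cfg.get("fixed_gate"),
        )
    layers = spec.layer_geoms()
    loss_cfg = LossConfig(beta=compute_beta(train_labels), lam=cfg.lam)

    train_vols = _prepare(train_set)
    val_vols = _prepare(val_set)
    full_extent = train_vols[0].extent
    grid = make_coordinate_grid(full_extent)
    center_spec = (
        None
        if cfg.crop_size is None
        else sample_crop(full_extent, cfg.crop_size, mode="center")
    )

    opt = nn.Adam(list(state.parameters()))
    rng = np.random.default_rng([cfg.seed, 1])
    best_loss, best_snap, best_epoch = math.inf, _snapshot(state), -1
    since_improve = 0
    history: list[dict] = []

    for epoch in range(cfg.max_epochs):
        lr = lr_schedule(epoch, cfg)
        order = rng.permutation(len(train_vols))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            opt.zero_grad()
            batch_terms = []
            for idx in batch:
                v = train_vols[idx]
                spec_c = (
                    None
                    if cfg.crop_size is None
                    else sample_crop(
                        full_extent,
                        cfg.crop_size,
                        mode="random",
                        seed=int(rng.integers(0, 2**31)),
                    )
                )
                data, ind = _cropped_sample(v, grid, spec_c, layers)
                out = forward_sample(state, data, ind)
                loss = t_classification_loss(out["y_hat"], int(v.label), loss_cfg)
                if out["g"] is not None and state.gating_mode in (
                    "position_gate",
                    "feature_gate",
                ):
                    loss = loss + cfg.lam * (-t_gate_entropy(out["g"]))
                batch_terms.append(loss)
            total = batch_terms[0]
            for term in batch_terms[1:]:
                total = total + term
            total = total / float(len(batch_terms))
            total.backward()
            opt.step(lr)
            epoch_losses.append(total.item())

        # validation: center crop, balanced smoothed CE without entropy term
        val_terms = []
        for v in val_vols:
            data, ind = _cropped_sample(v, grid, center_spec, layers)
            out = forward_sample(state, data, ind)
            val_terms.append(
                t_classification_loss(out["y_hat"], int(v.label), loss_cfg).item()
            )
        val_loss = float(np.mean(val_terms))
        history.append(
            {
                "epoch": epoch,
                "lr": lr,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
            }
        )
        if val_loss < best_loss:
            best_loss, best_snap, best_epoch = val_loss, _snapshot(state), epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve > cfg.patience:
                break

    _restore(state, best_snap)
    scores = predict_scores(state, val_vols, crop_size=cfg.crop_size, prepared=True)
    try:
        acc, auroc = evaluate(scores, val_labels)
    except ValueError:
        acc, auroc = float("nan"), float("nan")
    return FoldResult(
        fold_index=fold_index,
        best_val_loss=best_loss,
        state=state,
        epoch_stopped=history[-1]["epoch"],
        history=history,
        metrics={
            "fold": fold_index,
            "acc": acc,
            "auroc": auroc,
            "val_loss": best_loss,
            "epoch_stopped": history[-1]["epoch"],
        },
    )


def cross_validate(
    volumes: Sequence[Volume],
    model_cfg: dict,
    cfg: TrainConfig,
    val_fraction: float = 0.2,
) -> list[FoldResult]:
    """Stratified k-fold CV; an inner validation split is carved from each
    training portion for early stopping, and metrics are reported on the
    held-out fold."""
    labels = np.asarray([int(v.label) for v in volumes])
    counts = np.bincount(labels, minlength=2)
    if counts.min() < cfg.folds:
        raise ValueError(
            f"need at least {cfg.folds} samples per class, got {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    results = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(labels, labels)):
        n_val = min(max(2, round(val_fraction * len(train_idx))), len(train_idx) - 2)
        tr_idx, val_idx = train_test_split(
            train_idx,
            test_size=n_val,
            stratify=labels[train_idx],
            random_state=cfg.seed + fold,
        )
        res = train_fold(
            [volumes[i] for i in tr_idx],
            [volumes[i] for i in val_idx],
            model_cfg,
            cfg,
            fold_index=fold,
        )
        test_vols = [volumes[i] for i in test_idx]
        scores = predict_scores(res.state, test_vols, crop_size=cfg.crop_size)
        acc, auroc = evaluate(scores, labels[test_idx])
        res.metrics.update({"acc": acc, "auroc": auroc})
        results.append(res)
    return results


def summarize_folds(results: Sequence[FoldResult]) -> dict:
    accs = [r.metrics["acc"] for r in results]
    aurocs = [r.metrics["auroc"] for r in results]
    return {
        "acc_mean": float(np.mean(accs)),
        "acc_sd": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        "auroc_mean": float(np.mean(aurocs)),
        "auroc_sd": float(np.std(aurocs, ddof=1)) if len(aurocs) > 1 else 0.0,
    }


def transfer_init(
    source: ModelState, gating_mode: str | None = None, spec: EncoderSpec | None = None
) -> ModelState:
    """Copy all trained parameters to initialize a new task (optimizer fresh).

    The source and target must share the encoder architecture and gating
    mode; transfer across patch sizes is an architecture mismatch.
    """
    gating_mode = gating_mode or source.gating_mode
    spec = spec or source.spec
    if spec != source.spec:
        raise ValueError(
            f"architecture mismatch: source {source.spec}, target {spec}"
        )
    if gating_mode != source.gating_mode:
        raise ValueError(
            f"gating mode mismatch: source {source.gating_mode}, target {gating_mode}"
        )
    target = build_model(
        spec, gating_mode=gating_mode, seed=source.seed, fixed_gate=source.fixed_gate
    )
    for bn, params in source.branches().items():
        for k, t in params.items():
            target.branches()[bn][k].data = t.data.copy()
    return target
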