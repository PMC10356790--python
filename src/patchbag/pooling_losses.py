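"""Image-level aggregation, the training objective, and evaluation metrics.

Aggregation (the MIL pooling step) has two forms.  Global average pooling
treats every patch alike:

    z = (1/whd) * sum_ijk x~_ijk

Gate-weighted pooling normalizes by the total gate mass so that *how much*
of the brain is gated does not change the scale of the image response:

    z = sum_ijk g_ijk * x~_ijk / sum_ijk g_ijk,      e_ijk = g_ijk * x~_ijk

The per-position products e form the patch-level class evidence map.  The
posterior is y^ = sigmoid(z).

The objective combines a balanced, label-smoothed cross-entropy

    L_cls = -beta * y_LS * log(y^) - (1 - beta) * (1 - y_LS) * log(1 - y^)

with beta = (#negatives)/(#total) of the training split and smoothed
targets y_LS in {0.1, 0.9}, and a gate-entropy regularizer

    H(G) = -(1/whd) * sum_ijk [g log g + (1-g) log(1-g)],   L_ent = -H(G)

so L_total = L_cls + lambda * L_ent.  Maximizing gate entropy keeps region
exploration open early in training; because G depends only on coordinates,
L_ent can only move the gating-branch parameters (pi, rho) — a structural
fact, asserted by tests rather than enforced by masking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from . import nn
from .model import GateMap, ResponseMap

__all__ = [
    "EvidenceMap",
    "Prediction",
    "LossConfig",
    "gap_pool",
    "gated_pool",
    "classification_loss",
    "gate_entropy",
    "total_loss",
    "compute_beta",
    "evaluate",
]

_EPS = 1e-12  # probability clamp for all logarithms
_GATE_MASS_TOL = 1e-8


@dataclass
class EvidenceMap:
    """Patch-level class evidence e = g * x~; positive values favor y=1."""

    values: np.ndarray


@dataclass
class Prediction:
    """Image-level raw response z and posterior y^ = sigmoid(z)."""

    z: float
    y_hat: float


@dataclass
class LossConfig:
    """beta: negative-class frequency; lam: entropy weight; smoothed targets."""

    beta: float = 0.5
    lam: float = 0.01
    smooth_targets: tuple[float, float] = (0.1, 0.9)

    def __post_init__(self):
        if not 0.0 < self.beta < 1.0:
            raise ValueError(f"beta must lie in (0,1), got {self.beta}")
        if self.lam < 0:
            raise ValueError(f"lambda must be >= 0, got {self.lam}")

    def smooth(self, y: int) -> float:
        return self.smooth_targets[1] if y == 1 else self.smooth_targets[0]


def _vals(m) -> np.ndarray:
    if isinstance(m, (ResponseMap, GateMap, EvidenceMap)):
        return m.values
    return np.asarray(m)


# ---------------------------------------------------------------------------
# Tensor-level forms (differentiable; used inside the training graph)


def t_gap_pool(r: nn.Tensor) -> nn.Tensor:
    return nn.tmean(r)


def t_gated_pool(r: nn.Tensor, g: nn.Tensor) -> nn.Tensor:
    mass = nn.tsum(g)
    if float(mass.data) <= _GATE_MASS_TOL:
        raise ValueError("degenerate gate: total gate mass is ~0")
    return nn.tsum(g * r) / mass


def t_classification_loss(y_hat: nn.Tensor, y: int, cfg: LossConfig) -> nn.Tensor:
    y_ls = cfg.smooth(int(y))
    p = nn.clip(y_hat, _EPS, 1.0 - _EPS)
    return -(cfg.beta * y_ls) * nn.log(p) - ((1.0 - cfg.beta) * (1.0 - y_ls)) * nn.log(
        1.0 - p
    )


def t_gate_entropy(g: nn.Tensor) -> nn.Tensor:
    p = nn.clip(g, _EPS, 1.0 - _EPS)
    return -nn.tmean(p * nn.log(p) + (1.0 - p) * nn.log(1.0 - p))


# ---------------------------------------------------------------------------
# public numpy-facing operations


def gap_pool(r) -> float:
    """Eq.-style mean pooling of patch responses."""
    v = _vals(r)
    if v.size == 0:
        raise ValueError("cannot pool an empty response map")
    return float(v.mean())


def gated_pool(r, g) -> tuple[float, EvidenceMap]:
    """Normalized gate-weighted pooling; returns z and the evidence map."""
    rv, gv = _vals(r), _vals(g)
    if rv.shape != gv.shape:
        raise ValueError(f"response {rv.shape} and gate {gv.shape} extents differ")
    mass = float(gv.sum())
    if mass <= _GATE_MASS_TOL:
        raise ValueError("degenerate gate: total gate mass is ~0")
    e = (gv * rv).astype(np.float64)
    return float(e.sum() / mass), EvidenceMap(values=e.astype(np.float32))


def classification_loss(y_hat, y, cfg: LossConfig) -> float:
    """Balanced label-smoothed BCE; arrays are reduced by the mean."""
    y_hat = np.atleast_1d(np.asarray(y_hat, dtype=np.float64))
    y = np.atleast_1d(np.asarray(y, dtype=int))
    p = np.clip(y_hat, _EPS, 1.0 - _EPS)
    y_ls = np.where(y == 1, cfg.smooth_targets[1], cfg.smooth_targets[0])
    losses = -cfg.beta * y_ls * np.log(p) - (1.0 - cfg.beta) * (1.0 - y_ls) * np.log(
        1.0 - p
    )
    return float(losses.mean())


def gate_entropy(g) -> float:
    """Mean binary entropy of the gate map, in nats (max ln 2)."""
    p = np.clip(_vals(g).astype(np.float64), _EPS, 1.0 - _EPS)
    return float(-(p * np.log(p) + (1.0 - p) * np.log(1.0 - p)).mean())


def total_loss(y_hat, y, g, cfg: LossConfig) -> float:
    """L_cls + lambda * L_ent (L_ent = -H(G)); gate may be None in gap mode."""
    l_cls = classification_loss(y_hat, y, cfg)
    if g is None or cfg.lam == 0:
        return l_cls
    return l_cls + cfg.lam * (-gate_entropy(g))


def compute_beta(labels) -> float:
    """Negative-class frequency of the training split."""
    y = np.asarray(labels, dtype=int)
    if y.size == 0:
        raise ValueError("empty label list")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute beta")
    return float((y == 0).sum() / y.size)


def evaluate(scores, labels) -> tuple[float, float]:
    """Accuracy at threshold 0.5 and rank-statistic (Mann-Whitney) AUROC."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC undefined: only one class present")
    acc = float(((s >= 0.5).astype(int) == y).mean())
    return acc, float(roc_auc_score(y, s))
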