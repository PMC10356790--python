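"""Differentiable whole-sample forward pass shared by training and export."""

from __future__ import annotations

import numpy as np

from . import nn
from .geometry import PositionIndicator
from .model import ModelState, classifier_responses, encoder_features
from .model import feature_gate_logits, gate_logits
from .pooling_losses import t_gap_pool, t_gated_pool


def forward_sample(
    state: ModelState,
    x: np.ndarray,
    indicator: PositionIndicator | None = None,
) -> dict:
    """Run both branches on one normalized cropped volume.

    Returns tensors: ``r`` (patch responses), ``g`` (gate, None in gap
    mode), ``z`` (image-level response) and ``y_hat`` (posterior).  In
    ``position_gate`` mode an indicator matching the crop is required.
    """
    xt = nn.Tensor(np.asarray(x, dtype=np.float32)[None])
    feats = encoder_features(state, xt)
    r = classifier_responses(state, feats)

    mode = state.gating_mode
    if mode == "gap":
        g = None
        z = t_gap_pool(r)
    elif mode == "position_gate":
        if indicator is None:
            raise ValueError("position_gate mode needs a position indicator")
        if indicator.extent != r.shape:
            raise ValueError(
                f"indicator extent {indicator.extent} != response extent {r.shape}"
            )
        coords = nn.Tensor(np.moveaxis(indicator.coords, -1, 0))
        g = nn.sigmoid(gate_logits(state, coords))
        z = t_gated_pool(r, g)
    elif mode == "feature_gate":
        g = nn.sigmoid(feature_gate_logits(state, feats))
        z = t_gated_pool(r, g)
    elif mode == "fixed_gate":
        if state.fixed_gate is None:
            raise ValueError("fixed_gate mode has no gate map attached")
        if state.fixed_gate.shape != r.shape:
            raise ValueError(
                f"fixed gate extent {state.fixed_gate.shape} != responses {r.shape}"
            )
        g = nn.Tensor(state.fixed_gate)  # constant: no gradient flows into it
        z = t_gated_pool(r, g)
    else:  # pragma: no cover - guarded at build time
        raise ValueError(f"unknown gating mode {mode}")

    return {"r": r, "g": g, "z": z, "y_hat": nn.sigmoid(z)}
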