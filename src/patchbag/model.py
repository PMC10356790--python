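"""The two-branch network.

Patch-level prediction branch: an encoder with a deliberately limited
receptive field (a BagNet-style stack: conv 5/stride 2 stem, max-pool
3/stride 2, four residual blocks at 32/64/128/256 channels, all valid
padding) followed by a point-wise linear classifier that turns each
256-vector into one scalar patch response x~.  Because every layer after
the stem+pool is stride 1, the output grid spacing (jump) is 4 voxels and
the receptive field — the patch size s — is set purely by how many 3^3
convolutions the residual blocks contain:

    s = 9 + 8 * (# of 3^3 convolutions)

giving the supported family s in {9, 17, 25, 41, 57} with 0/1/2/4/6 such
convolutions, allocated front to back, at most two per block.

Position-based gating branch: a point-wise MLP over the normalized
patch-center coordinates (position embedding 3->128->256 with ReLUs, gate
network 256->128->16 with one ReLU, channel mean, sigmoid) producing a
discriminative probability map g in [0,1] per patch position.  Because it
sees only coordinates, the map is identical for every subject under the
same crop — it encodes *where* disease-discriminative patches consistently
sit in template space, not what any one image contains.

Gating modes: ``position_gate`` (the full method), ``feature_gate`` (same
gate topology fed with encoder features instead of coordinates),
``gap`` (no gate; plain mean pooling), and ``fixed_gate`` (a user-supplied
constant map, e.g. a precomputed anatomical prior).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from . import nn
from .geometry import LayerGeom, PositionIndicator, compose_geometry, output_extent

__all__ = [
    "PATCH_SIZES",
    "EncoderSpec",
    "ModelState",
    "ResponseMap",
    "GateMap",
    "build_model",
    "patch_responses",
    "gate_forward",
    "feature_gate_forward",
    "save_checkpoint",
    "load_checkpoint",
]

#: patch size -> number of 3^3 convolutions in the residual blocks
_N3 = {9: 0, 17: 1, 25: 2, 41: 4, 57: 6}
PATCH_SIZES = tuple(sorted(_N3))

GATING_MODES = ("gap", "position_gate", "feature_gate", "fixed_gate")


@dataclass(frozen=True)
class EncoderSpec:
    """Declarative encoder description; all geometry derives from it."""

    patch_size: int = 9
    stem_channels: int = 32
    block_channels: tuple[int, ...] = (32, 64, 128, 256)

    def __post_init__(self):
        if self.patch_size not in _N3:
            raise ValueError(
                f"unsupported patch_size {self.patch_size}; choose from {PATCH_SIZES}"
            )

    def block_kernels(self) -> list[tuple[int, int]]:
        """Kernel sizes (two convs per block), 3^3 convs front-loaded."""
        n3 = _N3[self.patch_size]
        kernels = []
        slot = 0
        for _ in self.block_channels:
            pair = []
            for _ in range(2):
                pair.append(3 if slot < n3 else 1)
                slot += 1
            kernels.append(tuple(pair))
        return kernels

    def layer_geoms(self) -> list[LayerGeom]:
        geoms = [LayerGeom(kernel=5, stride=2), LayerGeom(kernel=3, stride=2)]
        for ka, kb in self.block_kernels():
            geoms += [LayerGeom(kernel=ka), LayerGeom(kernel=kb)]
        return geoms

    @property
    def feature_dim(self) -> int:
        return self.block_channels[-1]


@dataclass
class ResponseMap:
    """Raw (pre-sigmoid) patch-level responses x~ on the (w, h, d) grid."""

    values: np.ndarray


@dataclass
class GateMap:
    """Per-patch gate probabilities g in [0, 1] on the (w, h, d) grid."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float32)
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("gate values must lie in [0, 1]")
        self.values = v


@dataclass
class ModelState:
    """All trainable parameters, partitioned into the four branches.

    ``phi``: encoder, ``psi``: classifier, ``pi``: position embedding,
    ``rho``: gate network.  Every trainable tensor belongs to exactly one
    partition; ``gap`` mode has no pi/rho, ``feature_gate`` no pi, and
    ``fixed_gate`` replaces the gating branch with a constant map.
    """

    spec: EncoderSpec
    gating_mode: str
    seed: int
    phi: dict[str, nn.Tensor] = field(default_factory=dict)
    psi: dict[str, nn.Tensor] = field(default_factory=dict)
    pi: dict[str, nn.Tensor] = field(default_factory=dict)
    rho: dict[str, nn.Tensor] = field(default_factory=dict)
    fixed_gate: np.ndarray | None = None

    def branches(self) -> dict[str, dict[str, nn.Tensor]]:
        return {"phi": self.phi, "psi": self.psi, "pi": self.pi, "rho": self.rho}

    def parameters(self) -> Iterable[nn.Tensor]:
        for params in self.branches().values():
            yield from params.values()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _param(rng, shape, fan_in, name):
    return nn.Tensor(nn.he_normal(rng, shape, fan_in), requires_grad=True, name=name)


def _zeros(shape, name):
    return nn.Tensor(np.zeros(shape, dtype=np.float32), requires_grad=True, name=name)


def _ones(shape, name):
    return nn.Tensor(np.ones(shape, dtype=np.float32), requires_grad=True, name=name)


def _conv_block_params(rng, prefix, cin, cout, k):
    return {
        f"{prefix}.w": _param(rng, (cout, cin, k, k, k), cin * k**3, f"{prefix}.w"),
        f"{prefix}.b": _zeros((cout,), f"{prefix}.b"),
        f"{prefix}.gamma": _ones((cout,), f"{prefix}.gamma"),
        f"{prefix}.beta": _zeros((cout,), f"{prefix}.beta"),
    }


def _mlp_params(rng, prefix, dims):
    out = {}
    for i, (cin, cout) in enumerate(zip(dims[:-1], dims[1:])):
        out[f"{prefix}.conv{i}.w"] = _param(
            rng, (cout, cin, 1, 1, 1), cin, f"{prefix}.conv{i}.w"
        )
        out[f"{prefix}.conv{i}.b"] = _zeros((cout,), f"{prefix}.conv{i}.b")
    return out


def build_model(
    spec: EncoderSpec,
    gating_mode: str = "position_gate",
    seed: int = 0,
    fixed_gate: np.ndarray | None = None,
) -> ModelState:
    """He-initialize all branches from a single seed (bit-reproducible)."""
    if gating_mode not in GATING_MODES:
        raise ValueError(f"unknown gating_mode {gating_mode!r}; choose {GATING_MODES}")
    if gating_mode == "fixed_gate" and fixed_gate is None:
        raise ValueError("fixed_gate mode requires a gate map")
    rng = np.random.default_rng(seed)
    state = ModelState(spec=spec, gating_mode=gating_mode, seed=seed)
    if fixed_gate is not None:
        state.fixed_gate = np.asarray(fixed_gate, dtype=np.float32)

    # encoder phi: stem + four residual blocks
    state.phi.update(_conv_block_params(rng, "stem", 1, spec.stem_channels, 5))
    cin = spec.stem_channels
    for bi, (cout, (ka, kb)) in enumerate(zip(spec.block_channels, spec.block_kernels())):
        state.phi.update(_conv_block_params(rng, f"block{bi}.conv0", cin, cout, ka))
        state.phi.update(_conv_block_params(rng, f"block{bi}.conv1", cout, cout, kb))
        if cin != cout:
            state.phi[f"block{bi}.proj.w"] = _param(
                rng, (cout, cin, 1, 1, 1), cin, f"block{bi}.proj.w"
            )
            state.phi[f"block{bi}.proj.b"] = _zeros((cout,), f"block{bi}.proj.b")
        cin = cout

    # classifier psi: one point-wise linear map f -> 1
    state.psi.update(_mlp_params(rng, "classifier", (spec.feature_dim, 1)))

    if gating_mode == "position_gate":
        state.pi.update(_mlp_params(rng, "embed", (3, 128, 256)))
        state.rho.update(_mlp_params(rng, "gate", (256, 128, 16)))
    elif gating_mode == "feature_gate":
        state.rho.update(
            _mlp_params(rng, "gate", (spec.feature_dim, 128, 16))
        )
    return state


# ---------------------------------------------------------------------------
# forward passes (Tensor-level, used by training; numpy wrappers below)


def _block_forward(p, prefix, x, stride=1):
    h = nn.conv3d(x, p[f"{prefix}.w"], p[f"{prefix}.b"], stride=stride)
    h = nn.instance_norm(h, p[f"{prefix}.gamma"], p[f"{prefix}.beta"])
    return h


def encoder_features(state: ModelState, x: nn.Tensor) -> nn.Tensor:
    """Run the encoder phi on a (1, X, Y, Z) tensor -> (f, w, h, d)."""
    p = state.phi
    h = nn.relu(_block_forward(p, "stem", x, stride=2))
    h = nn.maxpool3d(h, kernel=3, stride=2)
    for bi, (ka, kb) in enumerate(state.spec.block_kernels()):
        y = nn.relu(_block_forward(p, f"block{bi}.conv0", h))
        y = _block_forward(p, f"block{bi}.conv1", y)
        margin = (ka - 1) // 2 + (kb - 1) // 2
        sc = nn.crop_center(h, margin)
        if f"block{bi}.proj.w" in p:
            sc = nn.conv3d(sc, p[f"block{bi}.proj.w"], p[f"block{bi}.proj.b"])
        h = nn.relu(y + sc)
    return h


def classifier_responses(state: ModelState, features: nn.Tensor) -> nn.Tensor:
    """Point-wise classifier psi: (f, w, h, d) -> (w, h, d) raw responses."""
    p = state.psi
    out = nn.conv3d(features, p["classifier.conv0.w"], p["classifier.conv0.b"])
    return nn.channel_mean(out)  # single-channel mean == squeeze


def _gate_mlp(params, prefix_dims, x, relu_last=False):
    h = x
    n = len(prefix_dims)
    for i, prefix in enumerate(prefix_dims):
        h = nn.conv3d(h, params[f"{prefix}.w"], params[f"{prefix}.b"])
        if i < n - 1 or relu_last:
            h = nn.relu(h)
    return h


def gate_logits(state: ModelState, coords: nn.Tensor) -> nn.Tensor:
    """Position embedding + gate network on (3, w, h, d) coordinates."""
    h = _gate_mlp(state.pi, ("embed.conv0", "embed.conv1"), coords, relu_last=True)
    h = _gate_mlp(state.rho, ("gate.conv0", "gate.conv1"), h)
    return nn.channel_mean(h)


def feature_gate_logits(state: ModelState, features: nn.Tensor) -> nn.Tensor:
    h = _gate_mlp(state.rho, ("gate.conv0", "gate.conv1"), features)
    return nn.channel_mean(h)


# ---------------------------------------------------------------------------
# numpy-facing operations


def _as_input_tensor(x) -> nn.Tensor:
    from .io_volumes import Volume

    if isinstance(x, Volume):
        x = x.data
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {x.shape}")
    return nn.Tensor(x[None])


def patch_responses(state: ModelState, x) -> ResponseMap:
    """Patch-level responses for one normalized, cropped volume."""
    xt = _as_input_tensor(x)
    ext = xt.shape[1:]
    output_extent(ext, state.spec.layer_geoms())  # raises input-too-small
    feats = encoder_features(state, xt)
    return ResponseMap(values=classifier_responses(state, feats).data.copy())


def gate_forward(state: ModelState, indicator: PositionIndicator) -> GateMap:
    """Gate probabilities from patch-center coordinates alone."""
    if state.gating_mode != "position_gate":
        raise ValueError(f"gate_forward requires position_gate mode, not {state.gating_mode}")
    coords = nn.Tensor(np.moveaxis(indicator.coords, -1, 0))
    return GateMap(values=nn.sigmoid(gate_logits(state, coords)).data.copy())


def feature_gate_forward(state: ModelState, features: np.ndarray) -> GateMap:
    """Gate probabilities from encoder features (subject-specific variant)."""
    if state.gating_mode != "feature_gate":
        raise ValueError(
            f"feature_gate_forward requires feature_gate mode, not {state.gating_mode}"
        )
    f = np.asarray(features, dtype=np.float32)
    if f.ndim != 4:
        raise ValueError(f"features must be (f, w, h, d), got {f.shape}")
    if f.shape[0] != state.spec.feature_dim:
        raise ValueError(
            f"feature channels {f.shape[0]} != encoder feature_dim {state.spec.feature_dim}"
        )
    return GateMap(values=nn.sigmoid(feature_gate_logits(state, nn.Tensor(f))).data.copy())


# ---------------------------------------------------------------------------
# checkpoints: flat npz archive + JSON sidecar


def save_checkpoint(state: ModelState, path: str | Path) -> None:
    path = Path(path)
    arrays = {}
    for bname, params in state.branches().items():
        for pname, t in params.items():
            arrays[f"{bname}/{pname}"] = t.data
    if state.fixed_gate is not None:
        arrays["fixed_gate"] = state.fixed_gate
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {
        "patch_size": state.spec.patch_size,
        "stem_channels": state.spec.stem_channels,
        "block_channels": list(state.spec.block_channels),
        "gating_mode": state.gating_mode,
        "seed": state.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> ModelState:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = EncoderSpec(
        patch_size=meta["patch_size"],
        stem_channels=meta["stem_channels"],
        block_channels=tuple(meta["block_channels"]),
    )
    with np.load(path.with_suffix(".npz")) as arc:
        fixed = arc["fixed_gate"] if "fixed_gate" in arc.files else None
        state = build_model(
            spec, gating_mode=meta["gating_mode"], seed=meta["seed"], fixed_gate=fixed
        )
        for bname, params in state.branches().items():
            for pname, t in params.items():
                t.data = arc[f"{bname}/{pname}"].astype(np.float32)
    return state
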