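"""Export of gate and patch-level class-evidence maps back to template space.

The patch grid lives at stride ``jump`` with its first center at
``crop_origin + offset``; to overlay a (w, h, d) map on the original volume
we place each value at its patch-center voxel and interpolate linearly
between centers.  Voxels outside the patch-center bounding box get a fill
value of 0 plus an explicit validity mask, so downstream thresholding can
distinguish "no evidence" from "outside the evaluated region".

Evidence is exported pre-normalization (e = g * x~, positive values support
the positive class); the normalizer sum(g) is stored in the JSON prediction
record so the image-level response z can be re-aggregated exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .geometry import GeomState, make_coordinate_grid, extract_position_indicator
from .io_volumes import CropSpec, Volume, crop, normalize, sample_crop, write_volume
from .model import ModelState
from .pooling_losses import EvidenceMap, Prediction
from ._forward import forward_sample

__all__ = ["OverlayProduct", "upsample_map", "export_evidence"]


@dataclass
class OverlayProduct:
    """A patch-grid map resampled to full resolution, with provenance."""

    data: np.ndarray
    valid: np.ndarray  # True where the voxel lies inside the patch-center hull
    geometry: dict  # rf, jump, offset, crop origin — enough to regenerate


def upsample_map(
    values: np.ndarray,
    geom: GeomState,
    crop_spec: CropSpec,
    target_extent: Sequence[int],
) -> OverlayProduct:
    """Trilinearly interpolate a patch-grid map onto the full voxel grid."""
    v = np.asarray(values, dtype=np.float32)
    if v.ndim != 3:
        raise ValueError(f"expected a 3D patch-grid map, got shape {v.shape}")
    target_extent = tuple(int(n) for n in target_extent)
    centers = [
        np.asarray(crop_spec.origin[ax]) + geom.offset + np.arange(v.shape[ax]) * geom.jump
        for ax in range(3)
    ]
    for ax, c in enumerate(centers):
        if c[-1] > target_extent[ax] - 1 + 1e-9:
            raise ValueError(
                f"patch centers overrun target extent on axis {ax}: "
                f"{c[-1]} > {target_extent[ax] - 1}"
            )
    interp = RegularGridInterpolator(centers, v, method="linear", bounds_error=False)
    axes = [np.arange(n, dtype=float) for n in target_extent]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    out = interp(pts)
    valid = np.ones(target_extent, dtype=bool)
    for ax, c in enumerate(centers):
        coord = pts[..., ax]
        valid &= (coord >= c[0]) & (coord <= c[-1])
    out = np.where(valid, out, 0.0).astype(np.float32)
    return OverlayProduct(
        data=out,
        valid=valid,
        geometry={
            "rf": geom.rf,
            "jump": geom.jump,
            "offset": geom.offset,
            "crop_origin": list(crop_spec.origin),
        },
    )


def export_evidence(
    state: ModelState,
    v: Volume,
    crop_size: Sequence[int] | None = None,
    out_dir: str | Path | None = None,
    prefix: str = "subject",
):
    """Run both branches on one volume and package the interpretable outputs.

    Returns ``(gate_map, evidence_map, prediction, overlays)`` where
    ``gate_map`` is None in gap mode and ``overlays`` maps names to
    :class:`OverlayProduct`.  With ``out_dir`` set, writes the overlays as
    NIfTI (aligned to the input affine) and the prediction record as JSON.
    """
    from .geometry import compose_geometry
    from .model import GateMap

    vn = normalize(v)
    spec_c = (
        sample_crop(vn.extent, crop_size, mode="center")
        if crop_size is not None
        else CropSpec(origin=(0, 0, 0), size=vn.extent)
    )
    data = crop(vn, spec_c).data
    layers = state.spec.layer_geoms()
    grid = make_coordinate_grid(vn.extent).crop(spec_c.origin, spec_c.size)
    indicator = extract_position_indicator(grid, layers)
    out = forward_sample(state, data, indicator)

    geom = compose_geometry(layers)
    r = out["r"].data
    if out["g"] is None:
        gate_map = None
        evidence = EvidenceMap(values=(r / r.size).astype(np.float32))
        sum_g = float(r.size)
    else:
        g = out["g"].data
        gate_map = GateMap(values=g.copy())
        evidence = EvidenceMap(values=(g * r).astype(np.float32))
        sum_g = float(g.sum())
    pred = Prediction(z=out["z"].item(), y_hat=out["y_hat"].item())

    overlays = {
        "evidence": upsample_map(evidence.values, geom, spec_c, vn.extent)
    }
    if gate_map is not None:
        overlays["gate"] = upsample_map(gate_map.values, geom, spec_c, vn.extent)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, ov in overlays.items():
            write_volume(
                Volume(data=ov.data, affine=v.affine), out_dir / f"{prefix}_{name}.nii"
            )
            write_volume(
                Volume(data=ov.valid.astype(np.float32), affine=v.affine),
                out_dir / f"{prefix}_{name}_valid.nii",
            )
        record = {
            "z": pred.z,
            "y_hat": pred.y_hat,
            "sum_g": sum_g,
            "gating_mode": state.gating_mode,
            "geometry": overlays["evidence"].geometry,
        }
        (out_dir / f"{prefix}_prediction.json").write_text(json.dumps(record, indent=2))

    return gate_map, evidence, pred, overlays
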