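"""Synthetic template-aligned phantoms with a planted, position-consistent lesion.

The generator emulates the structure the gating method assumes about real
cohorts: every scan lives on one common grid; the positive class differs
from the negative class only inside a fixed region (the "lesion", an
additive intensity sphere at the same template position in every positive
subject); and both classes carry label-irrelevant "distractor" spheres at
random positions, visually identical to the lesion.  Because lesion and
distractors share amplitude and radius, patch *appearance* alone barely
separates the classes — position is the discriminative cue, which is
precisely what the coordinate-driven gate can exploit and plain mean
pooling cannot.

Every volume shares one smooth template background (what affine alignment
to a common template leaves in common across subjects) plus a weaker
per-subject smooth deviation standing in for residual anatomical
variability.  Each subject index yields a matched pair: one negative and
one positive volume built from the same deviation, sensor noise, and
distractor placement, differing exactly by the lesion sphere.  This makes
the class difference's support exact (not merely statistical) and keeps
cohort generation bit-reproducible from the seed.

Default condition: 48^3 grid, 50 subjects per class, unit-variance shared
background and 0.3-sd subject deviation (both Gaussian-smoothed at sigma
3), lesion and 8 distractors of radius 5 at amplitude 0.5 (above the
subject variability, identical to each other), sensor noise sd 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .geometry import LayerGeom, compose_geometry
from .io_volumes import Volume, write_manifest, write_volume
from .model import GateMap

__all__ = ["PhantomConfig", "generate_cohort", "localization_score", "write_cohort"]


@dataclass
class PhantomConfig:
    extent: tuple[int, int, int] = (48, 48, 48)
    n_per_class: int = 50
    lesion_center: tuple[int, int, int] = (30, 18, 24)
    lesion_radius: float = 5.0
    lesion_amplitude: float = 0.5
    n_distractors: int = 8
    distractor_amplitude: float = 0.5
    distractor_radius: float = 5.0
    noise_sd: float = 0.05
    smoothness_sigma: float = 3.0
    subject_variation: float = 0.3  # sd of the per-subject smooth deviation
    seed: int = 0

    def __post_init__(self):
        c = np.asarray(self.lesion_center, float)
        e = np.asarray(self.extent, float)
        if np.any(c - self.lesion_radius < 0) or np.any(c + self.lesion_radius > e - 1):
            raise ValueError(
                f"lesion sphere (center {self.lesion_center}, radius "
                f"{self.lesion_radius}) extends outside extent {self.extent}"
            )


def _sphere_mask(extent, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in extent)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def generate_cohort(cfg: PhantomConfig) -> tuple[list[Volume], np.ndarray]:
    """Generate the cohort plus the ground-truth lesion mask on the full grid.

    Returns ``2 * n_per_class`` volumes (labels attached, negatives first
    within each matched pair) and the boolean lesion mask.
    """
    ext = tuple(int(n) for n in cfg.extent)
    lesion = _sphere_mask(ext, cfg.lesion_center, cfg.lesion_radius).astype(np.float32)

    def smooth_field(rng):
        f = gaussian_filter(rng.standard_normal(ext).astype(np.float32), cfg.smoothness_sigma)
        sd = f.std()
        return f / sd if sd > 0 else f

    template = smooth_field(np.random.default_rng([cfg.seed, 2**20]))
    volumes: list[Volume] = []
    for i in range(cfg.n_per_class):
        rng = np.random.default_rng([cfg.seed, i])
        deviation = cfg.subject_variation * smooth_field(rng)
        noise = (rng.standard_normal(ext) * cfg.noise_sd).astype(np.float32)
        base = template + deviation + noise
        r = cfg.distractor_radius
        for _ in range(cfg.n_distractors):
            center = [rng.uniform(r, n - 1 - r) for n in ext]
            base = base + cfg.distractor_amplitude * _sphere_mask(ext, center, r)
        neg = base.astype(np.float32)
        pos = (base + cfg.lesion_amplitude * lesion).astype(np.float32)
        volumes.append(Volume(data=neg, label=0))
        volumes.append(Volume(data=pos, label=1))
    return volumes, lesion.astype(bool)


def localization_score(
    g: GateMap | np.ndarray,
    mask: np.ndarray,
    layers: Sequence[LayerGeom],
    crop_origin: Sequence[int] = (0, 0, 0),
) -> float:
    """Fraction of total gate mass on patches whose footprint touches the mask.

    Each patch-grid position (i, j, k) covers the input box centered at
    ``crop_origin + offset + index * jump`` with side ``rf``; the score is
    sum of g over mask-overlapping patches divided by sum of g.  A uniform
    gate scores exactly the fraction of overlapping patches, which is the
    chance baseline.
    """
    gv = np.asarray(g.values if isinstance(g, GateMap) else g, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    geom = compose_geometry(layers)
    origin = np.asarray(crop_origin, int)
    last_center = origin + geom.offset + (np.asarray(gv.shape) - 1) * geom.jump
    if np.any(last_center > np.asarray(mask.shape) - 1 + 1e-9):
        raise ValueError(
            f"gate extent {gv.shape} with crop origin {tuple(origin)} overruns "
            f"the mask grid {mask.shape}"
        )
    half = (geom.rf - 1) / 2
    # integral volume for O(1) box queries
    integ = np.zeros(tuple(n + 1 for n in mask.shape), dtype=np.int64)
    integ[1:, 1:, 1:] = mask.astype(np.int64).cumsum(0).cumsum(1).cumsum(2)

    def box_sum(lo, hi):
        # lo/hi: integer arrays (..., 3), inclusive box clipped to the grid
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, np.asarray(mask.shape) - 1)
        x0, y0, z0 = lo[..., 0], lo[..., 1], lo[..., 2]
        x1, y1, z1 = hi[..., 0] + 1, hi[..., 1] + 1, hi[..., 2] + 1
        return (
            integ[x1, y1, z1]
            - integ[x0, y1, z1]
            - integ[x1, y0, z1]
            - integ[x1, y1, z0]
            + integ[x0, y0, z1]
            + integ[x0, y1, z0]
            + integ[x1, y0, z0]
            - integ[x0, y0, z0]
        )

    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in gv.shape], indexing="ij"), axis=-1
    )
    centers = origin + geom.offset + idx * geom.jump
    lo = np.ceil(centers - half).astype(int)
    hi = np.floor(centers + half).astype(int)
    overlaps = box_sum(lo, hi) > 0
    total = gv.sum()
    if total <= 0:
        raise ValueError("gate map has no mass")
    return float(gv[overlaps].sum() / total)


def write_cohort(
    volumes: Sequence[Volume],
    mask: np.ndarray,
    out_dir: str | Path,
    prefix: str = "phantom",
) -> Path:
    """Write NIfTI volumes, the lesion mask, and a manifest CSV; return its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, v in enumerate(volumes):
        name = f"{prefix}_{i:04d}.nii"
        write_volume(v, out_dir / name)
        rows.append(
            {"path": name, "label": int(v.label), "subject_id": f"subj{i:04d}", "split": ""}
        )
    write_volume(
        Volume(data=mask.astype(np.float32)), out_dir / f"{prefix}_lesion_mask.nii"
    )
    manifest = out_dir / "manifest.csv"
    write_manifest(pd.DataFrame(rows), manifest)
    return manifest
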