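"""Template-aligned volume I/O, intensity normalization, and crop handling.

Volumes are assumed already affinely registered to a common template grid;
world coordinates never enter the model, so only the voxel array (and the
affine carried through for output alignment) matters.  All data is float32.

The pipeline order is normalize-then-crop: each image is standardized once
over its whole extent, so train/eval statistics do not depend on which crop
was sampled.  A :class:`CropSpec` applies identically to an image and to the
coordinate grid of matching extent (see :mod:`patchbag.geometry`), keeping
intensities and patch-center coordinates in lockstep under augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume",
    "CropSpec",
    "read_volume",
    "write_volume",
    "normalize",
    "crop",
    "sample_crop",
    "read_manifest",
    "write_manifest",
]


@dataclass
class Volume:
    """A 3D scalar image (the MIL "bag"), with optional affine and label."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    label: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def extent(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class CropSpec:
    """A corner-anchored sub-box: 0-based voxel origin plus size."""

    origin: tuple[int, int, int]
    size: tuple[int, int, int]

    def validate(self, extent: Sequence[int]) -> None:
        o, s, e = np.asarray(self.origin), np.asarray(self.size), np.asarray(extent)
        if np.any(o < 0) or np.any(s < 1):
            raise ValueError(f"invalid crop {self}")
        if np.any(o + s > e):
            raise ValueError(f"crop {self} out of bounds for extent {tuple(extent)}")


def read_volume(path: str | Path, label: int | None = None) -> Volume:
    """Read a NIfTI-1/2 file as a 3D :class:`Volume`.

    A trailing singleton fourth (temporal) dimension is squeezed; a genuine
    4D series is rejected, since the model consumes single structural scans.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        if data.shape[3] != 1:
            raise ValueError(
                f"{path}: expected a single 3D frame, got {data.shape[3]} frames"
            )
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D image, got {data.ndim}D")
    return Volume(data=data.astype(np.float32), affine=img.affine, label=label)


def write_volume(v: Volume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(v.data.astype(np.float32), v.affine), str(path))


def normalize(v: Volume) -> Volume:
    """Standardize the whole image to mean 0, standard deviation 1."""
    sd = float(v.data.std())
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("cannot normalize a constant (zero-variance) volume")
    out = (v.data - v.data.mean()) / sd
    return Volume(data=out.astype(np.float32), affine=v.affine, label=v.label)


def crop(v: Volume, spec: CropSpec) -> Volume:
    """Extract the sub-volume described by ``spec``; affine origin follows."""
    spec.validate(v.extent)
    o, s = spec.origin, spec.size
    data = v.data[o[0] : o[0] + s[0], o[1] : o[1] + s[1], o[2] : o[2] + s[2]]
    affine = v.affine.copy()
    affine[:3, 3] += affine[:3, :3] @ np.asarray(o, dtype=float)
    return Volume(data=data.copy(), affine=affine, label=v.label)


def sample_crop(
    extent: Sequence[int],
    size: Sequence[int],
    mode: str = "center",
    seed: int | None = None,
) -> CropSpec:
    """Draw a crop origin: uniform over valid origins, or the centered one.

    Training uses ``random`` crops for augmentation; evaluation uses the
    deterministic ``center`` crop.
    """
    e, s = np.asarray(extent, int), np.asarray(size, int)
    if np.any(s > e) or np.any(s < 1):
        raise ValueError(f"crop size {tuple(s)} exceeds extent {tuple(e)}")
    slack = e - s
    if mode == "center":
        origin = slack // 2
    elif mode == "random":
        rng = np.random.default_rng(seed)
        origin = np.array([rng.integers(0, m + 1) for m in slack])
    else:
        raise ValueError(f"unknown crop mode {mode!r}")
    return CropSpec(origin=tuple(int(x) for x in origin), size=tuple(int(x) for x in s))


# ---------------------------------------------------------------------------
# dataset manifests

_MANIFEST_COLS = ["path", "label", "subject_id", "split"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("path", "label") if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns {missing}")
    if not set(df["label"].unique()) <= {0, 1}:
        raise ValueError("manifest labels must be binary 0/1")
    base = Path(path).parent
    df = df.copy()
    df["path"] = [str((base / p)) if not Path(p).is_absolute() else p for p in df["path"]]
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in _MANIFEST_COLS if c in df.columns]
    df.to_csv(path, index=False, columns=cols)
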