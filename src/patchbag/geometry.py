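"""Receptive-field arithmetic and coordinate-grid bookkeeping.

A bag-of-patches encoder is a stack of valid-padding convolution/pooling
layers.  Three integers (per axis, but all layers here are isotropic)
summarize what one output unit sees in the input:

``rf``
    the extent of the input window (the patch size ``s``),
``jump``
    the input-index distance between the windows of adjacent output units,
``offset``
    the input index of the first output unit's patch center.

Folding layers ``(kernel k, stride t, padding p)`` front to back:

    jump' = jump * t
    rf'   = rf + (k - 1) * jump
    offset' = offset + ((k - 1)/2 - p) * jump

starting from ``rf=1, jump=1, offset=0``.  The same stack applied to the
normalized Cartesian coordinate grid yields the *position indicator*: the
coordinates of every patch center, which is what the position-based gating
branch consumes.  An independent gradient-support oracle (:func:`rf_oracle`)
measures rf and jump empirically so the closed-form calculus never has to be
trusted on faith.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn

__all__ = [
    "LayerGeom",
    "GeomState",
    "CoordinateGrid",
    "PositionIndicator",
    "compose_geometry",
    "output_extent",
    "make_coordinate_grid",
    "extract_position_indicator",
    "subsample_at_centers",
    "rf_oracle",
]


@dataclass(frozen=True)
class LayerGeom:
    """Geometry of one conv or pooling layer (isotropic, symmetric padding)."""

    kernel: int
    stride: int = 1
    padding: int = 0

    def __post_init__(self):
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError(f"kernel must be odd and >= 1, got {self.kernel}")
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")
        if self.padding < 0:
            raise ValueError(f"padding must be >= 0, got {self.padding}")


@dataclass(frozen=True)
class GeomState:
    """Accumulated receptive field, output spacing, and first-center offset."""

    rf: int
    jump: int
    offset: float


def compose_geometry(layers: Sequence[LayerGeom]) -> GeomState:
    """Fold the receptive-field recurrence over ``layers`` in order."""
    if not layers:
        raise ValueError("layer list must be non-empty")
    rf, jump, offset = 1, 1, 0.0
    for lg in layers:
        offset = offset + ((lg.kernel - 1) / 2 - lg.padding) * jump
        rf = rf + (lg.kernel - 1) * jump
        jump = jump * lg.stride
    return GeomState(rf=rf, jump=jump, offset=offset)


def _extent_through(n: int, lg: LayerGeom) -> int:
    return (n + 2 * lg.padding - lg.kernel) // lg.stride + 1


def output_extent(
    input_extent: Sequence[int], layers: Sequence[LayerGeom]
) -> tuple[int, int, int]:
    """Spatial extent of the layer stack's output for a given input extent."""
    out = []
    for n in input_extent:
        m = int(n)
        for lg in layers:
            m = _extent_through(m, lg)
            if m < 1:
                raise ValueError(
                    f"input extent {n} too small for layer stack (collapses at {lg})"
                )
        out.append(m)
    return tuple(out)  # type: ignore[return-value]


@dataclass
class CoordinateGrid:
    """Normalized Cartesian coordinates of every voxel of a template grid.

    ``coords[i, j, k, c]`` is the coordinate of voxel ``(i, j, k)`` along
    axis ``c``, scaled to [-1, +1] across the *full* template extent.  A
    crop slices this grid without renormalizing, which is what makes the
    coordinates (and hence the gate) translation-dependent.
    """

    coords: np.ndarray  # (W, H, D, 3) float32

    @property
    def extent(self) -> tuple[int, int, int]:
        return self.coords.shape[:3]

    def crop(self, origin: Sequence[int], size: Sequence[int]) -> "CoordinateGrid":
        o, s = np.asarray(origin, int), np.asarray(size, int)
        if np.any(o < 0) or np.any(o + s > np.asarray(self.extent)):
            raise ValueError(f"crop origin={tuple(o)} size={tuple(s)} out of bounds")
        return CoordinateGrid(
            self.coords[o[0] : o[0] + s[0], o[1] : o[1] + s[1], o[2] : o[2] + s[2]]
        )


@dataclass
class PositionIndicator:
    """Patch-center coordinates on the encoder's output grid: (w, h, d, 3)."""

    coords: np.ndarray

    @property
    def extent(self) -> tuple[int, int, int]:
        return self.coords.shape[:3]


def make_coordinate_grid(full_extent: Sequence[int]) -> CoordinateGrid:
    """Build the 3-channel coordinate space for a template grid.

    Channel ``c`` at index ``i`` holds ``2 i / (n_c - 1) - 1``, so corners
    map to ±1 and the grid center of an odd extent maps to 0.
    """
    ext = tuple(int(n) for n in full_extent)
    if any(n < 2 for n in ext):
        raise ValueError(f"every extent must be >= 2, got {ext}")
    axes = [np.linspace(-1.0, 1.0, n, dtype=np.float32) for n in ext]
    grids = np.meshgrid(*axes, indexing="ij")
    return CoordinateGrid(np.stack(grids, axis=-1).astype(np.float32))


def extract_position_indicator(
    grid: CoordinateGrid, layers: Sequence[LayerGeom]
) -> PositionIndicator:
    """Subsample the (possibly cropped) coordinate grid at patch centers.

    For output index ``i`` the patch center sits at input index
    ``offset + i * jump``; fractional offsets are resolved by linear
    interpolation along each axis (coordinates are affine in the index, so
    per-axis linear interpolation is exact).
    """
    geom = compose_geometry(layers)
    out_ext = output_extent(grid.extent, layers)
    return subsample_at_centers(grid, geom, out_ext)


def subsample_at_centers(
    grid: CoordinateGrid, geom: GeomState, out_ext: Sequence[int]
) -> PositionIndicator:
    """Take grid values at ``offset + index * jump`` per axis (linear interp)."""
    taken = grid.coords
    for ax, m in enumerate(out_ext):
        centers = geom.offset + np.arange(m) * geom.jump
        lo = np.floor(centers).astype(int)
        frac = (centers - lo).astype(np.float32)
        hi = np.minimum(lo + 1, grid.extent[ax] - 1)
        a = np.take(taken, lo, axis=ax)
        if np.any(frac > 0):
            b = np.take(taken, hi, axis=ax)
            shape = [1] * taken.ndim
            shape[ax] = m
            f = frac.reshape(shape)
            taken = a * (1 - f) + b * f
        else:
            taken = a
    return PositionIndicator(taken.astype(np.float32))


def rf_oracle(
    layers: Sequence[LayerGeom], probe_extent: Sequence[int]
) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
    """Measure (rf, jump) per axis empirically via gradient support.

    Each layer is replaced by an all-ones single-channel convolution with
    the same kernel and stride (pooling included — its window footprint is
    identical), a one-hot gradient is backpropagated from one output
    position, and the nonzero input support gives the receptive field; the
    displacement of the support between adjacent output positions gives the
    jump.  Entirely independent of :func:`compose_geometry`.
    """
    ext = tuple(int(n) for n in probe_extent)
    out_ext = output_extent(ext, layers)
    if any(m < 2 for m in out_ext):
        raise ValueError(f"probe extent {ext} yields output {out_ext}; need >= 2")
    for lg in layers:
        if lg.padding != 0:
            raise ValueError("gradient-support oracle assumes valid (zero) padding")

    weights = [
        nn.Tensor(np.ones((1, 1, lg.kernel, lg.kernel, lg.kernel), dtype=np.float32))
        for lg in layers
    ]

    def support(one_hot_pos):
        x = nn.Tensor(np.zeros((1,) + ext, dtype=np.float32), requires_grad=True)
        h = x
        for lg, w in zip(layers, weights):
            h = nn.conv3d(h, w, stride=lg.stride)
        g = np.zeros_like(h.data)
        g[(0,) + tuple(one_hot_pos)] = 1.0
        nn.tsum(h * nn.Tensor(g)).backward()
        nz = np.nonzero(x.grad[0])
        return [(int(a.min()), int(a.max())) for a in nz]

    s0 = support((0, 0, 0))
    s1 = support((1, 1, 1))
    rf = tuple(hi - lo + 1 for lo, hi in s0)
    jump = tuple(b[0] - a[0] for a, b in zip(s0, s1))
    return rf, jump  # type: ignore[return-value]
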