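"""Rotation-grid generation and bilinear direction sampling.

The axial-free attention mechanism attends along a line at an arbitrary
angle θ ∈ [0, π).  It does so by resampling the feature map on a rotated
grid: the *grid generator* produces, for every output pixel, a fractional
source coordinate obtained by rotating the pixel's centred coordinate by θ
about the image centre, and the *direction sampler* evaluates the feature
map there with a bilinear kernel ``max(0, 1−|Δx|)·max(0, 1−|Δy|)``, which
gives exactly zero weight to source locations outside the input (zero-fill
boundary).  Rows (or columns) of the resampled map are then 1D attention
banks oriented along θ in the original frame.

Coordinate convention: ``x`` is the column index, ``y`` the row index, both
centred at ``((W−1)/2, (H−1)/2)``; the rotation matrix is
``[[cos θ, −sin θ], [sin θ, cos θ]]``.  Any consistent convention yields an
equivalent model; this one is fixed so tests can pin it down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["SamplingGrid", "AngleSet", "make_rotation_grid", "make_angle_set",
           "sample", "bilinear_sample"]


@dataclass(frozen=True)
class SamplingGrid:
    """Fractional source coordinates, one per output pixel.

    ``ys``/``xs`` have the output map's shape (H, W) and hold row/column
    coordinates in the *input* frame, in unnormalized pixel units.
    """

    ys: np.ndarray
    xs: np.ndarray
    angle: float
    inverse: bool = False
    frame: str = "center-xy"  # x = col, y = row, origin at image centre

    @property
    def shape(self) -> tuple[int, int]:
        return self.ys.shape


@dataclass(frozen=True)
class AngleSet:
    """D uniformly spaced line orientations: {d·π/D, d = 0..D−1}."""

    D: int
    angles: np.ndarray

    @property
    def spacing(self) -> float:
        return np.pi / self.D


def make_angle_set(D: int) -> AngleSet:
    """Angles of the D parallel attention layers; spacing θ̄ satisfies D·θ̄ = π."""
    if not isinstance(D, (int, np.integer)) or D <= 0:
        raise ValueError(f"direction count D must be a positive integer, got {D!r}")
    return AngleSet(D=int(D), angles=np.arange(D) * (np.pi / D))


def make_rotation_grid(H: int, W: int, theta: float, inverse: bool = False) -> SamplingGrid:
    """Source coordinates for rotating the centred pixel grid by ``theta``.

    With ``inverse=True`` the grid uses −θ, which composes with the forward
    grid to the identity (up to bilinear smoothing at fractional coordinates).
    """
    if H <= 0 or W <= 0:
        raise ValueError(f"grid dimensions must be positive, got H={H}, W={W}")
    if not (0.0 <= theta < np.pi):
        raise ValueError(f"theta must lie in [0, pi), got {theta}")
    phi = -theta if inverse else theta
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(H) - cy, np.arange(W) - cx, indexing="ij")
    c, s = np.cos(phi), np.sin(phi)
    xs = c * xx - s * yy + cx
    ys = s * xx + c * yy + cy
    return SamplingGrid(ys=ys, xs=xs, angle=theta, inverse=inverse)


def _bilinear_coeffs(grid: SamplingGrid, H: int, W: int):
    """Corner indices and kernel weights, with out-of-range corners zeroed."""
    ys, xs = grid.ys, grid.xs
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    wy1 = ys - y0
    wx1 = xs - x0
    corners = []
    for dy, wy in ((0, 1.0 - wy1), (1, wy1)):
        for dx, wx in ((0, 1.0 - wx1), (1, wx1)):
            iy, ix = y0 + dy, x0 + dx
            valid = (iy >= 0) & (iy < H) & (ix >= 0) & (ix < W)
            w = wy * wx * valid
            corners.append((np.clip(iy, 0, H - 1), np.clip(ix, 0, W - 1), w))
    return corners


def bilinear_sample(x: np.ndarray, grid: SamplingGrid) -> np.ndarray:
    """Bilinear interpolation of ``x`` (… , H, W) at the grid coordinates.

    Applied identically and independently for every leading (channel/batch)
    dimension; coordinates outside the input contribute zero.
    """
    H, W = x.shape[-2:]
    out = np.zeros(x.shape[:-2] + grid.shape, dtype=x.dtype)
    for iy, ix, w in _bilinear_coeffs(grid, H, W):
        out += x[..., iy, ix] * w
    return out


def sample(x, grid: SamplingGrid):
    """Direction sampler: resample a feature map on a rotation grid.

    Accepts a plain numpy array or an autodiff :class:`Tensor` of shape
    (…, H, W); gradients flow to the input values (the grid is fixed).
    """
    if isinstance(x, Tensor):
        H, W = x.shape[-2:]
        out = None
        for iy, ix, w in _bilinear_coeffs(grid, H, W):
            term = ad.gather2d(x, iy, ix) * w.astype(x.dtype)
            out = term if out is None else out + term
        return out
    return bilinear_sample(np.asarray(x), grid)
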