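"""Contrast enhancement, 8-bit conversion, boundary convolution and tiling.

The boundary-enhancing step applies a fixed 5×5 high-pass matrix (all −1 with a
centre weight of 24 and a single 0 in the bottom-right corner; coefficients sum
to 1) as a *correlation* — the kernel is not flipped, matching the convolver
convention of the tool this pipeline descends from.  Large sections are cut
into an n×n grid (n in 2..5) of nearly equal tiles that are processed
independently and stitched back losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import MyosegError

#: 5×5 boundary-enhancing matrix: −1 everywhere, centre 24, bottom-right 0.
BOUNDARY_KERNEL = np.full((5, 5), -1.0)
BOUNDARY_KERNEL[2, 2] = 24.0
BOUNDARY_KERNEL[4, 4] = 0.0
assert BOUNDARY_KERNEL.sum() == 1.0


def enhance_contrast(plane: np.ndarray, saturated_fraction: float = 0.0035) -> np.ndarray:
    """Percentile-clip linear contrast stretch (histogram 'color balancer').

    The lowest and highest ``saturated_fraction/2`` of pixels are clipped to
    the dtype extremes; the mapping is monotone non-decreasing and a constant
    plane is returned unchanged.
    """
    if plane.size == 0:
        raise MyosegError("empty plane")
    if not 0 <= saturated_fraction < 1:
        raise MyosegError("saturated_fraction must be in [0, 1)")
    hi_out = 255 if plane.dtype == np.uint8 else 65535
    x = plane.astype(np.float64)
    if saturated_fraction == 0:
        lo, hi = x.min(), x.max()
    else:
        lo = np.quantile(x, saturated_fraction / 2)
        hi = np.quantile(x, 1 - saturated_fraction / 2)
    if hi <= lo:
        return plane.copy()
    y = (x - lo) / (hi - lo) * hi_out
    return np.clip(np.floor(y + 0.5), 0, hi_out).astype(plane.dtype)


def to_8bit(plane: np.ndarray) -> np.ndarray:
    """Map the plane's current [min, max] linearly onto [0, 255].

    Rounds half up; a constant (degenerate-range) plane maps to 0.
    """
    x = plane.astype(np.float64)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(plane.shape, dtype=np.uint8)
    y = (x - lo) / (hi - lo) * 255.0
    return np.floor(y + 0.5).astype(np.uint8)


def convolve_boundary_kernel(plane: np.ndarray) -> np.ndarray:
    """Correlate with :data:`BOUNDARY_KERNEL`, replicate-padded, clipped to 8 bits."""
    if plane.shape[0] < 5 or plane.shape[1] < 5:
        raise MyosegError(f"plane {plane.shape} smaller than the 5x5 kernel")
    out = ndimage.correlate(plane.astype(np.float64), BOUNDARY_KERNEL, mode="nearest")
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


@dataclass
class TileSet:
    """Disjoint rectangular tiles exactly covering a parent plane."""

    tiles: list[np.ndarray]
    offsets: list[tuple[int, int]]  # (row, col) of each tile's top-left corner
    grid_factor: int
    parent_shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.tiles)


def _edges(extent: int, n: int) -> list[int]:
    """Half-open tile edges; the last tile absorbs any remainder."""
    step = extent // n
    return [i * step for i in range(n)] + [extent]


def tile_image(plane: np.ndarray, grid_factor: int) -> TileSet:
    """Cut a plane into ``grid_factor``² equally sized tiles (last row/col wider)."""
    if not 2 <= grid_factor <= 5:
        raise MyosegError(f"grid_factor must be in [2, 5], got {grid_factor}")
    h, w = plane.shape
    re, ce = _edges(h, grid_factor), _edges(w, grid_factor)
    tiles, offsets = [], []
    for i in range(grid_factor):
        for j in range(grid_factor):
            tiles.append(plane[re[i]:re[i + 1], ce[j]:ce[j + 1]].copy())
            offsets.append((re[i], ce[j]))
    return TileSet(tiles=tiles, offsets=offsets, grid_factor=grid_factor,
                   parent_shape=(h, w))


def stitch(ts: TileSet) -> np.ndarray:
    """Reassemble tiles into the parent plane; exact inverse of :func:`tile_image`."""
    if len(ts.tiles) != len(ts.offsets):
        raise MyosegError("tiles and offsets disagree in length")
    out = np.zeros(ts.parent_shape, dtype=ts.tiles[0].dtype)
    covered = np.zeros(ts.parent_shape, dtype=np.uint8)
    for tile, (r, c) in zip(ts.tiles, ts.offsets):
        h, w = tile.shape
        if r + h > ts.parent_shape[0] or c + w > ts.parent_shape[1]:
            raise MyosegError(f"tile at {(r, c)} exceeds parent bounds")
        out[r:r + h, c:c + w] = tile
        covered[r:r + h, c:c + w] += 1
    if (covered > 1).any():
        raise MyosegError("overlapping tiles")
    if (covered == 0).any():
        raise MyosegError("missing tiles: parent not fully covered")
    return out


def preprocess_boundary_channel(plane: np.ndarray,
                                saturated_fraction: float = 0.0035) -> np.ndarray:
    """Contrast-enhance, convert to 8 bits and apply the boundary kernel."""
    return convolve_boundary_kernel(to_8bit(enhance_contrast(plane, saturated_fraction)))
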