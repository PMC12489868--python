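"""Contrast-limited adaptive histogram equalization with a Rayleigh output.

The image is divided into non-overlapping tiles; each tile's histogram is
clipped at a limit (excess mass redistributed equally over all bins) and a
transfer function shaping the output histogram as a Rayleigh distribution is
built from the clipped CDF.  Tile mappings are rejoined by bilinear
interpolation between the four nearest tile centers, which suppresses blocky
seams at tile boundaries.

The clip limit bounds local contrast amplification: a smaller limit yields
gentler enhancement and less noise amplification.  The Rayleigh shape
parameter ``alpha`` governs the spread/brightness of the remapped tile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .imaging import GrayImage

__all__ = [
    "ClaheParams",
    "TileMapping",
    "tile_histogram",
    "clip_and_redistribute",
    "rayleigh_quantile",
    "rayleigh_transfer",
    "clahe",
]


@dataclass(frozen=True)
class ClaheParams:
    """The four-dimensional CLAHE decision vector.

    tiles_x, tiles_y : number of horizontal / vertical tiles (>= 2 each,
        since bilinear blending needs a 2x2 grid of tile centers).
    clip_limit : normalized histogram clip limit in (0, 1], expressed as a
        fraction of the tile pixel count.
    alpha : Rayleigh shape parameter (> 0) of the output histogram.
    """

    tiles_x: int
    tiles_y: int
    clip_limit: float
    alpha: float

    def __post_init__(self) -> None:
        if self.tiles_x < 2 or self.tiles_y < 2:
            raise ValueError(
                f"need at least a 2x2 tile grid, got {self.tiles_x}x{self.tiles_y}"
            )
        if not 0.0 < self.clip_limit <= 1.0:
            raise ValueError(f"clip_limit must be in (0, 1], got {self.clip_limit}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")


@dataclass(frozen=True)
class TileMapping:
    """Monotone lookup table from input bin index to output luminance."""

    lut: np.ndarray
    bins: int

    def __post_init__(self) -> None:
        lut = np.asarray(self.lut, dtype=np.float64)
        if lut.shape != (self.bins,):
            raise ValueError(f"lut must have shape ({self.bins},), got {lut.shape}")
        if np.any(np.diff(lut) < -1e-12):
            raise ValueError("lut must be non-decreasing")
        if lut.min() < -1e-12 or lut.max() > 1 + 1e-12:
            raise ValueError("lut values must lie in [0, 1]")
        lut.setflags(write=False)
        object.__setattr__(self, "lut", lut)


def _bin_indices(arr: np.ndarray, bins: int) -> np.ndarray:
    """Map [0, 1] values to bin indices 0..bins-1 (1.0 falls in the top bin)."""
    return np.minimum((arr * bins).astype(np.intp), bins - 1)


def tile_histogram(
    img: GrayImage, region: tuple[int, int, int, int], bins: int = 256
) -> np.ndarray:
    """Histogram of counts over a rectangular region (row, col, height, width)."""
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    r, c, h, w = region
    if r < 0 or c < 0 or h <= 0 or w <= 0 or r + h > img.height or c + w > img.width:
        raise ValueError(f"region {region} falls outside image of shape {img.shape}")
    idx = _bin_indices(img.pixels[r : r + h, c : c + w], bins)
    return np.bincount(idx.ravel(), minlength=bins)


def clip_and_redistribute(
    hist: np.ndarray, clip_count: float, max_iter: int = 100
) -> np.ndarray:
    """Clip histogram bins at ``clip_count``, redistributing excess equally.

    Redistribution can push bins back above the limit, so clipping and equal
    redistribution are iterated to their fixed point (excess below 1e-9 of
    the total mass, or ``max_iter`` rounds).  Total mass is conserved.  If
    the limit is infeasible (total mass exceeds ``bins * clip_count``) the
    histogram converges toward uniform instead, the flattest achievable.
    """
    if clip_count <= 0:
        raise ValueError(f"clip_count must be positive, got {clip_count}")
    h = np.asarray(hist, dtype=np.float64).copy()
    total = h.sum()
    if total == 0:
        return h
    tol = 1e-9 * total
    for _ in range(max_iter):
        excess = np.maximum(h - clip_count, 0.0).sum()
        if excess <= tol:
            break
        np.minimum(h, clip_count, out=h)
        h += excess / h.size
    return h


def rayleigh_quantile(c: np.ndarray | float, alpha: float) -> np.ndarray | float:
    """Rayleigh inverse CDF: g(c) = sqrt(2 * alpha^2 * ln(1 / (1 - c)))."""
    return np.sqrt(2.0 * alpha * alpha * np.log(1.0 / (1.0 - np.asarray(c))))


def rayleigh_transfer(
    cdf: np.ndarray,
    alpha: float,
    g_min: float = 0.0,
    g_max: float = 1.0,
    eps: float = 1e-6,
) -> TileMapping:
    """Build the Rayleigh-shaped transfer function from a clipped-histogram CDF.

    The raw mapping ``g_min + rayleigh_quantile(c, alpha)`` is unbounded as
    c -> 1, so c is clamped at ``1 - eps`` and the mapping is affinely
    rescaled to span [g_min, g_max] exactly.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    cdf = np.asarray(cdf, dtype=np.float64)
    if np.any(np.diff(cdf) < -1e-12):
        raise ValueError("cdf must be non-decreasing")
    c = np.clip(cdf, 0.0, 1.0 - eps)
    g = g_min + rayleigh_quantile(c, alpha)
    lo, hi = float(g.min()), float(g.max())
    if hi > lo:
        g = g_min + (g - lo) * (g_max - g_min) / (hi - lo)
    else:
        g = np.full_like(g, g_min)
    return TileMapping(lut=g, bins=cdf.size)


def clahe(img: GrayImage, params: ClaheParams, bins: int = 256) -> GrayImage:
    """Apply Rayleigh-CLAHE with the given tile grid, clip limit and alpha.

    Images whose sides are not multiples of the tile grid are reflect-padded
    up to the nearest multiple and cropped back after enhancement.  The
    absolute clip count is ``max(1, clip_limit * tile_pixel_count)``.
    """
    ty, tx = params.tiles_y, params.tiles_x
    H, W = img.shape
    th = math.ceil(H / ty)
    tw = math.ceil(W / tx)
    if th < 2 or tw < 2:
        raise ValueError(
            f"tile grid {tx}x{ty} leaves tiles under 2 pixels for image {img.shape}"
        )
    pad_h, pad_w = th * ty - H, tw * tx - W
    arr = np.pad(img.pixels, ((0, pad_h), (0, pad_w)), mode="reflect")
    idx = _bin_indices(arr, bins)

    tile_pixels = th * tw
    clip_count = max(1.0, params.clip_limit * tile_pixels)
    eps = 1.0 / tile_pixels

    luts = np.empty((ty, tx, bins))
    for i in range(ty):
        for j in range(tx):
            block = idx[i * th : (i + 1) * th, j * tw : (j + 1) * tw]
            hist = np.bincount(block.ravel(), minlength=bins).astype(np.float64)
            clipped = clip_and_redistribute(hist, clip_count)
            cdf = np.cumsum(clipped) / clipped.sum()
            luts[i, j] = rayleigh_transfer(cdf, params.alpha, eps=eps).lut

    # bilinear blend between the four nearest tile centers; pixels beyond the
    # outer ring of centers clamp to the edge mapping
    gy = np.clip((np.arange(th * ty) + 0.5) / th - 0.5, 0.0, ty - 1.0)
    gx = np.clip((np.arange(tw * tx) + 0.5) / tw - 0.5, 0.0, tx - 1.0)
    i0 = gy.astype(np.intp)
    j0 = gx.astype(np.intp)
    i1 = np.minimum(i0 + 1, ty - 1)
    j1 = np.minimum(j0 + 1, tx - 1)
    wy = (gy - i0)[:, None]
    wx = (gx - j0)[None, :]

    I0, J0 = i0[:, None], j0[None, :]
    I1, J1 = i1[:, None], j1[None, :]
    a = luts[I0, J0, idx]
    b = luts[I0, J1, idx]
    c = luts[I1, J0, idx]
    d = luts[I1, J1, idx]
    # grouped so that equal corner values pass through exactly (a constant
    # image stays bitwise constant)
    out = a + wx * (b - a) + wy * (c - a) + wy * wx * (a - b - c + d)
    out = np.clip(out[:H, :W], 0.0, 1.0)
    return GrayImage(out, source_depth=img.source_depth)
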