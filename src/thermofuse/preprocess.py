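"""Contrast enhancement for gray-scale thermograms.

Two classical operators, written against integer rasters of bit depth
``r`` (8 or 16):

* global histogram equalization with the cumulative-count mapping
  ``M0(j) = round(G_j * (2^r - 1) / (Q*y))`` where ``G_j`` is the cumulative
  number of pixels up to gray level ``j`` and ``Q*y`` the pixel count;
* CLAHE — contrast-limited adaptive histogram equalization — per-tile
  equalization with the tile histograms clipped at

      beta = (tile_pixels / N) * (1 + (alpha/100) * (L_max - 1))

  (``N`` histogram bins, clip factor ``alpha`` in percent, maximum allowed
  slope ``L_max``), excess mass redistributed uniformly over the bins, and
  the per-tile mappings blended bilinearly to avoid tile-boundary seams.

With ``alpha = 0`` the clip limit reduces to the mean bin height
``tile_pixels / N`` (maximal clipping); as ``alpha`` grows the limit rises
and CLAHE approaches plain tiled equalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GrayImage", "ClaheParams", "clahe_clip_limit", "clahe", "hist_equalize"]


@dataclass(frozen=True)
class GrayImage:
    """A 2-D integer intensity raster with an explicit bit depth."""

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self):
        pixels = np.asarray(self.pixels)
        if pixels.ndim != 2 or pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if pixels.min() < 0 or pixels.max() > self.max_level:
            raise ValueError("pixel values exceed the declared bit depth")
        object.__setattr__(self, "pixels", pixels.astype(np.int64))

    @property
    def max_level(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def to_uint(self) -> np.ndarray:
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        return self.pixels.astype(dtype)


@dataclass(frozen=True)
class ClaheParams:
    """CLAHE configuration: tile grid, histogram bins, clip factor, max slope."""

    tile_rows: int = 8
    tile_cols: int = 8
    bins: int = 256
    clip_factor: float = 40.0
    max_slope: float = 4.0

    def __post_init__(self):
        if self.tile_rows < 1 or self.tile_cols < 1:
            raise ValueError("tile grid dimensions must be >= 1")
        if self.bins < 2:
            raise ValueError("need at least 2 histogram bins")
        if self.clip_factor < 0:
            raise ValueError("clip_factor must be >= 0")
        if self.max_slope < 1:
            raise ValueError("max_slope must be >= 1")


def clahe_clip_limit(params: ClaheParams, tile_pixel_count: int) -> float:
    """Clip limit beta for one tile histogram."""
    if tile_pixel_count <= 0:
        raise ValueError("tile_pixel_count must be positive")
    if params.bins == 0:
        raise ValueError("bins must be nonzero")
    base = tile_pixel_count / params.bins
    return base * (1.0 + (params.clip_factor / 100.0) * (params.max_slope - 1.0))


def _clip_histogram(hist: np.ndarray, beta: float) -> np.ndarray:
    """Clip bins at beta and spread the excess uniformly over all bins."""
    hist = hist.astype(float)
    excess = np.maximum(hist - beta, 0.0).sum()
    clipped = np.minimum(hist, beta)
    return clipped + excess / hist.size


def _equalize_mapping(hist: np.ndarray, max_level: int) -> np.ndarray:
    """Cumulative-count gray-level mapping for one (possibly clipped) histogram."""
    cdf = np.cumsum(hist)
    total = cdf[-1]
    return np.rint(cdf * max_level / total).astype(np.int64)


def hist_equalize(img: GrayImage) -> GrayImage:
    """Global histogram equalization with the cumulative-count mapping.

    The mapping is monotone non-decreasing and idempotent up to one gray
    level of rounding.
    """
    levels = img.max_level + 1
    hist = np.bincount(img.pixels.ravel(), minlength=levels)
    mapping = _equalize_mapping(hist, img.max_level)
    return GrayImage(mapping[img.pixels], img.bit_depth)


def clahe(img: GrayImage, params: ClaheParams | None = None) -> GrayImage:
    """Contrast-limited adaptive histogram equalization.

    The image is split into a ``tile_rows x tile_cols`` grid (padded by edge
    reflection when the dimensions do not divide evenly, cropped after).
    Each tile's histogram is clipped at the clip limit above and equalized;
    pixel mappings are blended bilinearly between the four neighboring tile
    centers, with edge tiles replicated.
    """
    if params is None:
        params = ClaheParams()
    h, w = img.shape
    if params.tile_rows > h or params.tile_cols > w:
        raise ValueError("tile grid is larger than the image")

    th = -(-h // params.tile_rows)  # ceil
    tw = -(-w // params.tile_cols)
    pad_h = th * params.tile_rows - h
    pad_w = tw * params.tile_cols - w
    pixels = np.pad(img.pixels, ((0, pad_h), (0, pad_w)), mode="reflect") if (pad_h or pad_w) else img.pixels

    levels = img.max_level + 1
    nbins = min(params.bins, levels)
    # integer bin index per pixel; bins evenly partition the gray range
    bin_of = (pixels * nbins) // levels

    beta = clahe_clip_limit(
        ClaheParams(params.tile_rows, params.tile_cols, nbins, params.clip_factor, params.max_slope),
        th * tw,
    )

    maps = np.empty((params.tile_rows, params.tile_cols, nbins), dtype=np.int64)
    for i in range(params.tile_rows):
        for j in range(params.tile_cols):
            tile_bins = bin_of[i * th : (i + 1) * th, j * tw : (j + 1) * tw]
            hist = np.bincount(tile_bins.ravel(), minlength=nbins)
            maps[i, j] = _equalize_mapping(_clip_histogram(hist, beta), img.max_level)

    # bilinear blend of the four neighboring tile mappings
    H, W = pixels.shape
    rows = np.arange(H, dtype=float)
    cols = np.arange(W, dtype=float)
    ry = rows / th - 0.5  # tile-center coordinates
    cx = cols / tw - 0.5
    i0 = np.clip(np.floor(ry).astype(int), 0, params.tile_rows - 1)
    i1 = np.clip(i0 + 1, 0, params.tile_rows - 1)
    j0 = np.clip(np.floor(cx).astype(int), 0, params.tile_cols - 1)
    j1 = np.clip(j0 + 1, 0, params.tile_cols - 1)
    fy = np.clip(ry - np.floor(ry), 0.0, 1.0)
    fx = np.clip(cx - np.floor(cx), 0.0, 1.0)
    # edge replication: where i0 == i1 the weight is irrelevant
    fy = np.where(ry < 0, 0.0, np.where(ry > params.tile_rows - 1, 1.0, fy))
    fx = np.where(cx < 0, 0.0, np.where(cx > params.tile_cols - 1, 1.0, fx))

    b = bin_of
    I0 = i0[:, None]
    I1 = i1[:, None]
    J0 = j0[None, :]
    J1 = j1[None, :]
    v00 = maps[I0, J0, b]
    v01 = maps[I0, J1, b]
    v10 = maps[I1, J0, b]
    v11 = maps[I1, J1, b]
    FY = fy[:, None]
    FX = fx[None, :]
    out = (
        (1 - FY) * (1 - FX) * v00
        + (1 - FY) * FX * v01
        + FY * (1 - FX) * v10
        + FY * FX * v11
    )
    out = np.clip(np.rint(out), 0, img.max_level).astype(np.int64)
    return GrayImage(out[:h, :w], img.bit_depth)
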