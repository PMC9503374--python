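"""Contrast-limited adaptive histogram equalization (CLAHE).

The frame is divided into a non-overlapping grid of equal tiles; each
tile's gray-level histogram is clipped at the Reza clip limit

    beta = (M / N) * (1 + (alpha / 100) * (S_max - 1))

with M the pixel count of one tile, N the number of gray levels, alpha
the clip factor in [0, 100] and S_max the maximum slope of the
transformation function.  Clipped excess is redistributed uniformly
over the histogram, the per-tile cumulative distribution defines a
gray-level mapping, and pixel outputs are bilinearly interpolated
between the four neighbouring tile mappings (two at borders, one at
corners).

Colour frames are handled in CIELAB by default: only the lightness
channel is equalized, preserving the hue of the mucosa.  A per-channel
RGB mode is available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import color as skcolor

__all__ = [
    "CLAHEParams",
    "ClipLimit",
    "compute_clip_limit",
    "clip_and_redistribute",
    "equalize_channel",
    "equalize_frame",
    "preprocess_dataset",
]

log = logging.getLogger(__name__)

IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


class ParameterError(ValueError):
    """CLAHE parameter outside its valid domain."""


class DimensionError(ValueError):
    """Frame too small for the requested tile grid."""


@dataclass(frozen=True)
class CLAHEParams:
    """Tiling grid and clip-limit parameters.

    alpha is the clip factor in [0, 100]; s_max >= 1 is the maximum
    slope of the mapping; n_gray the number of gray levels.  alpha = 0
    collapses the clip limit to the uniform-histogram floor M/N, and
    alpha = 100 with s_max = n_gray disables clipping entirely.
    """

    tiles_x: int = 8
    tiles_y: int = 8
    alpha: float = 50.0
    s_max: float = 4.0
    n_gray: int = 256

    def __post_init__(self):
        if not 0 <= self.alpha <= 100:
            raise ParameterError(f"alpha must be in [0, 100], got {self.alpha}")
        if self.s_max < 1:
            raise ParameterError(f"s_max must be >= 1, got {self.s_max}")
        if self.n_gray < 2:
            raise ParameterError(f"n_gray must be >= 2, got {self.n_gray}")
        if self.tiles_x < 1 or self.tiles_y < 1:
            raise ParameterError("tile counts must be >= 1")


@dataclass(frozen=True)
class ClipLimit:
    """The clip limit beta (histogram counts per bin) for one tile size."""

    beta: float
    region_pixels: int

    def __post_init__(self):
        if self.region_pixels < 1:
            raise ParameterError("region_pixels must be >= 1")
        if self.beta < 0:
            raise ParameterError("beta must be non-negative")


def compute_clip_limit(params: CLAHEParams, region_pixels: int) -> ClipLimit:
    """Reza clip limit beta = (M/N) * (1 + (alpha/100) * (S_max - 1)).

    M is the tile pixel count and N the number of gray levels, so the
    alpha = 0 floor M/N is the count of a perfectly uniform histogram.
    """
    if region_pixels < 1:
        raise ParameterError(f"region_pixels must be >= 1, got {region_pixels}")
    m, n = region_pixels, params.n_gray
    beta = (m / n) * (1.0 + (params.alpha / 100.0) * (params.s_max - 1.0))
    return ClipLimit(beta=beta, region_pixels=region_pixels)


def clip_and_redistribute(hist: np.ndarray, limit: ClipLimit) -> np.ndarray:
    """Clip histogram bins at ceil(beta) and redistribute the excess uniformly.

    Redistribution is iterated: mass handed to bins near the ceiling can
    push them over it, in which case they are re-clipped and the new
    excess redistributed, until no bin exceeds the ceiling or every bin
    sits at it.  Total count is conserved exactly (integer arithmetic).
    A degenerate all-zero histogram is returned unchanged.
    """
    h = np.asarray(hist, dtype=np.int64).copy()
    if h.ndim != 1:
        raise ValueError("histogram must be one-dimensional")
    if (h < 0).any():
        raise ValueError("histogram bins must be non-negative")
    if h.sum() == 0:
        return h
    ceiling = max(1, math.ceil(limit.beta))
    while True:
        over = h > ceiling
        excess = int((h[over] - ceiling).sum())
        h[over] = ceiling
        if excess == 0:
            return h
        under = h < ceiling
        n_under = int(under.sum())
        if n_under == 0:
            # total mass exceeds ceiling * bins: spread the residue evenly
            h += excess // h.size
            h[: excess % h.size] += 1
            return h
        share, rem = divmod(excess, n_under)
        h[under] += share
        if rem:
            h[np.flatnonzero(under)[:rem]] += 1


def _tile_mappings(channel: np.ndarray, params: CLAHEParams) -> np.ndarray:
    """Per-tile clipped-CDF gray-level mappings, shape (ty, tx, n_gray)."""
    ty, tx, n = params.tiles_y, params.tiles_x, params.n_gray
    h_, w_ = channel.shape
    th, tw = h_ // ty, w_ // tx
    limit = compute_clip_limit(params, th * tw)
    maps = np.empty((ty, tx, n), dtype=np.float64)
    for iy in range(ty):
        for ix in range(tx):
            tile = channel[iy * th : (iy + 1) * th, ix * tw : (ix + 1) * tw]
            hist = np.bincount(tile.ravel(), minlength=n)[:n]
            hist = clip_and_redistribute(hist, limit)
            cdf = np.cumsum(hist) / hist.sum()
            maps[iy, ix] = np.rint((n - 1) * cdf)
    return maps


def equalize_channel(channel: np.ndarray, params: CLAHEParams) -> np.ndarray:
    """CLAHE on a single integer channel in [0, n_gray).

    Frames whose extent is not a multiple of the tile grid are padded by
    edge reflection, equalized, and cropped back.  Per-pixel outputs
    bilinearly interpolate the mappings of the (up to) four neighbouring
    tiles; interpolation coordinates are clamped so corner pixels use a
    single mapping and border pixels two.
    """
    ch = np.asarray(channel)
    if ch.ndim != 2:
        raise DimensionError("channel must be 2-D")
    h_, w_ = ch.shape
    ty, tx = params.tiles_y, params.tiles_x
    if h_ < ty or w_ < tx:
        raise DimensionError(f"frame {h_}x{w_} smaller than tile grid {ty}x{tx}")
    pad_y = (-h_) % ty
    pad_x = (-w_) % tx
    chp = np.pad(ch, ((0, pad_y), (0, pad_x)), mode="reflect") if (pad_y or pad_x) else ch
    hp, wp = chp.shape
    th, tw = hp // ty, wp // tx
    maps = _tile_mappings(chp.astype(np.intp), params)

    # fractional tile-center coordinates of every pixel
    gy = (np.arange(hp) + 0.5) / th - 0.5
    gx = (np.arange(wp) + 0.5) / tw - 0.5
    y0 = np.clip(np.floor(gy).astype(int), 0, ty - 1)
    x0 = np.clip(np.floor(gx).astype(int), 0, tx - 1)
    y1 = np.clip(y0 + 1, 0, ty - 1)
    x1 = np.clip(x0 + 1, 0, tx - 1)
    wy = np.clip(gy - y0, 0.0, 1.0)[:, None]
    wx = np.clip(gx - x0, 0.0, 1.0)[None, :]

    v = chp.astype(np.intp)
    y0c, y1c = y0[:, None], y1[:, None]
    x0c, x1c = x0[None, :], x1[None, :]
    m00 = maps[y0c, x0c, v]
    m01 = maps[y0c, x1c, v]
    m10 = maps[y1c, x0c, v]
    m11 = maps[y1c, x1c, v]
    out = (1 - wy) * ((1 - wx) * m00 + wx * m01) + wy * ((1 - wx) * m10 + wx * m11)
    out = np.rint(out).astype(ch.dtype)
    return out[:h_, :w_]


def equalize_frame(frame: np.ndarray, params: CLAHEParams, mode: str = "lab") -> np.ndarray:
    """CLAHE on an RGB (or grayscale) uint8 frame.

    mode="lab" converts to CIELAB and equalizes only lightness,
    preserving mucosal hue; mode="rgb" equalizes each channel
    independently. Output has the input's shape and dtype.
    """
    arr = np.asarray(frame)
    if arr.size == 0:
        raise DimensionError("empty frame")
    if arr.ndim == 2:
        return equalize_channel(arr, params)
    if arr.ndim != 3 or arr.shape[2] not in (1, 3):
        raise DimensionError(f"expected HxWx{{1,3}} frame, got shape {arr.shape}")
    if arr.shape[2] == 1:
        return equalize_channel(arr[..., 0], params)[..., None]
    if mode == "rgb":
        return np.stack([equalize_channel(arr[..., c], params) for c in range(3)], axis=-1)
    if mode != "lab":
        raise ValueError(f"mode must be 'lab' or 'rgb', got {mode!r}")
    lab = skcolor.rgb2lab(arr.astype(np.float64) / 255.0)
    n = params.n_gray
    lch = np.clip(np.rint(lab[..., 0] / 100.0 * (n - 1)), 0, n - 1).astype(np.intp)
    leq = equalize_channel(lch, params)
    lab[..., 0] = leq.astype(np.float64) / (n - 1) * 100.0
    rgb = np.clip(skcolor.lab2rgb(lab), 0.0, 1.0)
    return np.rint(rgb * 255.0).astype(arr.dtype)


def preprocess_dataset(in_dir, out_dir, params: CLAHEParams, mode: str = "lab") -> int:
    """Equalize every readable frame in ``in_dir`` into ``out_dir``.

    Filenames are preserved (so mask pairing survives); unreadable
    files are logged and skipped. Returns the number of frames written.
    Masks are never routed through this function by the pipeline.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = 0
    for path in sorted(in_dir.iterdir()):
        if path.suffix.lower() not in IMAGE_SUFFIXES:
            continue
        try:
            frame = np.asarray(Image.open(path).convert("RGB"))
            eq = equalize_frame(frame, params)
        except Exception as exc:  # unreadable/corrupt input
            log.warning("skipping %s: %s", path.name, exc)
            continue
        Image.fromarray(eq).save(out_dir / path.name)
        written += 1
    return written
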