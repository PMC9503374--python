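"""Shared independent oracles used by more than one test module."""

import numpy as np

from graftunet.clahe import CLAHEParams


def tile_ahe_oracle(channel: np.ndarray, params: CLAHEParams) -> np.ndarray:
    """Independent unclipped tiled adaptive histogram equalization.

    Per-pixel loop: build each tile's plain CDF mapping, then bilinearly
    interpolate between the four neighbouring tile mappings with clamped
    tile-centre coordinates.
    """
    h, w = channel.shape
    ty, tx, n = params.tiles_y, params.tiles_x, params.n_gray
    th, tw = h // ty, w // tx
    maps = np.zeros((ty, tx, n))
    for iy in range(ty):
        for ix in range(tx):
            tile = channel[iy * th:(iy + 1) * th, ix * tw:(ix + 1) * tw]
            hist = np.bincount(tile.ravel(), minlength=n)[:n]
            cdf = np.cumsum(hist) / hist.sum()
            maps[iy, ix] = np.rint((n - 1) * cdf)
    out = np.zeros_like(channel)
    for y in range(h):
        for x in range(w):
            gy = (y + 0.5) / th - 0.5
            gx = (x + 0.5) / tw - 0.5
            y0 = min(max(int(np.floor(gy)), 0), ty - 1)
            x0 = min(max(int(np.floor(gx)), 0), tx - 1)
            y1 = min(y0 + 1, ty - 1)
            x1 = min(x0 + 1, tx - 1)
            wy = min(max(gy - y0, 0.0), 1.0)
            wx = min(max(gx - x0, 0.0), 1.0)
            v = channel[y, x]
            val = (1 - wy) * ((1 - wx) * maps[y0, x0, v] + wx * maps[y0, x1, v]) + wy * (
                (1 - wx) * maps[y1, x0, v] + wx * maps[y1, x1, v]
            )
            out[y, x] = np.rint(val)
    return out
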