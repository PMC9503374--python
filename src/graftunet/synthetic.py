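"""Synthetic colonoscopy-like frames with pixel-exact polyp masks.

Each frame is a pink-red textured mucosa background with a vignette
darkening toward one corner (the lumen), optional bright specular
ellipses, and one to three raised polyp blobs that are brighter and
redder than their surroundings.  A polyp support is an ellipse whose
radius is perturbed by a low-order radial Fourier series, giving
smooth irregular outlines with controllable area.  The binary mask is
exactly the union of polyp supports; specular highlights never enter
the mask.

The generator is fully deterministic under a fixed seed and writes the
paired-folder layout that :func:`graftunet.data_io.index_dataset`
expects, so every other module is testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .data_io import DatasetIndex, index_dataset

__all__ = ["SyntheticConfig", "generate_frame", "generate_dataset"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator recipe.

    ``polyp_radius_frac`` bounds each polyp semi-axis as a fraction of
    the frame side; ``min_contrast`` is the smallest mean gray-level
    separation enforced between polyp and background pixels, which is
    what makes the segmentation task learnable at small scale.
    """

    n_frames: int = 20
    frame_size: int = 64
    polyps_min: int = 1
    polyps_max: int = 3
    polyp_radius_frac: tuple[float, float] = (0.08, 0.25)
    highlight_prob: float = 0.3
    noise_sd: float = 4.0
    min_contrast: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1 or self.frame_size < 16:
            raise ValueError("n_frames must be >= 1 and frame_size >= 16")
        if self.noise_sd < 0 or not 0 <= self.highlight_prob <= 1:
            raise ValueError("noise_sd must be >= 0 and highlight_prob in [0, 1]")
        if not 0 <= self.polyps_min <= self.polyps_max:
            raise ValueError("need 0 <= polyps_min <= polyps_max")
        lo, hi = self.polyp_radius_frac
        if not 0 < lo <= hi < 0.5:
            raise ValueError("polyp_radius_frac must satisfy 0 < lo <= hi < 0.5")


def _smooth_noise(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    """Zero-mean low-frequency field with unit-ish amplitude."""
    field = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma)
    amp = np.abs(field).max()
    return field / amp if amp > 0 else field


def _blob_support(
    rng: np.random.Generator, size: int, cy: float, cx: float, a: float, b: float, theta: float
) -> np.ndarray:
    """Boolean support of an ellipse with low-order radial perturbation."""
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (ct * dx + st * dy) / a
    v = (-st * dx + ct * dy) / b
    rho = np.sqrt(u * u + v * v)
    phi = np.arctan2(v, u)
    r_bound = np.ones_like(phi)
    for m in (2, 3, 4):
        r_bound += rng.normal(0.0, 0.06) * np.cos(m * phi + rng.uniform(0, 2 * np.pi))
    return rho <= np.maximum(r_bound, 0.3)


def generate_frame(cfg: SyntheticConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One (RGB uint8 frame, binary uint8 mask) pair.

    Draws from ``rng`` only, so a generator seeded identically
    reproduces the frame bit for bit.
    """
    s = cfg.frame_size
    # mucosa base colour with low-frequency texture
    base = np.array([175.0, 95.0, 105.0])
    tex = _smooth_noise(rng, s, sigma=s / 8.0)
    frame = np.empty((s, s, 3), dtype=np.float64)
    for c, (b0, amp) in enumerate(zip(base, (25.0, 15.0, 12.0))):
        frame[..., c] = b0 + amp * tex + rng.uniform(-10, 10)
    # vignette darkening toward a random corner (the lumen)
    corner = rng.integers(0, 4)
    yy, xx = np.mgrid[0:s, 0:s] / (s - 1)
    cy = 0.0 if corner < 2 else 1.0
    cx = 0.0 if corner % 2 == 0 else 1.0
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2) / np.sqrt(2)
    frame *= (0.55 + 0.45 * np.clip(dist, 0, 1))[..., None]

    # polyps: perturbed ellipses, brighter and redder, with dome shading
    n_polyps = int(rng.integers(cfg.polyps_min, cfg.polyps_max + 1))
    mask = np.zeros((s, s), dtype=bool)
    lo, hi = cfg.polyp_radius_frac
    for _ in range(n_polyps):
        a = rng.uniform(lo, hi) * s
        b = rng.uniform(lo, hi) * s
        margin = max(a, b)
        cy_p = rng.uniform(margin, s - margin)
        cx_p = rng.uniform(margin, s - margin)
        sup = _blob_support(rng, s, cy_p, cx_p, a, b, rng.uniform(0, np.pi))
        if not sup.any():
            continue
        dome = ndimage.distance_transform_edt(sup)
        dome = dome / dome.max() if dome.max() > 0 else dome
        boost = cfg.min_contrast + 35.0
        shade = (0.6 + 0.4 * dome) * boost
        frame[..., 0][sup] += shade[sup] * 1.0
        frame[..., 1][sup] += shade[sup] * 0.55
        frame[..., 2][sup] += shade[sup] * 0.45
        mask |= sup

    # specular highlights on the background only, never in the mask
    if rng.uniform() < cfg.highlight_prob:
        for _ in range(int(rng.integers(1, 4))):
            r = rng.uniform(0.015, 0.04) * s
            hy = rng.uniform(r, s - r)
            hx = rng.uniform(r, s - r)
            yy2, xx2 = np.mgrid[0:s, 0:s]
            spot = ((yy2 - hy) ** 2 + (xx2 - hx) ** 2) <= r * r
            spot &= ~mask
            frame[spot] = 250.0

    frame += rng.normal(0.0, cfg.noise_sd, size=frame.shape)
    return np.clip(frame, 0, 255).astype(np.uint8), mask.astype(np.uint8)


def generate_dataset(cfg: SyntheticConfig, out_images_dir, out_masks_dir) -> DatasetIndex:
    """Write ``cfg.n_frames`` pairs in the paired-folder layout.

    Masks are stored as 0/255 PNGs; filenames match across folders.
    Returns the index of the written dataset.
    """
    out_images_dir, out_masks_dir = Path(out_images_dir), Path(out_masks_dir)
    out_images_dir.mkdir(parents=True, exist_ok=True)
    out_masks_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    for i in range(cfg.n_frames):
        frame, mask = generate_frame(cfg, rng)
        name = f"frame_{i:04d}.png"
        Image.fromarray(frame).save(out_images_dir / name)
        Image.fromarray(mask * 255).save(out_masks_dir / name)
    return index_dataset(out_images_dir, out_masks_dir)
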