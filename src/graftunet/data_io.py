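"""Dataset indexing, resizing, splitting, and contour-overlay rendering.

Datasets follow the paired-folder layout common to the public polyp
segmentation collections: an images folder and a masks folder holding
files with identical names, the mask being a binary PNG marking polyp
pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "DatasetIndex",
    "SplitSpec",
    "PairingError",
    "index_dataset",
    "split_dataset",
    "load_and_resize",
    "render_overlay",
    "save_mask",
    "load_mask",
]

IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}

#: Contour colours: the prediction is outlined blue, the ground truth red.
PRED_COLOR = (0, 0, 255)
GT_COLOR = (255, 0, 0)


class PairingError(ValueError):
    """Image/mask folders whose filenames do not pair one-to-one."""


@dataclass(frozen=True)
class DatasetIndex:
    """Sorted list of (image path, mask path) pairs."""

    pairs: tuple[tuple[Path, Path], ...]
    source_layout: str = "paired-folders"

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def subset(self, positions: Sequence[int]) -> "DatasetIndex":
        return DatasetIndex(tuple(self.pairs[i] for i in positions), self.source_layout)


@dataclass(frozen=True)
class SplitSpec:
    """Seeded random train/test split; default 70% training."""

    train_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def _listing(folder: Path) -> dict[str, Path]:
    return {
        p.name: p
        for p in sorted(folder.iterdir())
        if p.suffix.lower() in IMAGE_SUFFIXES
    }


def index_dataset(images_dir, masks_dir) -> DatasetIndex:
    """Pair image and mask files by identical filename, sorted.

    Raises :class:`PairingError` naming every orphan on either side.
    """
    images_dir, masks_dir = Path(images_dir), Path(masks_dir)
    for d in (images_dir, masks_dir):
        if not d.is_dir():
            raise FileNotFoundError(f"not a directory: {d}")
    imgs = _listing(images_dir)
    masks = _listing(masks_dir)
    orphan_imgs = sorted(set(imgs) - set(masks))
    orphan_masks = sorted(set(masks) - set(imgs))
    if orphan_imgs or orphan_masks:
        raise PairingError(
            f"unpaired files: images without masks {orphan_imgs}, "
            f"masks without images {orphan_masks}"
        )
    pairs = tuple((imgs[name], masks[name]) for name in sorted(imgs))
    return DatasetIndex(pairs)


def split_dataset(index: DatasetIndex, spec: SplitSpec) -> tuple[DatasetIndex, DatasetIndex]:
    """Disjoint, exhaustive, seed-deterministic train/test split.

    The training set size is round(train_fraction * n).
    """
    n = len(index)
    if n < 2:
        raise ValueError("need at least 2 pairs to split")
    n_train = int(np.floor(spec.train_fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    order = np.random.default_rng(spec.seed).permutation(n)
    return index.subset(sorted(order[:n_train])), index.subset(sorted(order[n_train:]))


def load_mask(path, threshold_frac: float = 0.5) -> np.ndarray:
    """Load a mask file as a strict 0/1 uint8 array (threshold at half max)."""
    arr = np.asarray(Image.open(path).convert("L"))
    mx = arr.max()
    if mx == 0:
        return np.zeros_like(arr, dtype=np.uint8)
    return (arr >= threshold_frac * mx).astype(np.uint8)


def save_mask(path, mask: np.ndarray) -> None:
    """Write a 0/1 (or boolean) mask as a 0/255 PNG."""
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255).save(path)


def load_and_resize(pair: tuple, target_h: int, target_w: int) -> tuple[np.ndarray, np.ndarray]:
    """Load one (image, mask) pair resized to the network input.

    The image is bilinearly resized (uint8 RGB); the mask is resized
    with nearest-neighbour interpolation then re-binarized at half its
    maximum, so it stays strictly 0/1.
    """
    img_path, mask_path = pair
    try:
        img = Image.open(img_path).convert("RGB")
        mask_img = Image.open(mask_path).convert("L")
    except Exception as exc:
        raise OSError(f"cannot read pair ({img_path}, {mask_path}): {exc}") from exc
    if img.size != (target_w, target_h):
        img = img.resize((target_w, target_h), Image.BILINEAR)
    if mask_img.size != (target_w, target_h):
        mask_img = mask_img.resize((target_w, target_h), Image.NEAREST)
    arr = np.asarray(img)
    marr = np.asarray(mask_img)
    mx = marr.max()
    mask = (marr >= 0.5 * mx).astype(np.uint8) if mx else np.zeros_like(marr, dtype=np.uint8)
    return arr, mask


def mask_contour(mask: np.ndarray) -> np.ndarray:
    """Boolean one-pixel inner boundary of a binary mask (4-connected)."""
    m = np.asarray(mask) > 0
    eroded = ndimage.binary_erosion(m, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    return m & ~eroded


def render_overlay(frame: np.ndarray, gt_mask: np.ndarray, pred_mask: np.ndarray) -> np.ndarray:
    """Outline the ground truth (red) and the prediction (blue) on the frame.

    The prediction contour is drawn last, so where the contours
    coincide the blue outline is visible on top.
    """
    frame = np.asarray(frame)
    if frame.ndim == 2:
        frame = np.stack([frame] * 3, axis=-1)
    if frame.shape[:2] != np.asarray(gt_mask).shape or frame.shape[:2] != np.asarray(pred_mask).shape:
        raise ValueError("frame and masks must share their spatial extent")
    out = frame.copy()
    out[mask_contour(gt_mask)] = GT_COLOR
    out[mask_contour(pred_mask)] = PRED_COLOR
    return out
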