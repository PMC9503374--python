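"""Training, prediction, and end-to-end experiment orchestration.

The optimizer is Adam on a binary cross-entropy loss over the sigmoid
output (a soft-Dice loss is available via ``loss="dice"``). Runs are
deterministic for fixed seeds: weight initialization, batch shuffling,
and the synthetic data are all driven by explicit generators.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import autograd as ag
from .arch import ArchConfig
from .autograd import Tensor
from .clahe import CLAHEParams, preprocess_dataset
from .data_io import (
    DatasetIndex,
    SplitSpec,
    index_dataset,
    load_and_resize,
    render_overlay,
    save_mask,
    split_dataset,
)
from .metrics import evaluate_both, evaluate_set
from .model import GraftUNet, build_network
from .synthetic import SyntheticConfig, generate_dataset

__all__ = ["TrainConfig", "RunReport", "Adam", "train", "predict", "run_experiment"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol.

    The published protocol fixes only the epoch count (40) and the
    70/30 split; loss, optimizer, batch size and learning rate are this
    package's own defaults (see docs/methods.md).
    """

    epochs: int = 40
    batch_size: int = 4
    learning_rate: float = 1e-4
    loss: str = "bce"  # "bce" | "dice"
    seed: int = 0
    input_size: int = 64
    preprocess: bool = False
    threshold: float = 0.5

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size >= 1 and learning_rate > 0 required")
        if self.loss not in ("bce", "dice"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class RunReport:
    """Per-epoch losses, final test metrics (both aggregations), timings."""

    epoch_losses: list[float] = field(default_factory=list)
    metrics: dict | None = None
    config: dict = field(default_factory=dict)
    wall_clock_s: float = 0.0

    def as_dict(self) -> dict:
        return {
            "epoch_losses": self.epoch_losses,
            "metrics": self.metrics,
            "config": self.config,
            "wall_clock_s": self.wall_clock_s,
        }


class Adam:
    """Standard Adam optimizer over a flat list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float, b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad * p.grad
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _load_arrays(index: DatasetIndex, size: int) -> tuple[np.ndarray, np.ndarray]:
    """All pairs as float32 images in [0,1] (N,H,W,3) and masks (N,H,W,1)."""
    imgs, masks = [], []
    for pair in index:
        img, mask = load_and_resize(pair, size, size)
        imgs.append(img.astype(np.float32) / 255.0)
        masks.append(mask.astype(np.float32)[..., None])
    return np.stack(imgs), np.stack(masks)


def train(
    index: DatasetIndex,
    arch: ArchConfig,
    cfg: TrainConfig,
    eval_index: DatasetIndex | None = None,
) -> tuple[GraftUNet, RunReport]:
    """Train on every pair in ``index``; optionally evaluate afterwards.

    Raises on an empty index and aborts with epoch context if the loss
    turns non-finite.
    """
    if len(index) == 0:
        raise ValueError("cannot train on an empty dataset index")
    t0 = time.time()
    model = GraftUNet(arch, seed=cfg.seed)
    x, y = _load_arrays(index, cfg.input_size)
    opt = Adam(model.parameters(), cfg.learning_rate)
    shuffle_rng = np.random.default_rng(cfg.seed + 1)
    report = RunReport(config={"arch": arch.__dict__ | {"filter_depths": list(arch.filter_depths)},
                               "train": cfg.__dict__})
    n = len(x)
    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.forward_logits(Tensor(x[idx]), training=True)
            if cfg.loss == "bce":
                loss = ag.bce_with_logits(logits, y[idx])
            else:
                loss = ag.soft_dice_loss(logits, y[idx])
            if not np.isfinite(loss.item()):
                raise FloatingPointError(f"non-finite loss at epoch {epoch + 1}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        report.epoch_losses.append(float(np.mean(losses)))
        log.info("epoch %d/%d loss %.4f", epoch + 1, cfg.epochs, report.epoch_losses[-1])
    if eval_index is not None and len(eval_index):
        xe, ye = _load_arrays(eval_index, cfg.input_size)
        probs = predict(model, xe)
        report.metrics = evaluate_both(list(probs), [m[..., 0] for m in ye], cfg.threshold)
    report.wall_clock_s = time.time() - t0
    return model, report


def predict(model: GraftUNet, frames: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Per-pixel polyp probabilities in (0, 1), shape (N, H, W).

    ``frames`` is (N, H, W, 3) float32 in [0, 1] (a single frame may be
    passed as (H, W, 3)).
    """
    arr = np.asarray(frames, dtype=np.float32)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    outs = []
    for start in range(0, len(arr), batch_size):
        p = model.forward(Tensor(arr[start : start + batch_size]), training=False)
        outs.append(p.data[..., 0])
    probs = np.concatenate(outs, axis=0)
    return probs[0] if single else probs


def run_experiment(config, out_dir=None) -> RunReport:
    """Execute the full pipeline described by a YAML config (or dict).

    Stages: optional synthetic-data generation, optional CLAHE
    preprocessing, indexing, a seeded 70/30 split, training, evaluation
    in both aggregation modes, and overlay rendering. Writes
    ``report.json``, prediction masks, overlays and a checkpoint under
    ``out_dir``. Any stage failure aborts with the stage name.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out_dir = Path(out_dir or config.get("out_dir", "runs/latest"))
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "configure"
    try:
        arch = ArchConfig(**config.get("arch", {"input_h": 64, "input_w": 64}))
        tcfg = TrainConfig(**config.get("train", {}))
        stage = "synthesize"
        if "synthetic" in config:
            scfg = SyntheticConfig(**config["synthetic"])
            data_dir = out_dir / "data"
            generate_dataset(scfg, data_dir / "images", data_dir / "masks")
            images_dir, masks_dir = data_dir / "images", data_dir / "masks"
        else:
            images_dir = Path(config["images_dir"])
            masks_dir = Path(config["masks_dir"])
        stage = "preprocess"
        if tcfg.preprocess:
            params = CLAHEParams(**config.get("clahe", {}))
            pre_dir = out_dir / "preprocessed"
            preprocess_dataset(images_dir, pre_dir, params)
            images_dir = pre_dir
        stage = "index"
        index = index_dataset(images_dir, masks_dir)
        stage = "split"
        split = SplitSpec(**config.get("split", {"seed": tcfg.seed}))
        train_idx, test_idx = split_dataset(index, split)
        stage = "train"
        model, report = train(train_idx, arch, tcfg, eval_index=test_idx)
        stage = "evaluate"
        xe, ye = _load_arrays(test_idx, tcfg.input_size)
        probs = predict(model, xe)
        pred_dir = out_dir / "predictions"
        overlay_dir = out_dir / "overlays"
        pred_dir.mkdir(exist_ok=True)
        overlay_dir.mkdir(exist_ok=True)
        from PIL import Image  # local: only needed for overlay output

        for (img_path, _), prob, mask, frame in zip(test_idx, probs, ye, xe):
            binm = (prob >= tcfg.threshold).astype(np.uint8)
            save_mask(pred_dir / img_path.name, binm)
            ov = render_overlay((frame * 255).astype(np.uint8), mask[..., 0].astype(np.uint8), binm)
            Image.fromarray(ov).save(overlay_dir / img_path.name)
        stage = "report"
        model.save(out_dir / "checkpoint.npz")
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report.as_dict(), fh, indent=2)
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
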