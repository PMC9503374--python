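"""Train a small network on synthetic frames and evaluate it.

Uses a 64x64 input so the run finishes in about a minute on one CPU
core. The pipeline: generate 40 frames, split 70/30 with a fixed seed,
train with Adam on binary cross-entropy, then report all six metrics
under both aggregation modes (mean of per-image scores, and scores of
the pooled pixel-level confusion counts).

Run from the repository root:
    python examples/04_train_and_evaluate.py
"""

import numpy as np

from graftunet import (
    ArchConfig,
    SplitSpec,
    SyntheticConfig,
    TrainConfig,
    generate_dataset,
    predict,
    split_dataset,
    train,
)
from graftunet.training import _load_arrays

index = generate_dataset(
    SyntheticConfig(n_frames=40, frame_size=64, seed=11),
    "runs/example_train/images",
    "runs/example_train/masks",
)
train_idx, test_idx = split_dataset(index, SplitSpec(train_fraction=0.7, seed=0))
print(f"{len(train_idx)} training frames, {len(test_idx)} test frames")

arch = ArchConfig(input_h=64, input_w=64)
cfg = TrainConfig(epochs=15, batch_size=4, learning_rate=1e-4, seed=0, input_size=64)
model, report = train(train_idx, arch, cfg, eval_index=test_idx)

print(f"loss: {report.epoch_losses[0]:.4f} (epoch 1) -> {report.epoch_losses[-1]:.4f} (epoch {cfg.epochs})")
for mode, scores in report.metrics.items():
    print(f"{mode}: " + "  ".join(f"{k}={v:.4f}" for k, v in scores.items() if k != "aggregation"))

# per-frame probabilities for the first test frame
x, _ = _load_arrays(test_idx, 64)
probs = predict(model, x[0])
print(f"first test frame: max probability {probs.max():.3f}, "
      f"predicted polyp area {(probs >= cfg.threshold).sum()} px")
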