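"""Segmentation metrics from confusion counts, and contour overlays.

All six metrics (Dice, IoU, recall, precision, F2, accuracy) are pure
functions of the pixel confusion counts (tp, fp, fn, tn). This script
works through a hand-checkable example, shows the two aggregation
modes, and renders a ground-truth (red) versus prediction (blue)
contour overlay.

Run from the repository root:
    python examples/05_metrics_and_overlays.py
"""

import pathlib

import numpy as np
from PIL import Image

from graftunet import ConfusionCounts, SyntheticConfig, metrics_from_counts, render_overlay
from graftunet.metrics import evaluate_set
from graftunet.synthetic import generate_frame

# hand-checkable confusion counts: dice = 2*3/(2*3+1+2) = 2/3
counts = ConfusionCounts(tp=3, fp=1, fn=2, tn=4)
report = metrics_from_counts(counts)
print(f"tp=3 fp=1 fn=2 tn=4 -> dice={report.mdice:.4f} iou={report.miou:.4f} "
      f"recall={report.recall:.4f} precision={report.precision:.4f} accuracy={report.accuracy:.4f}")

# aggregation modes differ when per-image quality varies
gt = np.ones((4, 4), dtype=int)
perfect, quarter = np.ones((4, 4)), np.zeros((4, 4))
quarter[0] = 1.0
per_image = evaluate_set([perfect, quarter], [gt, gt], aggregation="per_image_mean")
pooled = evaluate_set([perfect, quarter], [gt, gt], aggregation="global_counts")
print(f"per-image-mean dice = {per_image.mdice:.4f}, global-counts dice = {pooled.mdice:.4f}")

# overlay: shift the true mask to fake an imperfect prediction
frame, mask = generate_frame(SyntheticConfig(frame_size=96, seed=5), np.random.default_rng(5))
pred = np.roll(mask, shift=(3, 3), axis=(0, 1))
overlay = render_overlay(frame, mask, pred)
out = "runs/example_overlay.png"
pathlib.Path(out).parent.mkdir(parents=True, exist_ok=True)
Image.fromarray(overlay).save(out)
print(f"overlay written to {out} (ground truth red, prediction blue)")
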