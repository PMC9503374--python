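"""Generate a small synthetic colonoscopy dataset and inspect it.

The generator produces RGB frames that mimic the statistics a polyp
segmentation network cares about: a pink-red mucosa texture, a dark
lumen region toward one corner, one to three raised polyp blobs that
are brighter and redder than their surroundings, optional specular
highlights, and pixel noise. Masks are written as 0/255 PNGs whose
filenames match the frames.

Run from the repository root:
    python examples/01_generate_synthetic_dataset.py
"""

import numpy as np

from graftunet import SyntheticConfig, generate_dataset, load_mask

cfg = SyntheticConfig(n_frames=24, frame_size=96, seed=42)
index = generate_dataset(cfg, "runs/example_data/images", "runs/example_data/masks")

print(f"wrote {len(index)} frame/mask pairs")
areas = np.array([int(load_mask(mask_path).sum()) for _, mask_path in index])
print(f"polyp area per frame: min={areas.min()} median={int(np.median(areas))} max={areas.max()}")
print("first pair:", index.pairs[0][0], "<->", index.pairs[0][1])
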