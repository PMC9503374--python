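"""Dataset pairing, splitting, resizing, and overlay rendering."""

from pathlib import Path

import numpy as np
import pytest
from PIL import Image

from graftunet.data_io import (
    DatasetIndex,
    PairingError,
    SplitSpec,
    index_dataset,
    load_and_resize,
    load_mask,
    mask_contour,
    render_overlay,
    save_mask,
    split_dataset,
)


def _write_pairs(root: Path, names, sizes=None):
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(0)
    for i, name in enumerate(names):
        size = (sizes or {}).get(name, (20, 20))
        Image.fromarray(rng.integers(0, 255, size=(*size, 3), dtype=np.uint8)).save(
            root / "images" / name
        )
        mask = np.zeros(size, dtype=np.uint8)
        mask[: size[0] // 2] = 255
        Image.fromarray(mask).save(root / "masks" / name)


def test_index_matches_pairs_sorted(tmp_path):
    names = [f"x_{i}.png" for i in range(10)]
    _write_pairs(tmp_path, names)
    index = index_dataset(tmp_path / "images", tmp_path / "masks")
    assert len(index) == 10
    assert [p.name for p, _ in index] == sorted(names)
    assert all(p.name == m.name for p, m in index)


def test_index_reports_orphans_by_name(tmp_path):
    _write_pairs(tmp_path, [f"x_{i}.png" for i in range(10)])
    (tmp_path / "masks" / "x_3.png").unlink()
    with pytest.raises(PairingError, match="x_3.png"):
        index_dataset(tmp_path / "images", tmp_path / "masks")


def _fake_index(n):
    pairs = tuple((Path(f"i{i}.png"), Path(f"i{i}.png")) for i in range(n))
    return DatasetIndex(pairs)


@pytest.mark.parametrize("n, expected_train", [(1000, 700), (10, 7), (3, 2)])
def test_split_sizes_follow_the_70_30_ratio(n, expected_train):
    train, test = split_dataset(_fake_index(n), SplitSpec(train_fraction=0.7, seed=1))
    assert len(train) == expected_train
    assert len(test) == n - expected_train


def test_split_is_deterministic_disjoint_and_exhaustive():
    index = _fake_index(50)
    spec = SplitSpec(train_fraction=0.7, seed=42)
    t1, e1 = split_dataset(index, spec)
    t2, e2 = split_dataset(index, spec)
    assert t1.pairs == t2.pairs and e1.pairs == e2.pairs
    names = {p.name for p, _ in t1} | {p.name for p, _ in e1}
    assert len(names) == 50
    assert not ({p.name for p, _ in t1} & {p.name for p, _ in e1})


def test_different_seeds_give_different_partitions():
    index = _fake_index(50)
    t1, _ = split_dataset(index, SplitSpec(seed=0))
    t2, _ = split_dataset(index, SplitSpec(seed=1))
    assert t1.pairs != t2.pairs


def test_load_and_resize_to_network_input(tmp_path):
    # emulate a 384x288 clinical frame resized to 512
    _write_pairs(tmp_path, ["a.png"], sizes={"a.png": (288, 384)})
    index = index_dataset(tmp_path / "images", tmp_path / "masks")
    img, mask = load_and_resize(index.pairs[0], 512, 512)
    assert img.shape == (512, 512, 3)
    assert mask.shape == (512, 512)
    assert set(np.unique(mask)) <= {0, 1}


def test_mask_passthrough_when_already_target_size(tmp_path):
    _write_pairs(tmp_path, ["b.png"], sizes={"b.png": (32, 32)})
    index = index_dataset(tmp_path / "images", tmp_path / "masks")
    _, mask = load_and_resize(index.pairs[0], 32, 32)
    original = load_mask(index.pairs[0][1])
    np.testing.assert_array_equal(mask, original)


def test_checkerboard_mask_resize_stays_binary(tmp_path):
    (tmp_path / "m").mkdir()
    checker = (np.indices((64, 64)).sum(axis=0) % 2 * 255).astype(np.uint8)
    Image.fromarray(checker).save(tmp_path / "m" / "c.png")
    (tmp_path / "i").mkdir()
    Image.fromarray(np.zeros((64, 64, 3), dtype=np.uint8)).save(tmp_path / "i" / "c.png")
    _, mask = load_and_resize((tmp_path / "i" / "c.png", tmp_path / "m" / "c.png"), 24, 24)
    assert set(np.unique(mask)) <= {0, 1}


def test_save_load_mask_roundtrip(tmp_path):
    mask = (np.random.default_rng(1).random((16, 16)) > 0.5).astype(np.uint8)
    save_mask(tmp_path / "m.png", mask)
    stored = np.asarray(Image.open(tmp_path / "m.png"))
    assert set(np.unique(stored)) <= {0, 255}
    np.testing.assert_array_equal(load_mask(tmp_path / "m.png"), mask)


# ---------------------------------------------------------------------------
# overlays


def _boundary_oracle(mask):
    """A pixel is boundary iff inside the mask with a 4-neighbour outside
    (image border counts as outside)."""
    m = np.asarray(mask) > 0
    h, w = m.shape
    out = np.zeros_like(m)
    for y in range(h):
        for x in range(w):
            if not m[y, x]:
                continue
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ny, nx = y + dy, x + dx
                if not (0 <= ny < h and 0 <= nx < w) or not m[ny, nx]:
                    out[y, x] = True
                    break
    return out


def test_blue_contour_pixels_match_boundary_oracle():
    rng = np.random.default_rng(2)
    frame = rng.integers(0, 200, size=(24, 24, 3), dtype=np.uint8)
    pred = np.zeros((24, 24), dtype=np.uint8)
    pred[4:10, 4:10] = 1
    gt = np.zeros_like(pred)
    gt[14:20, 14:20] = 1  # disjoint from pred
    overlay = render_overlay(frame, gt, pred)
    blue = np.all(overlay == (0, 0, 255), axis=-1)
    np.testing.assert_array_equal(blue, _boundary_oracle(pred))
    red = np.all(overlay == (255, 0, 0), axis=-1)
    np.testing.assert_array_equal(red, _boundary_oracle(gt))


def test_identical_masks_contours_coincide():
    frame = np.zeros((16, 16, 3), dtype=np.uint8)
    m = np.zeros((16, 16), dtype=np.uint8)
    m[5:11, 5:11] = 1
    overlay = render_overlay(frame, m, m)
    blue = np.all(overlay == (0, 0, 255), axis=-1)
    np.testing.assert_array_equal(blue, mask_contour(m))
    assert not np.any(np.all(overlay == (255, 0, 0), axis=-1))  # red fully covered


def test_empty_prediction_leaves_only_red():
    frame = np.zeros((16, 16, 3), dtype=np.uint8)
    gt = np.zeros((16, 16), dtype=np.uint8)
    gt[3:9, 3:9] = 1
    overlay = render_overlay(frame, gt, np.zeros_like(gt))
    assert np.any(np.all(overlay == (255, 0, 0), axis=-1))
    assert not np.any(np.all(overlay == (0, 0, 255), axis=-1))


def test_overlay_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        render_overlay(np.zeros((8, 8, 3)), np.zeros((8, 8)), np.zeros((8, 9)))
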