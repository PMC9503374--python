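"""Semantics of the graft block, squeeze-excitation, batch norm, and the
assembled network, checked against hand arithmetic and independent
reference computations."""

import numpy as np
import pytest
from scipy.signal import correlate

from graftunet import autograd as ag
from graftunet.arch import ArchConfig
from graftunet.autograd import Tensor
from graftunet.model import (
    BatchNorm2d,
    GraftStage,
    GraftUNet,
    SqueezeExcite,
    build_network,
    graft_block_forward,
    squeeze_excite,
)


def _identity_kernel(c: int) -> np.ndarray:
    w = np.zeros((3, 3, c, c), dtype=np.float32)
    for i in range(c):
        w[1, 1, i, i] = 1.0
    return w


def _neutralize_bn(bn: BatchNorm2d) -> None:
    """Make inference-mode batch norm an exact identity."""
    bn.eps = 0.0
    bn.running_mean[:] = 0.0
    bn.running_var[:] = 1.0


def _fresh_stage(c_in=4, depth=4, seed=7) -> GraftStage:
    cfg = ArchConfig(input_h=64, input_w=64)
    return GraftStage(c_in, depth, cfg, np.random.default_rng(seed))


def test_graft_block_zeroed_graft_branch_reduces_to_conventional():
    stage = _fresh_stage()
    for bn in (stage.stem_bn, stage.conv_bn, stage.graft_bn):
        _neutralize_bn(bn)
    stage.graft_branch.w.data[:] = 0.0
    stage.graft_branch.b.data[:] = 0.0
    x = np.random.default_rng(0).random((1, 8, 8, 4), dtype=np.float32)
    h = graft_block_forward(stage, x).data
    stem = ag.relu(stage.stem(Tensor(x))).data
    lam = ag.relu(stage.conv_branch(Tensor(stem))).data
    np.testing.assert_array_equal(h, lam)


def test_graft_block_identity_branches_double_the_stem():
    stage = _fresh_stage()
    for bn in (stage.stem_bn, stage.conv_bn, stage.graft_bn):
        _neutralize_bn(bn)
    for conv in (stage.conv_branch, stage.graft_branch):
        conv.w.data = _identity_kernel(4)
        conv.b.data[:] = 0.0
    x = np.random.default_rng(1).random((1, 6, 6, 4), dtype=np.float32)
    h = graft_block_forward(stage, x).data
    stem = ag.relu(stage.stem(Tensor(x))).data  # non-negative, so identity branches pass it through
    np.testing.assert_allclose(h, 2.0 * stem, rtol=1e-6)


def _reference_conv(x, w, b):
    """Independent 'Same' cross-correlation via scipy, one output channel at a time."""
    n, h, w_, ci = x.shape
    co = w.shape[-1]
    out = np.zeros((n, h, w_, co))
    for ni in range(n):
        for o in range(co):
            acc = np.zeros((h, w_))
            for c in range(ci):
                acc += correlate(x[ni, :, :, c], w[:, :, c, o], mode="same")
            out[ni, :, :, o] = acc + b[o]
    return out


def test_graft_block_matches_independent_two_branch_reference():
    """Forward pass equals stem->two parallel conv branches->sum computed
    with an independent scipy-based convolution on random 8x8x4 tensors."""
    stage = _fresh_stage(c_in=4, depth=4, seed=11)
    for bn in (stage.stem_bn, stage.conv_bn, stage.graft_bn):
        _neutralize_bn(bn)
    x = np.random.default_rng(2).standard_normal((2, 8, 8, 4)).astype(np.float32)
    got = graft_block_forward(stage, x).data

    stem_ref = np.maximum(_reference_conv(x, stage.stem.w.data, stage.stem.b.data), 0.0)
    lam = np.maximum(_reference_conv(stem_ref, stage.conv_branch.w.data, stage.conv_branch.b.data), 0.0)
    vth = np.maximum(_reference_conv(stem_ref, stage.graft_branch.w.data, stage.graft_branch.b.data), 0.0)
    np.testing.assert_allclose(got, lam + vth, atol=1e-5)


def test_branch_and_sum_shapes_agree():
    stage = _fresh_stage()
    x = np.random.default_rng(3).random((1, 8, 8, 4), dtype=np.float32)
    s = ag.relu(stage.stem_bn(stage.stem(Tensor(x)), False))
    lam = ag.relu(stage.conv_bn(stage.conv_branch(s), False))
    vth = ag.relu(stage.graft_bn(stage.graft_branch(s), False))
    assert lam.shape == vth.shape
    np.testing.assert_array_equal(ag.add(lam, vth).data, lam.data + vth.data)


def test_squeeze_excite_identity_when_gates_forced_to_one():
    se = SqueezeExcite(4, 2, np.random.default_rng(0))
    se.w1.data[:] = 0.0
    se.b1.data[:] = 0.0
    se.w2.data[:] = 0.0
    se.b2.data[:] = 500.0  # sigmoid(500) == 1.0 in float32
    x = np.random.default_rng(4).random((2, 4, 4, 4), dtype=np.float32)
    np.testing.assert_array_equal(squeeze_excite(x, se).data, x)


def test_squeeze_excite_gates_bound_the_output():
    se = SqueezeExcite(4, 2, np.random.default_rng(1))
    x = np.random.default_rng(5).random((2, 4, 4, 4), dtype=np.float32)
    y = squeeze_excite(x, se).data
    g = se.gates(Tensor(x)).data
    assert np.all((g > 0) & (g < 1))
    assert np.all(np.abs(y) <= np.abs(x) + 1e-7)


def test_squeeze_excite_matches_hand_computed_gate():
    se = SqueezeExcite(4, 4, np.random.default_rng(2))  # reduction 4 -> width 1
    x = np.arange(4, dtype=np.float32).reshape(1, 1, 1, 4)
    squeezed = x.max(axis=(1, 2))  # (1, 4)
    h = np.maximum(squeezed @ se.w1.data + se.b1.data, 0)
    gate = 1 / (1 + np.exp(-(h @ se.w2.data + se.b2.data)))
    np.testing.assert_allclose(squeeze_excite(x, se).data, x * gate[:, None, None, :], rtol=1e-6)


def test_batchnorm_hand_example_and_centering():
    # batch {1, 3}: mean 2, variance 1 -> normalized {-1, +1} for sigma << 1
    x = np.array([1.0, 3.0], dtype=np.float32).reshape(2, 1, 1, 1)
    out, m, v = ag.batchnorm2d(Tensor(x), Tensor(np.ones(1)), Tensor(np.zeros(1)), eps=1e-12)
    assert m[0] == 2.0 and v[0] == 1.0
    np.testing.assert_allclose(out.data.ravel(), [-1.0, 1.0], atol=1e-5)

    rng = np.random.default_rng(6)
    xb = rng.standard_normal((8, 3, 3, 2)).astype(np.float32)
    out, _, _ = ag.batchnorm2d(Tensor(xb), Tensor(np.ones(2)), Tensor(np.zeros(2)))
    assert np.abs(out.data.mean(axis=(0, 1, 2))).max() < 1e-6


def test_batchnorm_constant_batch_maps_to_zero():
    x = np.full((4, 2, 2, 3), 7.0, dtype=np.float32)
    out, _, _ = ag.batchnorm2d(Tensor(x), Tensor(np.ones(3)), Tensor(np.zeros(3)))
    np.testing.assert_allclose(out.data, 0.0, atol=1e-3)


def test_network_output_in_open_unit_interval():
    model, trace = build_network(ArchConfig(input_h=64, input_w=64), seed=0)
    x = np.random.default_rng(7).random((2, 64, 64, 3), dtype=np.float32)
    p = model.forward(Tensor(x)).data
    assert p.shape == (2, 64, 64, 1)
    assert np.all((p > 0) & (p < 1))
    assert trace.final_shape() == (64, 64, 1)


def test_checkpoint_roundtrip_reproduces_predictions(tmp_path):
    cfg = ArchConfig(input_h=64, input_w=64)
    model = GraftUNet(cfg, seed=3)
    x = np.random.default_rng(8).random((1, 64, 64, 3), dtype=np.float32)
    p1 = model.forward(Tensor(x)).data
    path = tmp_path / "ckpt.npz"
    model.save(path)
    other = GraftUNet(cfg, seed=99)
    other.load(path)
    np.testing.assert_array_equal(other.forward(Tensor(x)).data, p1)
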