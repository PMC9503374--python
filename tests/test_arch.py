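"""Symbolic shape propagation and conformance with the published layer table."""

import numpy as np
import pytest

from graftunet.arch import (
    ArchConfig,
    ConfigError,
    ConvGeometry,
    GeometryError,
    conv_output_extent,
    build_decoder_stage,
    build_encoder_stage,
    load_table2,
    parameter_count_formula,
    trace_network,
    verify_against_table2,
)
from graftunet.model import GraftUNet, count_parameters


@pytest.mark.parametrize(
    "i, f, p, s, expected",
    [
        (512, 3, 1, 1, 512),  # "Same" convolution preserves extent
        (512, 3, 1, 2, 256),  # first pooling halves 512
        (512, 3, 0, 1, 510),  # valid convolution
        (7, 3, 0, 2, 3),
        (1, 1, 0, 1, 1),
    ],
)
def test_conv_output_extent(i, f, p, s, expected):
    assert conv_output_extent(ConvGeometry(i, f, p, s)) == expected


def test_conv_geometry_rejects_negative_numerator():
    with pytest.raises(GeometryError):
        ConvGeometry(2, 5, 0, 1)


def test_arch_config_validation():
    with pytest.raises(ConfigError):
        ArchConfig(input_h=100, input_w=100)  # not divisible by 2^5
    with pytest.raises(ConfigError):
        ArchConfig(filter_depths=(8, 16, 32, 48))
    with pytest.raises(ConfigError):
        ArchConfig(filter_depths=(8, 16, 0, 48, 64))


@pytest.mark.parametrize(
    "stage, in_shape, pre_pool, post_pool",
    [
        (1, (512, 512, 3), (512, 512, 8), (256, 256, 8)),
        (5, (32, 32, 48), (32, 32, 64), (16, 16, 64)),
        (1, (32, 32, 3), (32, 32, 8), (16, 16, 8)),
    ],
)
def test_encoder_stage_shapes(stage, in_shape, pre_pool, post_pool):
    cfg = ArchConfig(input_h=512, input_w=512)
    spec, pre, post = build_encoder_stage(cfg, stage, in_shape)
    assert pre == pre_pool
    assert post == post_pool
    assert spec.branch_shape == spec.stem_shape  # H(x) shape = branch shapes


@pytest.mark.parametrize(
    "stage, in_shape, skip_shape, cnc, out",
    [
        (1, (16, 16, 64), (32, 32, 64), (32, 32, 128), (32, 32, 64)),
        (5, (256, 256, 16), (512, 512, 8), (512, 512, 24), (512, 512, 8)),
        (1, (2, 2, 64), (4, 4, 64), (4, 4, 128), (4, 4, 64)),  # 64x64-input network
    ],
)
def test_decoder_stage_shapes(stage, in_shape, skip_shape, cnc, out):
    cfg = ArchConfig()
    spec = build_decoder_stage(cfg, stage, in_shape, skip_shape)
    assert spec.concat_shape == cnc
    assert spec.out_shape == out
    assert spec.concat_shape[2] == spec.upsampled_shape[2] + spec.skip_shape[2]


def test_decoder_stage_rejects_spatial_mismatch():
    with pytest.raises(ConfigError, match="stage 2"):
        build_decoder_stage(ArchConfig(), 2, (16, 16, 64), (64, 64, 48))


def test_default_trace_conforms_to_published_table():
    trace = trace_network(ArchConfig())
    assert verify_against_table2(trace) == []
    assert len(trace.tabular()) == len(load_table2()) == 81


def test_trace_cnc_channels_and_head():
    trace = trace_network(ArchConfig())
    assert trace.cnc_channels() == [128, 112, 80, 48, 24]
    assert trace.final_shape() == (512, 512, 1)


def test_trace_scales_with_input_extent():
    trace = trace_network(ArchConfig(input_h=64, input_w=64))
    assert trace.final_shape() == (64, 64, 1)


def test_perturbed_depths_mismatch_localizes_to_late_stages():
    trace = trace_network(ArchConfig(filter_depths=(8, 16, 32, 64, 64)))
    mismatches = verify_against_table2(trace)
    assert mismatches  # stage 4 depth 64 != published 48
    # stages 1-3 (table rows up to the third pooling, row 31) are clean
    assert all(int(m.split()[1].rstrip(":").rstrip("(")) > 31 for m in mismatches)


def test_every_trace_extent_matches_the_output_size_formula():
    """Each C/MP output extent equals floor((I - f + 2p)/S) + 1 applied per layer."""
    cfg = ArchConfig()
    prev = (cfg.input_h, cfg.input_w, cfg.input_c)
    for entry in trace_network(cfg):
        if entry.kind == "C":
            expect = conv_output_extent(ConvGeometry(prev[0], cfg.kernel, 1, 1))
            assert entry.shape[0] == entry.shape[1] == expect
        elif entry.kind == "MP":
            expect = conv_output_extent(ConvGeometry(prev[0], cfg.pool_window, 1, cfg.pool_stride))
            assert entry.shape[0] == entry.shape[1] == expect
        elif entry.kind == "UPS":
            assert entry.shape[0] == 2 * prev[0]
        prev = entry.shape


def test_spatial_dims_halve_at_mp_and_double_at_ups():
    prev = None
    for entry in trace_network(ArchConfig()):
        if prev is not None:
            if entry.kind == "MP":
                assert entry.shape[0] * 2 == prev.shape[0]
                assert entry.shape[1] * 2 == prev.shape[1]
            if entry.kind == "UPS":
                assert entry.shape[0] == 2 * prev.shape[0]
        prev = entry


def test_parameter_count_matches_per_row_oracle():
    """Model parameter count equals a spreadsheet walk over the layer trace.

    Convolution rows contribute f*f*c_in*c_out + c_out (c_in read from the
    preceding trace row), batch-norm rows 2*c.
    """
    cfg = ArchConfig(input_h=64, input_w=64)
    model = GraftUNet(cfg, seed=0)
    trace = trace_network(cfg)
    total = 0
    prev_c = None
    for entry in trace.tabular():
        if entry.kind == "C":
            total += 3 * 3 * prev_c * entry.shape[2] + entry.shape[2]
        elif entry.kind == "BN":
            total += 2 * entry.shape[2]
        prev_c = entry.shape[2]
    assert count_parameters(model) == total == parameter_count_formula(cfg)


def test_single_conv_parameter_count():
    from graftunet.model import Conv2d

    conv = Conv2d(3, 8, 3, np.random.default_rng(0))
    assert sum(p.data.size for p in conv.parameters()) == 3 * 3 * 3 * 8 + 8 == 224


def test_se_enabled_trace_still_matches_table_rows():
    # squeeze-excitation is not a published table row; with it enabled the
    # tabular subset of the trace must still conform
    trace = trace_network(ArchConfig(se_enabled=True))
    assert verify_against_table2(trace) == []
    assert any(e.kind == "SE" for e in trace)
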