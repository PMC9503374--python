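"""Symbolic Graft-U-Net architecture: configuration, shape propagation, trace.

The network is a five-stage encoder/decoder. Each encoder stage (a
down-sample block, DSB) is a stem convolution followed by two parallel
convolution branches — the conventional branch and the "graft" branch —
whose feature maps are added element-wise before 3x3/stride-2 max
pooling. Each decoder stage (an up-sample block, USB) doubles the
spatial extent, concatenates the mirrored encoder skip along channels,
and convolves. A final 1-channel convolution with a sigmoid produces
the mask probability map.

Everything here is symbolic: shapes only, no weights. The companion
:mod:`graftunet.model` builds the runnable network from the same trace.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from math import floor

__all__ = [
    "ArchConfig",
    "ConvGeometry",
    "GraftBlockSpec",
    "DecoderStageSpec",
    "TraceEntry",
    "LayerTrace",
    "conv_output_extent",
    "build_encoder_stage",
    "build_decoder_stage",
    "trace_network",
    "load_table2",
    "verify_against_table2",
    "parameter_count_formula",
]

#: Layer kinds that appear as rows of the published layer table.
TABLE_KINDS = {"input", "C", "BN", "A", "MP", "UPS", "CNC"}

#: Decoder convolution depths, mirroring the encoder depths in reverse.
DECODER_DEPTHS = (64, 48, 32, 16, 8)


class ConfigError(ValueError):
    """Invalid architecture configuration."""


class GeometryError(ValueError):
    """Convolution geometry with a negative output extent."""


@dataclass(frozen=True)
class ArchConfig:
    """Declarative description of the network.

    Defaults reproduce the published 512x512x3 configuration with
    filter depths 8, 16, 32, 48, 64 and 3x3 kernels throughout.
    """

    input_h: int = 512
    input_w: int = 512
    input_c: int = 3
    filter_depths: tuple[int, ...] = (8, 16, 32, 48, 64)
    kernel: int = 3
    pool_window: int = 3
    pool_stride: int = 2
    se_enabled: bool = False
    se_reduction: int = 4

    def __post_init__(self):
        object.__setattr__(self, "filter_depths", tuple(self.filter_depths))
        if len(self.filter_depths) != 5:
            raise ConfigError("filter_depths must list exactly 5 stage depths")
        if any(d <= 0 for d in self.filter_depths):
            raise ConfigError("filter depths must be strictly positive")
        if self.input_h % 32 or self.input_w % 32:
            raise ConfigError(
                "input extent must be divisible by 2^5 so five poolings halve exactly; "
                f"got {self.input_h}x{self.input_w}"
            )
        if self.input_c < 1 or self.kernel < 1 or self.se_reduction < 1:
            raise ConfigError("input_c, kernel and se_reduction must be >= 1")


@dataclass(frozen=True)
class ConvGeometry:
    """One spatial dimension of a convolution/pooling window application."""

    i_size: int
    f_size: int
    p: int
    s: int

    def __post_init__(self):
        if self.s < 1:
            raise GeometryError("stride must be >= 1")
        if self.i_size - self.f_size + 2 * self.p < 0:
            raise GeometryError(
                f"window {self.f_size} exceeds padded input {self.i_size} + 2*{self.p}"
            )


def conv_output_extent(g: ConvGeometry) -> int:
    """Output extent floor((I - f + 2p)/S) + 1 of a window scan."""
    return floor((g.i_size - g.f_size + 2 * g.p) / g.s) + 1


@dataclass(frozen=True)
class TraceEntry:
    name: str
    kind: str  # C | BN | A | MP | UPS | CNC | input | ADD | SE
    shape: tuple[int, int, int]  # (h, w, c)


@dataclass
class LayerTrace:
    """Ordered record of every layer's output shape."""

    entries: list[TraceEntry] = field(default_factory=list)

    def append(self, name: str, kind: str, shape: tuple[int, int, int]) -> None:
        self.entries.append(TraceEntry(name, kind, tuple(int(v) for v in shape)))

    def tabular(self) -> list[TraceEntry]:
        """Entries that correspond to rows of the published layer table."""
        return [e for e in self.entries if e.kind in TABLE_KINDS]

    def cnc_channels(self) -> list[int]:
        return [e.shape[2] for e in self.entries if e.kind == "CNC"]

    def final_shape(self) -> tuple[int, int, int]:
        return self.entries[-1].shape

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def format(self) -> str:
        lines = [f"{'#':>3}  {'layer':<8} {'kind':<5} shape"]
        for i, e in enumerate(self.entries, 1):
            h, w, c = e.shape
            lines.append(f"{i:>3}  {e.name:<8} {e.kind:<5} {h} x {w} x {c}")
        return "\n".join(lines)


@dataclass(frozen=True)
class GraftBlockSpec:
    """Symbolic description of one encoder stage (DSB).

    The stem convolution lifts the incoming map to ``depth`` channels;
    the conventional and graft branches each convolve the stem output at
    the same depth, and the stage output H(x) is their element-wise sum.
    """

    stage_index: int
    depth: int
    in_shape: tuple[int, int, int]
    stem_shape: tuple[int, int, int]
    branch_shape: tuple[int, int, int]  # both branches and H(x)
    post_pool_shape: tuple[int, int, int]


@dataclass(frozen=True)
class DecoderStageSpec:
    """Symbolic description of one decoder stage (USB)."""

    stage_index: int
    depth: int
    in_shape: tuple[int, int, int]
    upsampled_shape: tuple[int, int, int]
    skip_shape: tuple[int, int, int]
    concat_shape: tuple[int, int, int]
    out_shape: tuple[int, int, int]


def _same_pad(k: int) -> int:
    return (k - 1) // 2


def build_encoder_stage(
    cfg: ArchConfig, stage: int, in_shape: tuple[int, int, int]
) -> tuple[GraftBlockSpec, tuple[int, int, int], tuple[int, int, int]]:
    """Shape-propagate one encoder DSB.

    Returns ``(spec, pre_pool_shape, post_pool_shape)`` where the
    pre-pool shape is the H(x) map that also feeds the decoder skip.
    """
    if not 1 <= stage <= 5:
        raise ConfigError("encoder stage index must be in 1..5")
    h, w, _ = in_shape
    if h < cfg.pool_window or w < cfg.pool_window:
        raise ConfigError(f"stage {stage}: spatial extent {h}x{w} below pool window")
    depth = cfg.filter_depths[stage - 1]
    p = _same_pad(cfg.kernel)
    hc = conv_output_extent(ConvGeometry(h, cfg.kernel, p, 1))
    wc = conv_output_extent(ConvGeometry(w, cfg.kernel, p, 1))
    stem = (hc, wc, depth)
    branch = (hc, wc, depth)
    hp = conv_output_extent(ConvGeometry(hc, cfg.pool_window, 1, cfg.pool_stride))
    wp = conv_output_extent(ConvGeometry(wc, cfg.pool_window, 1, cfg.pool_stride))
    if 2 * hp != hc or 2 * wp != wc:
        raise ConfigError(f"stage {stage}: pooling does not halve {hc}x{wc} exactly")
    post = (hp, wp, depth)
    spec = GraftBlockSpec(stage, depth, tuple(in_shape), stem, branch, post)
    return spec, branch, post


def build_decoder_stage(
    cfg: ArchConfig,
    stage: int,
    in_shape: tuple[int, int, int],
    skip_shape: tuple[int, int, int],
) -> DecoderStageSpec:
    """Shape-propagate one decoder USB (upsample -> concat skip -> conv)."""
    if not 1 <= stage <= 5:
        raise ConfigError("decoder stage index must be in 1..5")
    h, w, c = in_shape
    up = (2 * h, 2 * w, c)
    if up[:2] != tuple(skip_shape[:2]):
        raise ConfigError(
            f"decoder stage {stage}: upsampled extent {up[0]}x{up[1]} does not match "
            f"skip extent {skip_shape[0]}x{skip_shape[1]}"
        )
    cnc = (up[0], up[1], up[2] + skip_shape[2])
    depth = DECODER_DEPTHS[stage - 1] if cfg.filter_depths == (8, 16, 32, 48, 64) else tuple(
        reversed(cfg.filter_depths)
    )[stage - 1]
    out = (cnc[0], cnc[1], depth)
    return DecoderStageSpec(stage, depth, tuple(in_shape), up, tuple(skip_shape), cnc, out)


def trace_network(cfg: ArchConfig) -> LayerTrace:
    """Propagate shapes through the full network, one entry per layer.

    The entry order follows the published table: per encoder stage the
    stem, conventional and graft convolution groups (each C+BN+A), the
    element-wise add (kind ``ADD``, not a table row), optional
    squeeze-excitation (kind ``SE``), then max pooling; the bottleneck
    convolution group; per decoder stage upsample, concatenation and a
    convolution group; finally the 1-channel head convolution with
    sigmoid activation.
    """
    tr = LayerTrace()
    shape = (cfg.input_h, cfg.input_w, cfg.input_c)
    tr.append("Input", "input", shape)
    skips: list[tuple[int, int, int]] = []
    ci = 1
    bi = 1
    for stage in range(1, 6):
        spec, pre_pool, post_pool = build_encoder_stage(cfg, stage, shape)
        for _ in range(3):  # stem, conventional branch, graft branch
            tr.append(f"C{ci}", "C", spec.stem_shape)
            tr.append(f"BN{bi}", "BN", spec.stem_shape)
            tr.append(f"A{ci}", "A", spec.stem_shape)
            ci += 1
            bi += 1
        tr.append(f"ADD{stage}", "ADD", pre_pool)
        if cfg.se_enabled:
            tr.append(f"SE{stage}", "SE", pre_pool)
        skips.append(pre_pool)
        tr.append("MP", "MP", post_pool)
        shape = post_pool
    # bottleneck: single conv group, no graft pair
    tr.append(f"C{ci}", "C", (shape[0], shape[1], cfg.filter_depths[-1]))
    tr.append(f"BN{bi}", "BN", (shape[0], shape[1], cfg.filter_depths[-1]))
    tr.append(f"A{ci}", "A", (shape[0], shape[1], cfg.filter_depths[-1]))
    shape = (shape[0], shape[1], cfg.filter_depths[-1])
    ci += 1
    bi += 1
    for stage in range(1, 6):
        dspec = build_decoder_stage(cfg, stage, shape, skips[5 - stage])
        tr.append(f"UPS{stage}", "UPS", dspec.upsampled_shape)
        tr.append(f"CNC{stage}", "CNC", dspec.concat_shape)
        tr.append(f"C{ci}", "C", dspec.out_shape)
        tr.append(f"BN{bi}", "BN", dspec.out_shape)
        tr.append(f"A{ci}", "A", dspec.out_shape)
        ci += 1
        bi += 1
        shape = dspec.out_shape
    head = (shape[0], shape[1], 1)
    tr.append(f"C{ci}", "C", head)
    tr.append(f"A{ci}", "A", head)  # sigmoid
    return tr


def load_table2() -> list[dict]:
    """The published layer table as a list of {name, kind, shape} rows."""
    text = resources.files("graftunet").joinpath("data/table2.json").read_text()
    return json.loads(text)


def verify_against_table2(trace: LayerTrace) -> list[str]:
    """Compare a trace against the embedded published layer table.

    Only tabular layer kinds are compared (the element-wise add and
    squeeze-excitation do not appear as table rows). Returns a list of
    human-readable mismatch strings; an empty list means full
    conformance.
    """
    expected = load_table2()
    got = trace.tabular()
    mismatches: list[str] = []
    n = max(len(expected), len(got))
    for i in range(n):
        if i >= len(got):
            e = expected[i]
            mismatches.append(f"row {i + 1}: missing layer {e['name']} ({e['kind']})")
            continue
        if i >= len(expected):
            g = got[i]
            mismatches.append(f"row {i + 1}: extra layer {g.name} ({g.kind})")
            continue
        e, g = expected[i], got[i]
        if e["kind"] != g.kind:
            mismatches.append(f"row {i + 1}: kind {g.kind} != expected {e['kind']}")
        if tuple(e["shape"]) != g.shape:
            mismatches.append(
                f"row {i + 1} ({g.name}): shape {g.shape} != expected {tuple(e['shape'])}"
            )
    return mismatches


def parameter_count_formula(cfg: ArchConfig) -> int:
    """Independent closed-form parameter count from the symbolic trace.

    Convolution: f*f*c_in*c_out + c_out; batch norm: 2*c (scale and
    shift); squeeze-excitation: two dense layers c->c/r->c with biases.
    """
    k2 = cfg.kernel * cfg.kernel
    total = 0
    c_in = cfg.input_c
    for depth in cfg.filter_depths:
        # stem + two branches, each conv + BN
        total += k2 * c_in * depth + depth + 2 * depth
        total += 2 * (k2 * depth * depth + depth + 2 * depth)
        if cfg.se_enabled:
            cr = max(1, depth // cfg.se_reduction)
            total += depth * cr + cr + cr * depth + depth
        c_in = depth
    d5 = cfg.filter_depths[-1]
    total += k2 * d5 * d5 + d5 + 2 * d5  # bottleneck
    skip_depths = list(reversed(cfg.filter_depths))
    c = d5
    for stage in range(5):
        depth = skip_depths[stage]
        cnc = c + skip_depths[stage]
        total += k2 * cnc * depth + depth + 2 * depth
        c = depth
    total += k2 * c * 1 + 1  # head conv, no BN
    return total
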