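"""Runnable Graft-U-Net built on the NumPy autograd engine.

Layer parameters are He-uniform initialized from a seeded generator.
Feature maps are NHWC float32; the model consumes images scaled to
[0, 1] and produces per-pixel polyp probabilities.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .arch import ArchConfig, LayerTrace, trace_network
from .autograd import Tensor

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "SqueezeExcite",
    "GraftStage",
    "DecoderStage",
    "GraftUNet",
    "build_network",
    "count_parameters",
    "graft_block_forward",
    "squeeze_excite",
]


def _he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2d:
    """3x3 (configurable) stride-1 "Same" convolution with bias."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        fan_in = kernel * kernel * c_in
        self.w = Tensor(_he_uniform(rng, (kernel, kernel, c_in, c_out), fan_in), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)
        self.padding = (kernel - 1) // 2

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.w, self.b, padding=self.padding)

    def parameters(self):
        return [self.w, self.b]


class BatchNorm2d:
    """Per-channel batch normalization with running statistics.

    Training mode normalizes with batch statistics and updates the
    exponential running mean/variance; inference mode applies the frozen
    affine transform.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            out, m, v = ag.batchnorm2d(x, self.gamma, self.beta, self.eps)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * m
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * v
            return out
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = Tensor(self.gamma.data * inv)
        shift = Tensor(self.beta.data - self.gamma.data * self.running_mean * inv)
        return ag.add(ag.mul(x, scale), shift)

    def parameters(self):
        return [self.gamma, self.beta]


class SqueezeExcite:
    """Channel attention: global max-pool squeeze, bottlenecked gate, rescale.

    The squeeze pools each of the ``c`` feature maps to a scalar by a
    max operation; two dense layers reduce the vector to
    ``max(1, c // reduction)`` and expand it back; a sigmoid gives
    per-channel gates in (0, 1) that multiply the input map.
    """

    def __init__(self, c: int, reduction: int, rng: np.random.Generator):
        cr = max(1, c // reduction)
        self.w1 = Tensor(_he_uniform(rng, (c, cr), c), requires_grad=True)
        self.b1 = Tensor(np.zeros(cr, dtype=np.float32), requires_grad=True)
        self.w2 = Tensor(_he_uniform(rng, (cr, c), cr), requires_grad=True)
        self.b2 = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)

    def gates(self, x: Tensor) -> Tensor:
        s = ag.global_maxpool(x)  # (N, C)
        h = ag.relu(ag.add(ag.matmul(s, self.w1), self.b1))
        return ag.sigmoid(ag.add(ag.matmul(h, self.w2), self.b2))

    def __call__(self, x: Tensor) -> Tensor:
        g = self.gates(x)  # (N, C)
        n, c = g.shape
        return ag.mul(x, _reshape(g, (n, 1, 1, c)))

    def parameters(self):
        return [self.w1, self.b1, self.w2, self.b2]


def _reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    out = Tensor(x.data.reshape(shape), x.requires_grad, (x,))

    def bw(g):
        if x.requires_grad:
            if x.grad is None:
                x.grad = g.reshape(x.data.shape).astype(np.float32, copy=True)
            else:
                x.grad += g.reshape(x.data.shape)

    out._backward = bw
    return out


def squeeze_excite(x: Tensor | np.ndarray, se: SqueezeExcite) -> Tensor:
    """Functional squeeze-excitation: apply ``se``'s gates to ``x``."""
    if not isinstance(x, Tensor):
        x = Tensor(x)
    return se(x)


class GraftStage:
    """One encoder DSB: stem conv, two parallel branches, add, pool."""

    def __init__(self, c_in: int, depth: int, cfg: ArchConfig, rng: np.random.Generator):
        self.stem = Conv2d(c_in, depth, cfg.kernel, rng)
        self.stem_bn = BatchNorm2d(depth)
        self.conv_branch = Conv2d(depth, depth, cfg.kernel, rng)
        self.conv_bn = BatchNorm2d(depth)
        self.graft_branch = Conv2d(depth, depth, cfg.kernel, rng)
        self.graft_bn = BatchNorm2d(depth)
        self.se = SqueezeExcite(depth, cfg.se_reduction, rng) if cfg.se_enabled else None
        self.pool_window = cfg.pool_window

    def forward(self, x: Tensor, training: bool) -> tuple[Tensor, Tensor]:
        """Returns (post-pool output, pre-pool H(x) skip map)."""
        s = ag.relu(self.stem_bn(self.stem(x), training))
        lam = ag.relu(self.conv_bn(self.conv_branch(s), training))
        vth = ag.relu(self.graft_bn(self.graft_branch(s), training))
        h = ag.add(lam, vth)
        if self.se is not None:
            h = self.se(h)
        return ag.maxpool2d_s2(h, self.pool_window), h

    def parameters(self):
        ps = (
            self.stem.parameters()
            + self.stem_bn.parameters()
            + self.conv_branch.parameters()
            + self.conv_bn.parameters()
            + self.graft_branch.parameters()
            + self.graft_bn.parameters()
        )
        if self.se is not None:
            ps += self.se.parameters()
        return ps


def graft_block_forward(stage: GraftStage, x: Tensor | np.ndarray, training: bool = False) -> Tensor:
    """The pre-pool graft-block map H(x) = conventional(stem(x)) + graft(stem(x))."""
    if not isinstance(x, Tensor):
        x = Tensor(x)
    s = ag.relu(stage.stem_bn(stage.stem(x), training))
    lam = ag.relu(stage.conv_bn(stage.conv_branch(s), training))
    vth = ag.relu(stage.graft_bn(stage.graft_branch(s), training))
    return ag.add(lam, vth)


class DecoderStage:
    """One decoder USB: upsample x2, concatenate skip, conv+BN+ReLU."""

    def __init__(self, c_in: int, c_skip: int, depth: int, cfg: ArchConfig, rng: np.random.Generator):
        self.conv = Conv2d(c_in + c_skip, depth, cfg.kernel, rng)
        self.bn = BatchNorm2d(depth)

    def forward(self, x: Tensor, skip: Tensor, training: bool) -> Tensor:
        up = ag.upsample2x(x)
        cat = ag.concat(up, skip)
        return ag.relu(self.bn(self.conv(cat), training))

    def parameters(self):
        return self.conv.parameters() + self.bn.parameters()


class GraftUNet:
    """The full encoder-decoder segmentation network."""

    def __init__(self, cfg: ArchConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        depths = cfg.filter_depths
        self.encoder: list[GraftStage] = []
        c = cfg.input_c
        for d in depths:
            self.encoder.append(GraftStage(c, d, cfg, rng))
            c = d
        self.bottleneck = Conv2d(depths[-1], depths[-1], cfg.kernel, rng)
        self.bottleneck_bn = BatchNorm2d(depths[-1])
        self.decoder: list[DecoderStage] = []
        skip_depths = list(reversed(depths))
        c = depths[-1]
        for d in skip_depths:
            self.decoder.append(DecoderStage(c, d, d, cfg, rng))
            c = d
        self.head = Conv2d(depths[0], 1, cfg.kernel, rng)

    def forward_logits(self, x: Tensor | np.ndarray, training: bool = False) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        skips: list[Tensor] = []
        for stage in self.encoder:
            x, h = stage.forward(x, training)
            skips.append(h)
        x = ag.relu(self.bottleneck_bn(self.bottleneck(x), training))
        for i, stage in enumerate(self.decoder):
            x = stage.forward(x, skips[4 - i], training)
        return self.head(x)

    def forward(self, x: Tensor | np.ndarray, training: bool = False) -> Tensor:
        """Sigmoid probability map, shape (N, H, W, 1), values in (0, 1)."""
        return ag.sigmoid(self.forward_logits(x, training))

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for stage in self.encoder:
            ps += stage.parameters()
        ps += self.bottleneck.parameters() + self.bottleneck_bn.parameters()
        for stage in self.decoder:
            ps += stage.parameters()
        ps += self.head.parameters()
        return ps

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All trainable parameters and running statistics, keyed for npz."""
        state: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.parameters()):
            state[f"param_{i:03d}"] = p.data
        bns = self._batchnorms()
        for i, bn in enumerate(bns):
            state[f"bn_{i:02d}_mean"] = bn.running_mean
            state[f"bn_{i:02d}_var"] = bn.running_var
        return state

    def _batchnorms(self) -> list[BatchNorm2d]:
        bns: list[BatchNorm2d] = []
        for stage in self.encoder:
            bns += [stage.stem_bn, stage.conv_bn, stage.graft_bn]
        bns.append(self.bottleneck_bn)
        for stage in self.decoder:
            bns.append(stage.bn)
        return bns

    def save(self, path) -> None:
        np.savez(path, **self.state_arrays())

    def load(self, path) -> None:
        with np.load(path) as npz:
            for i, p in enumerate(self.parameters()):
                p.data = npz[f"param_{i:03d}"].astype(np.float32)
            for i, bn in enumerate(self._batchnorms()):
                bn.running_mean = npz[f"bn_{i:02d}_mean"]
                bn.running_var = npz[f"bn_{i:02d}_var"]


def build_network(cfg: ArchConfig, seed: int = 0) -> tuple[GraftUNet, LayerTrace]:
    """Construct the runnable model and its symbolic layer trace."""
    return GraftUNet(cfg, seed=seed), trace_network(cfg)


def count_parameters(model: GraftUNet) -> int:
    """Number of trainable scalars in the model."""
    return int(sum(p.data.size for p in model.parameters()))
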