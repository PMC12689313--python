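"""Classifier building blocks: ConvNeXt block, AKConv, CBAM, ConvMod.

AKConv (alterable-kernel convolution) samples the input at an arbitrary
number of kernel points — an initial integer layout anchored at the
upper-left corner plus learned per-position offsets — and mixes the
resampled values with a pointwise convolution.  CBAM applies sequential
channel and spatial attention.  ConvMod replaces self-attention with a
large-kernel depthwise-convolution branch that multiplicatively modulates
a linear value branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, bilinear_sample, concatenate, conv2d
from .modules import Conv2d, Linear, LayerNorm, Module

__all__ = [
    "AKConvConfig", "CBAMConfig", "ConvModConfig",
    "akconv_init_coords", "AKConv", "CBAM", "ConvMod",
    "ConvNeXtBlock", "Downsample",
]


@dataclass(frozen=True)
class AKConvConfig:
    num_param: int = 3
    stride: int = 1
    offset_lr_scale: float = 0.1


@dataclass(frozen=True)
class CBAMConfig:
    reduction: int = 16
    spatial_kernel: int = 7


@dataclass(frozen=True)
class ConvModConfig:
    dim: int = 768
    dw_kernel: int = 11
    dw_padding: int = 5


def akconv_init_coords(num_param: int) -> np.ndarray:
    """Initial integer sampling layout for an ``num_param``-point kernel.

    A regular grid of ``base = floor(sqrt(n))`` columns is filled row by
    row; leftover points are appended on the next row.  The first point is
    always the (0, 0) anchor.  Returns an (n, 2) array of (row, col).
    """
    if num_param < 1:
        raise ValueError("num_param must be >= 1")
    base = int(math.floor(math.sqrt(num_param)))
    rows, rem = divmod(num_param, base)
    coords = [(r, c) for r in range(rows) for c in range(base)]
    coords += [(rows, c) for c in range(rem)]
    return np.asarray(coords, dtype=np.float64)


class AKConv(Module):
    """Offset-sampled convolution with an arbitrary kernel-point count.

    A 3x3 convolution predicts 2N per-position offsets (zero-initialized,
    learning-rate scaled by ``offset_lr_scale``); the input is resampled
    bilinearly at initial-coordinate + offset, and the N sampled values per
    position are mixed by a pointwise convolution, then channel-normalized
    and passed through SiLU.
    """

    def __init__(self, cin, cout, cfg: AKConvConfig = AKConvConfig(), rng=None):
        if cfg.stride != 1:
            raise ValueError("only stride 1 is supported (resolution-preserving)")
        rng = rng or np.random.default_rng(0)
        n = cfg.num_param
        self.cfg = cfg
        self.coords = akconv_init_coords(n)           # (n, 2)
        self.offset_conv = Conv2d(cin, 2 * n, 3, padding=1, zero_init=True)
        for p in self.offset_conv.parameters():
            p.lr_scale = cfg.offset_lr_scale
        self.mix = Conv2d(cin * n, cout, 1, bias=False, rng=rng)
        self.norm = LayerNorm(cout, axis=1)

    def forward(self, x):
        B, C, H, W = x.data.shape
        n = self.cfg.num_param
        off = self.offset_conv(x)                              # (B, 2n, H, W)
        off = off.reshape(B, n, 2, H, W).transpose((0, 1, 3, 4, 2))  # B,n,H,W,2
        rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        base = np.stack([rr, cc], axis=-1)[None, None]         # 1,1,H,W,2
        base = base + self.coords[None, :, None, None, :]
        pos = off + base
        sampled = bilinear_sample(x, pos)                      # B,C,n,H,W
        sampled = sampled.reshape(B, C * n, H, W)
        out = self.mix(sampled)
        return self.norm(out).silu()


class CBAM(Module):
    """Channel then spatial attention.

    Channel attention: shared two-layer MLP (reduction ``r``, ReLU between
    the layers as in the original CBAM) applied to global average- and
    max-pooled descriptors, summed, sigmoid.  Spatial attention: 7x7
    convolution over the channel-wise average/max maps, sigmoid.
    """

    def __init__(self, channels, cfg: CBAMConfig = CBAMConfig(), rng=None):
        if channels % cfg.reduction:
            raise ValueError(
                f"channels ({channels}) must be divisible by reduction ({cfg.reduction})")
        rng = rng or np.random.default_rng(0)
        hidden = channels // cfg.reduction
        self.fc0 = Linear(channels, hidden, bias=False, rng=rng)   # W0
        self.fc1 = Linear(hidden, channels, bias=False, rng=rng)   # W1
        k = cfg.spatial_kernel
        self.spatial = Conv2d(2, 1, k, padding=k // 2, bias=False, rng=rng)
        self.cfg = cfg

    def forward(self, f):
        B, C, H, W = f.data.shape
        avg = f.mean(axis=(2, 3))                       # B,C
        mx = f.reshape(B, C, H * W).max(axis=2)         # B,C
        mc = (self.fc1(self.fc0(avg).relu())
              + self.fc1(self.fc0(mx).relu())).sigmoid()
        f1 = f * mc.reshape(B, C, 1, 1)
        s_avg = f1.mean(axis=1, keepdims=True)          # B,1,H,W
        s_max = f1.max(axis=1, keepdims=True)
        ms = self.spatial(concatenate([s_avg, s_max], axis=1)).sigmoid()
        return f1 * ms


class ConvMod(Module):
    """Convolutional modulation block with residual connection.

    out = x + proj( dw11x11(GELU(conv1x1(LN(x)))) * conv1x1(LN(x)) )
    """

    def __init__(self, cfg: ConvModConfig = ConvModConfig(), rng=None):
        rng = rng or np.random.default_rng(0)
        d = cfg.dim
        self.norm = LayerNorm(d, axis=1)
        self.a_pw = Conv2d(d, d, 1, rng=rng)
        self.a_dw = Conv2d(d, d, cfg.dw_kernel, padding=cfg.dw_padding,
                           groups=d, rng=rng)
        self.v = Conv2d(d, d, 1, rng=rng)
        self.proj = Conv2d(d, d, 1, rng=rng)
        self.cfg = cfg

    def forward(self, x):
        if x.data.shape[1] != self.cfg.dim:
            raise ValueError(f"expected dim {self.cfg.dim}, got {x.data.shape[1]}")
        h = self.norm(x)
        a = self.a_dw(self.a_pw(h).gelu())
        return x + self.proj(a * self.v(h))


class ConvNeXtBlock(Module):
    """Standard ConvNeXt block; the 7x7 depthwise conv may be swapped for an
    AKConv (the Stage-2 modification)."""

    def __init__(self, dim, rng=None, spatial_mixer: Module | None = None,
                 layer_scale_init=1e-6):
        rng = rng or np.random.default_rng(0)
        self.mixer = spatial_mixer or Conv2d(dim, dim, 7, padding=3,
                                             groups=dim, rng=rng)
        self.norm = LayerNorm(dim, axis=1)
        self.pw1 = Conv2d(dim, 4 * dim, 1, rng=rng)
        self.pw2 = Conv2d(4 * dim, dim, 1, rng=rng)
        self.gamma = Tensor(np.full(dim, layer_scale_init), requires_grad=True)
        self.dim = dim

    def forward(self, x):
        y = self.mixer(x)
        y = self.norm(y)
        y = self.pw2(self.pw1(y).gelu())
        return x + y * self.gamma.reshape(1, self.dim, 1, 1)


class Downsample(Module):
    def __init__(self, cin, cout, rng=None):
        self.norm = LayerNorm(cin, axis=1)
        self.conv = Conv2d(cin, cout, 2, stride=2, rng=rng)

    def forward(self, x):
        return self.conv(self.norm(x))
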