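"""ConvNeXt backbone assembly and the improved snore classifier.

The baseline layout is the standard ConvNeXt-Tiny: 4x4/stride-4 stem,
stages of depths (3, 3, 9, 3) at widths (96, 192, 384, 768) with
2x2/stride-2 downsampling between stages, global average pooling, LayerNorm
and a linear head.  The improved variant swaps the depthwise convolution of
every Stage-2 block for an AKConv, inserts one CBAM on the Stage-3 output,
and appends one ConvMod block after Stage 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blocks import (AKConv, AKConvConfig, CBAM, CBAMConfig, ConvMod,
                     ConvModConfig, ConvNeXtBlock, Downsample)
from .modules import Conv2d, LayerNorm, Linear, Module

__all__ = ["BackboneSpec", "ModelSpec", "build_model", "count_params",
           "ConvNeXtClassifier"]


@dataclass(frozen=True)
class BackboneSpec:
    depths: tuple = (3, 3, 9, 3)
    dims: tuple = (96, 192, 384, 768)
    in_chans: int = 3
    n_classes: int = 2


@dataclass(frozen=True)
class ModelSpec:
    """Block-level description of the classifier.

    ``akconv_stage`` / ``cbam_after_stage`` are 0-based stage indices
    (defaults 1 and 2 = the architecture's Stage 2 and Stage 3); ``None``
    disables the module.  ``convmod`` appends one modulation block after the
    last stage.
    """

    backbone: BackboneSpec = BackboneSpec()
    akconv: AKConvConfig | None = None
    akconv_stage: int = 1
    cbam: CBAMConfig | None = None
    cbam_after_stage: int = 2
    convmod: ConvModConfig | None = None
    seed: int = 0

    @staticmethod
    def convnext_tiny(n_classes: int = 2) -> "ModelSpec":
        return ModelSpec(backbone=BackboneSpec(n_classes=n_classes))

    @staticmethod
    def improved_tiny(n_classes: int = 2) -> "ModelSpec":
        return ModelSpec(
            backbone=BackboneSpec(n_classes=n_classes),
            akconv=AKConvConfig(num_param=3, stride=1),
            cbam=CBAMConfig(reduction=16, spatial_kernel=7),
            convmod=ConvModConfig(dim=768, dw_kernel=11, dw_padding=5),
        )

    @staticmethod
    def toy(dims=(8, 16, 32, 64), depths=(1, 1, 1, 1), improved=True,
            n_classes: int = 2, seed: int = 0) -> "ModelSpec":
        """Reduced-width/depth variant for CPU-scale experiments."""
        bb = BackboneSpec(depths=depths, dims=dims, n_classes=n_classes)
        if not improved:
            return ModelSpec(backbone=bb, seed=seed)
        return ModelSpec(
            backbone=bb,
            akconv=AKConvConfig(num_param=3),
            cbam=CBAMConfig(reduction=min(8, dims[2]), spatial_kernel=7),
            convmod=ConvModConfig(dim=dims[3], dw_kernel=5, dw_padding=2),
            seed=seed,
        )


class ConvNeXtClassifier(Module):
    def __init__(self, spec: ModelSpec):
        bb = spec.backbone
        rng = np.random.default_rng(spec.seed)
        if spec.cbam is not None and bb.dims[spec.cbam_after_stage] % spec.cbam.reduction:
            raise ValueError("CBAM reduction incompatible with stage width")
        if spec.convmod is not None and spec.convmod.dim != bb.dims[-1]:
            raise ValueError("ConvMod dim must match the last stage width")
        self.spec = spec
        self.stem_conv = Conv2d(bb.in_chans, bb.dims[0], 4, stride=4, rng=rng)
        self.stem_norm = LayerNorm(bb.dims[0], axis=1)
        self.stages, self.downsamples = [], []
        for i, (depth, dim) in enumerate(zip(bb.depths, bb.dims)):
            if i > 0:
                self.downsamples.append(Downsample(bb.dims[i - 1], dim, rng=rng))
            blocks = []
            for _ in range(depth):
                mixer = None
                if spec.akconv is not None and i == spec.akconv_stage:
                    mixer = AKConv(dim, dim, spec.akconv, rng=rng)
                blocks.append(ConvNeXtBlock(dim, rng=rng, spatial_mixer=mixer))
            self.stages.append(blocks)
        self.cbam = CBAM(bb.dims[spec.cbam_after_stage], spec.cbam,
                         rng=rng) if spec.cbam else None
        self.convmod = ConvMod(spec.convmod, rng=rng) if spec.convmod else None
        self.final_norm = LayerNorm(bb.dims[-1], axis=-1)
        self.head = Linear(bb.dims[-1], bb.n_classes, rng=rng)

    def forward(self, x):
        x = self.stem_norm(self.stem_conv(x))
        for i, blocks in enumerate(self.stages):
            if i > 0:
                x = self.downsamples[i - 1](x)
            for blk in blocks:
                x = blk(x)
            if self.cbam is not None and i == self.spec.cbam_after_stage:
                x = self.cbam(x)
        if self.convmod is not None:
            x = self.convmod(x)
        x = x.mean(axis=(2, 3))             # global average pool -> (B, C)
        return self.head(self.final_norm(x))

    def parameters(self):
        params = list(self.stem_conv.parameters()) + list(self.stem_norm.parameters())
        for i, blocks in enumerate(self.stages):
            if i > 0:
                params += self.downsamples[i - 1].parameters()
            for blk in blocks:
                params += blk.parameters()
        if self.cbam is not None:
            params += self.cbam.parameters()
        if self.convmod is not None:
            params += self.convmod.parameters()
        params += self.final_norm.parameters() + self.head.parameters()
        return params


def build_model(spec: ModelSpec) -> ConvNeXtClassifier:
    return ConvNeXtClassifier(spec)


def count_params(model: Module) -> int:
    """Number of trainable scalars."""
    return int(sum(p.size for p in model.parameters()))
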