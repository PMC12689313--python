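"""Per-layer parameter inventories for the reference classifier zoo.

Each builder enumerates every trainable tensor of the standard ImageNet
architecture (with a configurable classification head) as (name, shape)
pairs; :func:`count_inventory` sums them.  Batch-norm running statistics are
buffers, not parameters, and are excluded.  These inventories exist for
architecture accounting (parameter budgets) only — they are not runnable
networks.
"""

from __future__ import annotations

from math import prod

__all__ = [
    "count_inventory", "millions",
    "convnext_tiny_inventory", "resnet50_inventory",
    "swin_tiny_inventory", "mobilenet_v3_large_inventory",
]


def count_inventory(inv) -> int:
    return int(sum(prod(shape) for _, shape in inv))


def millions(n: int) -> float:
    """Parameter count in millions, rounded to 2 decimals (table convention)."""
    return round(n / 1e6, 2)


# ------------------------------------------------------------- ConvNeXt-T
def convnext_tiny_inventory(n_classes: int = 2):
    depths, dims = (3, 3, 9, 3), (96, 192, 384, 768)
    inv = [("stem.conv.weight", (dims[0], 3, 4, 4)), ("stem.conv.bias", (dims[0],)),
           ("stem.norm", (2 * dims[0],))]
    for i, (depth, d) in enumerate(zip(depths, dims)):
        if i > 0:
            inv += [(f"down{i}.norm", (2 * dims[i - 1],)),
                    (f"down{i}.conv.weight", (d, dims[i - 1], 2, 2)),
                    (f"down{i}.conv.bias", (d,))]
        for b in range(depth):
            p = f"stage{i}.block{b}"
            inv += [(f"{p}.dwconv.weight", (d, 1, 7, 7)), (f"{p}.dwconv.bias", (d,)),
                    (f"{p}.norm", (2 * d,)),
                    (f"{p}.pw1.weight", (4 * d, d, 1, 1)), (f"{p}.pw1.bias", (4 * d,)),
                    (f"{p}.pw2.weight", (d, 4 * d, 1, 1)), (f"{p}.pw2.bias", (d,)),
                    (f"{p}.gamma", (d,))]
    inv += [("final_norm", (2 * dims[-1],)),
            ("head.weight", (n_classes, dims[-1])), ("head.bias", (n_classes,))]
    return inv


# --------------------------------------------------------------- ResNet50
def resnet50_inventory(n_classes: int = 2):
    def bn(name, c):
        return [(f"{name}.weight", (c,)), (f"{name}.bias", (c,))]

    inv = [("conv1.weight", (64, 3, 7, 7))] + bn("bn1", 64)
    layers = [(3, 64), (4, 128), (6, 256), (3, 512)]
    inplanes = 64
    for li, (blocks, planes) in enumerate(layers):
        for b in range(blocks):
            p = f"layer{li + 1}.{b}"
            out = planes * 4
            inv += [(f"{p}.conv1.weight", (planes, inplanes, 1, 1))] + bn(f"{p}.bn1", planes)
            inv += [(f"{p}.conv2.weight", (planes, planes, 3, 3))] + bn(f"{p}.bn2", planes)
            inv += [(f"{p}.conv3.weight", (out, planes, 1, 1))] + bn(f"{p}.bn3", out)
            if b == 0:
                inv += [(f"{p}.downsample.weight", (out, inplanes, 1, 1))]
                inv += bn(f"{p}.downsample.bn", out)
            inplanes = out
    inv += [("fc.weight", (n_classes, 2048)), ("fc.bias", (n_classes,))]
    return inv


# ----------------------------------------------------------------- Swin-T
def swin_tiny_inventory(n_classes: int = 2, window: int = 7):
    depths, dims, heads = (2, 2, 6, 2), (96, 192, 384, 768), (3, 6, 12, 24)
    rel = (2 * window - 1) ** 2
    inv = [("patch_embed.proj.weight", (dims[0], 3, 4, 4)),
           ("patch_embed.proj.bias", (dims[0],)),
           ("patch_embed.norm", (2 * dims[0],))]
    for i, (depth, d, h) in enumerate(zip(depths, dims, heads)):
        for b in range(depth):
            p = f"stage{i}.block{b}"
            inv += [(f"{p}.norm1", (2 * d,)),
                    (f"{p}.attn.qkv.weight", (3 * d, d)), (f"{p}.attn.qkv.bias", (3 * d,)),
                    (f"{p}.attn.rel_pos_bias", (rel, h)),
                    (f"{p}.attn.proj.weight", (d, d)), (f"{p}.attn.proj.bias", (d,)),
                    (f"{p}.norm2", (2 * d,)),
                    (f"{p}.mlp.fc1.weight", (4 * d, d)), (f"{p}.mlp.fc1.bias", (4 * d,)),
                    (f"{p}.mlp.fc2.weight", (d, 4 * d)), (f"{p}.mlp.fc2.bias", (d,))]
        if i < 3:
            inv += [(f"merge{i}.reduction.weight", (2 * d, 4 * d)),
                    (f"merge{i}.norm", (2 * 4 * d,))]
    inv += [("final_norm", (2 * dims[-1],)),
            ("head.weight", (n_classes, dims[-1])), ("head.bias", (n_classes,))]
    return inv


# ------------------------------------------------------- MobileNetV3-Large
def _make_divisible(v, divisor=8):
    new_v = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return new_v


# (kernel, expanded, out, use_SE, stride) — activation carries no parameters
_MNV3_LARGE = [
    (3, 16, 16, False, 1), (3, 64, 24, False, 2), (3, 72, 24, False, 1),
    (5, 72, 40, True, 2), (5, 120, 40, True, 1), (5, 120, 40, True, 1),
    (3, 240, 80, False, 2), (3, 200, 80, False, 1), (3, 184, 80, False, 1),
    (3, 184, 80, False, 1), (3, 480, 112, True, 1), (3, 672, 112, True, 1),
    (5, 672, 160, True, 2), (5, 960, 160, True, 1), (5, 960, 160, True, 1),
]


def mobilenet_v3_large_inventory(n_classes: int = 2):
    def bn(name, c):
        return [(f"{name}.weight", (c,)), (f"{name}.bias", (c,))]

    inv = [("stem.conv.weight", (16, 3, 3, 3))] + bn("stem.bn", 16)
    cin = 16
    for i, (k, exp, out, se, _stride) in enumerate(_MNV3_LARGE):
        p = f"block{i}"
        if exp != cin:
            inv += [(f"{p}.expand.weight", (exp, cin, 1, 1))] + bn(f"{p}.expand.bn", exp)
        inv += [(f"{p}.dw.weight", (exp, 1, k, k))] + bn(f"{p}.dw.bn", exp)
        if se:
            sq = _make_divisible(exp // 4)
            inv += [(f"{p}.se.fc1.weight", (sq, exp, 1, 1)), (f"{p}.se.fc1.bias", (sq,)),
                    (f"{p}.se.fc2.weight", (exp, sq, 1, 1)), (f"{p}.se.fc2.bias", (exp,))]
        inv += [(f"{p}.project.weight", (out, exp, 1, 1))] + bn(f"{p}.project.bn", out)
        cin = out
    inv += [("last_conv.weight", (960, 160, 1, 1))] + bn("last_conv.bn", 960)
    inv += [("classifier.fc1.weight", (1280, 960)), ("classifier.fc1.bias", (1280,)),
            ("classifier.fc2.weight", (n_classes, 1280)),
            ("classifier.fc2.bias", (n_classes,))]
    return inv
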