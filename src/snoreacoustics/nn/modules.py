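"""Layer primitives built on the autograd engine."""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, conv2d

__all__ = ["Module", "Conv2d", "Linear", "LayerNorm", "Sequential", "Identity", "AdamW"]


class Module:
    """Base class; children discovered by attribute traversal."""

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def num_params(self) -> int:
        return int(sum(p.size for p in self.parameters()))


class Conv2d(Module):
    def __init__(self, cin, cout, kernel, stride=1, padding=0, groups=1,
                 bias=True, rng=None, zero_init=False):
        k = (kernel, kernel) if isinstance(kernel, int) else kernel
        fan_in = cin // groups * k[0] * k[1]
        if zero_init:
            w = np.zeros((cout, cin // groups, *k))
        else:
            rng = rng or np.random.default_rng(0)
            w = rng.normal(0.0, math.sqrt(2.0 / fan_in), (cout, cin // groups, *k))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class Linear(Module):
    def __init__(self, cin, cout, bias=True, rng=None):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, math.sqrt(2.0 / cin), (cout, cin))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def forward(self, x):
        y = x.matmul(self.weight.transpose((1, 0)))
        return y + self.bias if self.bias is not None else y


class LayerNorm(Module):
    """Normalizes over one axis with learnable per-element gain/shift.

    ``axis=1`` on NCHW input is the channels-first LayerNorm used throughout
    ConvNeXt-style blocks; ``axis=-1`` covers flat vectors.
    """

    def __init__(self, dim, axis=1, eps=1e-6):
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.shift = Tensor(np.zeros(dim), requires_grad=True)
        self.axis, self.eps, self.dim = axis, eps, dim

    def forward(self, x):
        ax = self.axis if self.axis >= 0 else x.data.ndim + self.axis
        mu = x.mean(axis=ax, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=ax, keepdims=True)
        xhat = xc * ((var + self.eps) ** -0.5)
        shape = [1] * x.data.ndim
        shape[ax] = self.dim
        return xhat * self.gain.reshape(shape) + self.shift.reshape(shape)


class Sequential(Module):
    def __init__(self, *mods):
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class AdamW:
    """Decoupled weight decay Adam; honors per-parameter ``lr_scale``."""

    def __init__(self, params, lr=2e-4, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.05):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            lr = self.lr * p.lr_scale
            p.data -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
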