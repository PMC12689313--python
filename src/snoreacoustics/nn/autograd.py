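"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operator set needed by the classifier blocks in this
package: broadcast arithmetic, matmul, reshape/transpose, reductions,
sigmoid / SiLU / GELU / ReLU, grouped 2-D convolution, bilinear grid
sampling (for offset-based kernels), concatenation and a fused
softmax-cross-entropy loss.  Arrays are float64 throughout; gradients are
accumulated into ``Tensor.grad`` by :func:`backward` via topological sort.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "conv2d",
    "bilinear_sample",
    "cross_entropy",
]


class Tensor:
    """An array node in the autograd graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "lr_scale")

    def __init__(self, data, requires_grad=False, _prev=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = _backward
        self._prev = tuple(_prev)
        self.lr_scale = 1.0  # per-parameter learning-rate multiplier

    # ------------------------------------------------------------------ info
    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------- structure
    def _needs_graph(self, *others):
        return self.requires_grad or any(o.requires_grad for o in others)

    def zero_grad(self):
        self.grad = None

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, self._needs_graph(other), (self, other))

        def _bw(g):
            _accum(self, _unbroadcast(g, self.data.shape))
            _accum(other, _unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: _accum(self, -g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, self._needs_graph(other), (self, other))

        def _bw(g):
            _accum(self, _unbroadcast(g * other.data, self.data.shape))
            _accum(other, _unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, self._needs_graph(other), (self, other))

        def _bw(g):
            _accum(self, _unbroadcast(g / other.data, self.data.shape))
            _accum(other, _unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._backward = _bw
        return out

    def __pow__(self, p):
        assert np.isscalar(p)
        out = Tensor(self.data**p, self.requires_grad, (self,))
        out._backward = lambda g: _accum(self, g * p * self.data ** (p - 1))
        return out

    def matmul(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, self._needs_graph(other), (self, other))

        def _bw(g):
            _accum(self, g @ other.data.swapaxes(-1, -2))
            _accum(other, self.data.swapaxes(-1, -2) @ g)

        out._backward = _bw
        return out

    __matmul__ = matmul

    # ------------------------------------------------------------ reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        out._backward = lambda g: _accum(self, g.reshape(src))
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        out._backward = lambda g: _accum(self, g.transpose(inv))
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def _bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            _accum(self, np.broadcast_to(g, self.data.shape))

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis, keepdims=False):
        val = self.data.max(axis=axis, keepdims=True)
        out = Tensor(val if keepdims else np.squeeze(val, axis=axis),
                     self.requires_grad, (self,))
        # ties share the gradient equally (deterministic, symmetric)
        mask = (self.data == val).astype(np.float64)
        mask /= mask.sum(axis=axis, keepdims=True)

        def _bw(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            _accum(self, mask * g)

        out._backward = _bw
        return out

    # ------------------------------------------------------------ nonlinear
    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, self.requires_grad, (self,))
        out._backward = lambda g: _accum(self, g * s * (1.0 - s))
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * s, self.requires_grad, (self,))
        out._backward = lambda g: _accum(self, g * (s + self.data * s * (1.0 - s)))
        return out

    def gelu(self):
        """Exact (erf) GELU."""
        from scipy.special import erf

        x = self.data
        cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        out = Tensor(x * cdf, self.requires_grad, (self,))
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
        out._backward = lambda g: _accum(self, g * (cdf + x * pdf))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))
        out._backward = lambda g: _accum(self, g * (self.data > 0))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, self.requires_grad, (self,))
        out._backward = lambda g: _accum(self, g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: _accum(self, g / self.data)
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = Tensor(r, self.requires_grad, (self,))
        out._backward = lambda g: _accum(self, g * 0.5 / r)
        return out

    # ------------------------------------------------------------- backward
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray):
    if not (t.requires_grad or t._prev):
        return
    if t.grad is None:
        t.grad = np.array(g, dtype=np.float64)
    else:
        t.grad = t.grad + g


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g.reshape(shape)


def concatenate(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    out._backward = _bw
    return out


# --------------------------------------------------------------------- conv
def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """Grouped 2-D cross-correlation, NCHW layout.

    ``w`` has shape (C_out, C_in/groups, kh, kw).
    """
    x, w = as_tensor(x), as_tensor(w)
    B, C, H, W = x.data.shape
    O, Cg, kh, kw = w.data.shape
    if C % groups or O % groups or Cg != C // groups:
        raise ValueError("channel/group mismatch")
    s, p = stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Hp, Wp = xp.shape[2:]
    Ho, Wo = (Hp - kh) // s + 1, (Wp - kw) // s + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]  # B,C,Ho,Wo,kh,kw

    og = O // groups
    outs = np.empty((B, O, Ho, Wo))
    for g in range(groups):
        cs, os_ = slice(g * Cg, (g + 1) * Cg), slice(g * og, (g + 1) * og)
        outs[:, os_] = np.einsum("bcxykl,ockl->boxy", win[:, cs], w.data[os_],
                                 optimize=True)
    if b is not None:
        outs += b.data.reshape(1, O, 1, 1)

    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(outs, any(t.requires_grad for t in prev), prev)

    def _bw(go):
        if b is not None:
            _accum(b, go.sum(axis=(0, 2, 3)))
        gw = np.empty_like(w.data)
        gxp = np.zeros((B, C, Hp, Wp))
        for g in range(groups):
            cs, os_ = slice(g * Cg, (g + 1) * Cg), slice(g * og, (g + 1) * og)
            gw[os_] = np.einsum("boxy,bcxykl->ockl", go[:, os_], win[:, cs],
                                optimize=True)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, cs, i:i + s * Ho:s, j:j + s * Wo:s] += np.einsum(
                        "boxy,oc->bcxy", go[:, os_], w.data[os_, :, i, j],
                        optimize=True)
        _accum(w, gw)
        _accum(x, gxp[:, :, p:Hp - p, p:Wp - p] if p else gxp)

    out._backward = _bw
    return out


# --------------------------------------------------------------- grid sample
def bilinear_sample(x: Tensor, pos: Tensor) -> Tensor:
    """Sample ``x`` (B,C,H,W) at fractional pixel positions.

    ``pos`` has shape (B, N, Ho, Wo, 2) holding (row, col) coordinates.
    Out-of-bounds samples read as zero.  Returns (B, C, N, Ho, Wo) and is
    differentiable in both the image and the positions.
    """
    x, pos = as_tensor(x), as_tensor(pos)
    B, C, H, W = x.data.shape
    r, c = pos.data[..., 0], pos.data[..., 1]          # (B,N,Ho,Wo)
    r0, c0 = np.floor(r).astype(int), np.floor(c).astype(int)
    dr, dc = r - r0, c - c0

    def gather(ri, ci):
        valid = (ri >= 0) & (ri < H) & (ci >= 0) & (ci < W)
        ric = np.clip(ri, 0, H - 1)
        cic = np.clip(ci, 0, W - 1)
        bidx = np.arange(B)[:, None, None, None]
        vals = x.data[bidx, :, ric, cic]               # (B,N,Ho,Wo,C)
        vals = np.moveaxis(vals, -1, 1)                # (B,C,N,Ho,Wo)
        return vals * valid[:, None], valid

    v00, m00 = gather(r0, c0)
    v01, m01 = gather(r0, c0 + 1)
    v10, m10 = gather(r0 + 1, c0)
    v11, m11 = gather(r0 + 1, c0 + 1)
    wr, wc = dr[:, None], dc[:, None]                  # (B,1,N,Ho,Wo)
    out_data = ((1 - wr) * (1 - wc) * v00 + (1 - wr) * wc * v01
                + wr * (1 - wc) * v10 + wr * wc * v11)
    out = Tensor(out_data, x.requires_grad or pos.requires_grad, (x, pos))

    def _bw(go):
        if x.requires_grad or x._prev:
            gx = np.zeros_like(x.data)
            flat = gx.reshape(B, C, -1)
            bidx = np.arange(B)[:, None, None, None]
            for (ri, ci, m, wgt) in (
                (r0, c0, m00, (1 - wr) * (1 - wc)),
                (r0, c0 + 1, m01, (1 - wr) * wc),
                (r0 + 1, c0, m10, wr * (1 - wc)),
                (r0 + 1, c0 + 1, m11, wr * wc),
            ):
                lin = (np.clip(ri, 0, H - 1) * W + np.clip(ci, 0, W - 1))
                contrib = go * wgt * m[:, None]
                # scatter-add per batch/channel
                for bb in range(B):
                    for ch in range(C):
                        np.add.at(flat[bb, ch], lin[bb].ravel(),
                                  contrib[bb, ch].ravel())
            _accum(x, gx)
        if pos.requires_grad or pos._prev:
            d_dr = ((1 - wc) * (v10 - v00) + wc * (v11 - v01))
            d_dc = ((1 - wr) * (v01 - v00) + wr * (v11 - v10))
            gr = (go * d_dr).sum(axis=1)
            gc = (go * d_dc).sum(axis=1)
            _accum(pos, np.stack([gr, gc], axis=-1))

    out._backward = _bw
    return out


# --------------------------------------------------------------------- loss
def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``labels`` is an int array of class ids."""
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    ll = -np.log(np.clip(probs[np.arange(n), labels], 1e-300, None))
    out = Tensor(ll.mean(), logits.requires_grad or bool(logits._prev), (logits,))

    def _bw(g):
        gz = probs.copy()
        gz[np.arange(n), labels] -= 1.0
        _accum(logits, g * gz / n)

    out._backward = _bw
    return out
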