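"""Minimal reverse-mode autodiff on numpy arrays.

This is the numerical substrate for the detector: a `Tensor` wraps a numpy
array, records the operations applied to it, and `backward()` propagates
gradients through the recorded graph.  Only the operations the detector
actually needs are implemented (dense/conv linear algebra, the usual
activations, reductions, bilinear resizing, normalization, softmax).

Conventions
-----------
* dtype is float32 throughout; shapes follow (N, C, H, W) for feature maps.
* Broadcasting follows numpy; gradients are summed back to the operand shape.
* Gradient accumulation: repeated uses of a tensor add their contributions.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float32, copy=False)
    return np.asarray(x, dtype=np.float32)


def _sum_to(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- helpers ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- autograd driver -------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = _as_array(grad)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, g: np.ndarray):
        if not self.requires_grad:
            return
        g = _sum_to(g, self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accum(g)
            other._accum(g)

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self.pow(-1.0)

    def pow(self, p: float):
        out_data = self.data**p

        def bwd(g):
            self._accum(g * p * self.data ** (p - 1.0))

        return self._make(out_data, (self,), bwd)

    def sqrt(self):
        return self.pow(0.5)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bwd)

    def clip_min(self, lo: float):
        """max(x, lo); gradient passes where x > lo."""
        mask = self.data > lo

        def bwd(g):
            self._accum(g * mask)

        return self._make(np.maximum(self.data, lo), (self,), bwd)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g
                if not keepdims:
                    gg = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))

        return self._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        expanded = self.data.max(axis=axis, keepdims=True)
        mask = self.data == expanded
        # split gradient evenly across ties so the op stays well-defined
        counts = mask.sum(axis=axis, keepdims=True)
        w = mask / counts

        def bwd(g):
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accum(w * gg)

        return self._make(out_data, (self,), bwd)

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bwd(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), bwd)

    def __getitem__(self, idx):
        def bwd(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, idx, g)
            self._accum(gx)

        return self._make(self.data[idx], (self,), bwd)

    # -- linear algebra --------------------------------------------------
    def matmul(self, other):
        other = self._lift(other)
        a, b = self.data, other.data

        def bwd(g):
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            self._accum(ga)
            other._accum(gb)

        return self._make(np.matmul(a, b), (self, other), bwd)

    __matmul__ = matmul

    # -- specialized ops -------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """2-D convolution, input (N,C,H,W), weight (O,C,kh,kw)."""
        x, w = self.data, weight.data
        n, c, h, wd = x.shape
        o, _, kh, kw = w.shape
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        oh = (h + 2 * padding - kh) // stride + 1
        ow = (wd + 2 * padding - kw) // stride + 1
        s0, s1, s2, s3 = xp.strides
        patches = np.lib.stride_tricks.as_strided(
            xp, (n, c, kh, kw, oh, ow),
            (s0, s1, s2, s3, s2 * stride, s3 * stride), writeable=False,
        )
        cols = patches.reshape(n, c * kh * kw, oh * ow)
        wmat = w.reshape(o, c * kh * kw)
        out = np.matmul(wmat, cols).reshape(n, o, oh, ow)
        if bias is not None:
            out = out + bias.data.reshape(1, o, 1, 1)
        parents = (self, weight) if bias is None else (self, weight, bias)

        def bwd(g):
            gmat = g.reshape(n, o, oh * ow)
            weight._accum(
                np.einsum("nop,ncp->oc", gmat, cols, optimize=True).reshape(w.shape)
            )
            if bias is not None:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                gcols = np.matmul(wmat.T, gmat)  # (n, c*kh*kw, oh*ow)
                gcols = gcols.reshape(n, c, kh, kw, oh, ow)
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i:i + stride * oh:stride,
                            j:j + stride * ow:stride] += gcols[:, :, i, j]
                if padding:
                    gxp = gxp[:, :, padding:-padding, padding:-padding]
                self._accum(gxp)

        return self._make(out, parents, bwd)

    def maxpool2d(self, kernel: int, stride: int, padding: int = 0):
        """Max pooling over (N,C,H,W); padded cells are -inf."""
        x = self.data
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
        oh = (h + 2 * padding - kernel) // stride + 1
        ow = (w + 2 * padding - kernel) // stride + 1
        s0, s1, s2, s3 = xp.strides
        patches = np.lib.stride_tricks.as_strided(
            xp, (n, c, kernel, kernel, oh, ow),
            (s0, s1, s2, s3, s2 * stride, s3 * stride), writeable=False,
        )
        flat = patches.reshape(n, c, kernel * kernel, oh, ow)
        arg = flat.argmax(axis=2)
        out = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]

        def bwd(g):
            if not self.requires_grad:
                return
            gxp = np.zeros_like(xp)
            ki, kj = np.divmod(arg, kernel)
            ni, ci, oi, oj = np.indices(arg.shape, sparse=False)
            np.add.at(gxp, (ni, ci, oi * stride + ki, oj * stride + kj), g)
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            self._accum(gxp)

        return self._make(out, (self,), bwd)

    def subsample2(self):
        """Stride-2 spatial subsampling (kernel-1 pooling)."""
        def bwd(g):
            gx = np.zeros_like(self.data)
            gx[:, :, ::2, ::2] = g
            self._accum(gx)

        return self._make(self.data[:, :, ::2, ::2].copy(), (self,), bwd)

    def minimum(self, other: "Tensor") -> "Tensor":
        """Elementwise min via min(a,b) = a - relu(a-b)."""
        return self - (self - other).relu()

    def bilinear_resize(self, out_h: int, out_w: int):
        """Bilinear interpolation of (N,C,H,W) maps (half-pixel centers)."""
        n, c, h, w = self.data.shape
        ah = _interp_matrix(h, out_h)
        aw = _interp_matrix(w, out_w)
        out = np.einsum("ij,ncjk,lk->ncil", ah, self.data, aw, optimize=True)

        def bwd(g):
            self._accum(np.einsum("ij,ncil,lk->ncjk", ah, g, aw, optimize=True))

        return self._make(out, (self,), bwd)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            self._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))

        return self._make(s, (self,), bwd)

    def layer_norm(self, weight: "Tensor", bias: "Tensor", eps: float = 1e-5):
        """Normalize over the last axis, then affine."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out = xhat * weight.data + bias.data
        d = self.data.shape[-1]

        def bwd(g):
            weight._accum((g * xhat).sum(axis=tuple(range(g.ndim - 1))))
            bias._accum(g.sum(axis=tuple(range(g.ndim - 1))))
            if self.requires_grad:
                gh = g * weight.data
                self._accum(inv * (gh - gh.mean(axis=-1, keepdims=True)
                                   - xhat * (gh * xhat).mean(axis=-1, keepdims=True)))
            _ = d

        return self._make(out, (self, weight, bias), bwd)

    def group_norm(self, num_groups: int, weight: "Tensor", bias: "Tensor",
                   eps: float = 1e-5):
        """GroupNorm over (N,C,H,W)."""
        n, c, h, w = self.data.shape
        gshape = (n, num_groups, c // num_groups * h * w)
        xg = self.data.reshape(gshape)
        mu = xg.mean(axis=-1, keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (xc * inv).reshape(n, c, h, w)
        out = xhat * weight.data.reshape(1, c, 1, 1) + bias.data.reshape(1, c, 1, 1)

        def bwd(g):
            weight._accum((g * xhat).sum(axis=(0, 2, 3)))
            bias._accum(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                gh = (g * weight.data.reshape(1, c, 1, 1)).reshape(gshape)
                xh = xhat.reshape(gshape)
                gx = inv * (gh - gh.mean(axis=-1, keepdims=True)
                            - xh * (gh * xh).mean(axis=-1, keepdims=True))
                self._accum(gx.reshape(n, c, h, w))

        return self._make(out, (self, weight, bias), bwd)


def _interp_cache():
    cache: dict[tuple[int, int], np.ndarray] = {}

    def get(src: int, dst: int) -> np.ndarray:
        key = (src, dst)
        if key not in cache:
            a = np.zeros((dst, src), dtype=np.float32)
            if src == 1:
                a[:, 0] = 1.0
            else:
                pos = (np.arange(dst, dtype=np.float64) + 0.5) * (src / dst) - 0.5
                pos = np.clip(pos, 0, src - 1)
                lo = np.floor(pos).astype(int)
                hi = np.minimum(lo + 1, src - 1)
                t = (pos - lo).astype(np.float32)
                a[np.arange(dst), lo] += 1.0 - t
                a[np.arange(dst), hi] += t
            cache[key] = a
        return cache[key]

    return get


_interp_matrix = _interp_cache()


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        sizes = [d.shape[axis] for d in datas]
        offsets = np.cumsum([0] + sizes)

        def bwd(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])

        out._backward = bwd
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        shape = list(t.data.shape)
        shape.insert(axis if axis >= 0 else t.data.ndim + 1 + axis, 1)
        expanded.append(t.reshape(tuple(shape)))
    return concat(expanded, axis=axis)
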