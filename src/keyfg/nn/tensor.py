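"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied
to it; :meth:`Tensor.backward` accumulates gradients through the recorded
graph in reverse topological order.  Broadcasting is supported by
summing gradients back over broadcast axes.  The op set is exactly what
the detector needs: elementwise arithmetic, matmul (2-D and batched),
exp/log/sqrt, sigmoid/relu/maximum/minimum, reductions, reshape /
transpose / slicing / gather, concatenation, padding and a bilinear
image-sampling primitive (differentiable in both the feature map and the
sampling coordinates, as deformable attention requires).
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "stack", "sigmoid", "softmax",
           "relu", "log", "exp", "sqrt", "maximum", "minimum", "clip",
           "bilinear_sample", "pad2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _prev: tuple = (),
        _backward: Callable[[np.ndarray], None] | None = None,
        name: str = "",
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._prev = _prev if self.requires_grad else ()
        self._backward = _backward
        self.name = name

    # ------------------------------------------------------------------
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
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient on non-scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = bw
        return out

    # ------------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g.reshape(self.data.shape)
        )
        return out

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g.transpose(inv)
        )
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ----------------------------------------------------------------------
# functional ops


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.exp(x.data), _prev=(x,))
    out._backward = lambda g: x.requires_grad and x._accumulate(g * out.data)
    return out


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.log(x.data), _prev=(x,))
    out._backward = lambda g: x.requires_grad and x._accumulate(g / x.data)
    return out


def sqrt(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.sqrt(x.data), _prev=(x,))
    out._backward = lambda g: x.requires_grad and x._accumulate(
        g * 0.5 / np.sqrt(x.data)
    )
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, _prev=(x,))
    out._backward = lambda g: x.requires_grad and x._accumulate(g * s * (1 - s))
    return out


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    out = Tensor(x.data * mask, _prev=(x,))
    out._backward = lambda g: x.requires_grad and x._accumulate(g * mask)
    return out


def maximum(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    mask = a.data >= b.data
    out = Tensor(np.where(mask, a.data, b.data), _prev=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * mask, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * (~mask), b.data.shape))

    out._backward = bw
    return out


def minimum(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    mask = a.data <= b.data
    out = Tensor(np.where(mask, a.data, b.data), _prev=(a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * mask, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * (~mask), b.data.shape))

    out._backward = bw
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only inside the interval."""
    x = as_tensor(x)
    mask = (x.data >= lo) & (x.data <= hi)
    out = Tensor(np.clip(x.data, lo, hi), _prev=(x,))
    out._backward = lambda g: x.requires_grad and x._accumulate(g * mask)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, _prev=(x,))

    def bw(g):
        if not x.requires_grad:
            return
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accumulate(s * (g - dot))

    out._backward = bw
    return out


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    out._backward = bw
    return out


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))

    def bw(g):
        parts = np.split(g, len(tensors), axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p.reshape(t.data.shape))

    out._backward = bw
    return out


def pad2d(x: Tensor, pad: int, mode: str = "edge") -> Tensor:
    """Pad the two leading spatial axes of an (H, W, C) tensor.

    Edge padding preserves constant inputs (zero padding would not),
    which matters for the stand-in backbone's constant-response check.
    """
    x = as_tensor(x)
    widths = ((pad, pad), (pad, pad)) + ((0, 0),) * (x.ndim - 2)
    out = Tensor(np.pad(x.data, widths, mode=mode), _prev=(x,))

    def bw(g):
        if not x.requires_grad:
            return
        if mode == "constant" or mode == "edge":
            core = g[pad:-pad or None, pad:-pad or None]
            if mode == "edge":
                core = core.copy()
                # gradient of replicated borders folds back onto edge cells
                core[0] += g[:pad, pad:-pad or None].sum(axis=0)
                core[-1] += g[g.shape[0] - pad:, pad:-pad or None].sum(axis=0)
                core[:, 0] += g[pad:-pad or None, :pad].sum(axis=1)
                core[:, -1] += g[pad:-pad or None, g.shape[1] - pad:].sum(axis=1)
                core[0, 0] += g[:pad, :pad].sum(axis=(0, 1))
                core[0, -1] += g[:pad, g.shape[1] - pad:].sum(axis=(0, 1))
                core[-1, 0] += g[g.shape[0] - pad:, :pad].sum(axis=(0, 1))
                core[-1, -1] += g[g.shape[0] - pad:, g.shape[1] - pad:].sum(axis=(0, 1))
            x._accumulate(core)
        else:  # pragma: no cover
            raise NotImplementedError(mode)

    out._backward = bw
    return out


def bilinear_sample(feat: Tensor, coords: Tensor) -> Tensor:
    """Bilinearly sample a (H, W, C) feature map at (N, 2) pixel
    coordinates given as (x, y); samples outside the map contribute zero.

    Differentiable with respect to both the feature map and the
    coordinates.  Coordinates are in *pixel* units where (0, 0) is the
    centre of the top-left cell.
    """
    feat = as_tensor(feat)
    coords = as_tensor(coords)
    H, W, C = feat.data.shape
    xy = coords.data
    x, y = xy[:, 0], xy[:, 1]
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    fx = x - x0
    fy = y - y0

    corners = []
    for dy in (0, 1):
        for dx in (0, 1):
            xi = x0 + dx
            yi = y0 + dy
            valid = (xi >= 0) & (xi < W) & (yi >= 0) & (yi < H)
            wgt = (fx if dx else 1 - fx) * (fy if dy else 1 - fy)
            xi_c = np.clip(xi, 0, W - 1)
            yi_c = np.clip(yi, 0, H - 1)
            vals = feat.data[yi_c, xi_c] * valid[:, None]
            corners.append((xi_c, yi_c, valid, wgt, vals, dx, dy))

    out_data = sum(w[:, None] * v for (_, _, _, w, v, _, _) in corners)
    out = Tensor(out_data, _prev=(feat, coords))

    def bw(g):
        if feat.requires_grad:
            gf = np.zeros_like(feat.data)
            for xi, yi, valid, wgt, _, _, _ in corners:
                contrib = g * (wgt * valid)[:, None]
                np.add.at(gf, (yi, xi), contrib)
            feat._accumulate(gf)
        if coords.requires_grad:
            gx = np.zeros_like(x)
            gy = np.zeros_like(y)
            for xi, yi, valid, _, vals, dx, dy in corners:
                gv = (g * vals).sum(axis=1)
                # vals already include validity; weight derivatives:
                dwdx = (1.0 if dx else -1.0) * (fy if dy else 1 - fy)
                dwdy = (fx if dx else 1 - fx) * (1.0 if dy else -1.0)
                gdot = (g * feat.data[yi, xi]).sum(axis=1) * valid
                gx += gdot * dwdx
                gy += gdot * dwdy
                del gv
            gc = np.stack([gx, gy], axis=1)
            coords._accumulate(gc)

    out._backward = bw
    return out
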