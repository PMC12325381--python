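"""Neural-network building blocks: modules, initialisation, optimiser."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, pad2d, relu

__all__ = ["Module", "Linear", "MLP", "LayerNorm", "Conv2d", "Adam"]


class Module:
    """Base class: tracks parameters of itself and child modules."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for v in self.__dict__.values():
            items = v if isinstance(v, (list, tuple)) else [v]
            for item in items:
                if isinstance(item, Tensor) and item.requires_grad:
                    if id(item) not in seen:
                        seen.add(id(item))
                        params.append(item)
                elif isinstance(item, Module):
                    for p in item.parameters():
                        if id(p) not in seen:
                            seen.add(id(p))
                            params.append(p)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state size mismatch")
        for p, s in zip(params, state):
            if p.data.shape != s.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {s.shape}")
            p.data = s.copy()


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, zero_init: bool = False):
        w = np.zeros((d_in, d_out)) if zero_init else _xavier(rng, d_in, d_out, (d_in, d_out))
        self.weight = Tensor(w, requires_grad=True, name="weight")
        self.bias = Tensor(np.zeros(d_out), requires_grad=True, name="bias") if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class MLP(Module):
    """ReLU MLP with arbitrary hidden widths."""

    def __init__(self, dims: list[int], rng: np.random.Generator, bias: bool = True):
        self.layers = [Linear(a, b, rng, bias=bias) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = relu(x)
        return x


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True, name="gamma")
        self.beta = Tensor(np.zeros(d), requires_grad=True, name="beta")
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc * ((var + self.eps) ** -0.5)
        return xn * self.gamma + self.beta


class Conv2d(Module):
    """2-D convolution on (H, W, C) maps via im2col.

    Uses "same" arithmetic with edge padding (output H = ceil(H/stride)),
    matching the ResNet stride chain; edge padding keeps constant inputs
    constant, a property the heatmap check relies on.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator, bias: bool = True):
        fan_in = kernel * kernel * c_in
        self.weight = Tensor(
            _xavier(rng, fan_in, c_out, (fan_in, c_out)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None
        self.kernel = kernel
        self.stride = stride
        self.c_in = c_in
        self.c_out = c_out

    def __call__(self, x: Tensor) -> Tensor:
        H, W, C = x.shape
        k, s = self.kernel, self.stride
        pad = k // 2
        xp = pad2d(x, pad, mode="edge")
        Ho = -(-H // s)
        Wo = -(-W // s)
        oy = np.arange(Ho) * s
        ox = np.arange(Wo) * s
        ky, kx = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
        rows = oy[:, None, None, None] + ky[None, None]
        cols = ox[None, :, None, None] + kx[None, None]
        rows = np.broadcast_to(rows, (Ho, Wo, k, k))
        cols = np.broadcast_to(cols, (Ho, Wo, k, k))
        patches = xp[rows, cols]                       # (Ho, Wo, k, k, C)
        flat = patches.reshape(Ho * Wo, k * k * C)
        out = flat @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out.reshape(Ho, Wo, self.c_out)


class Adam:
    """Adam optimiser with decoupled weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
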