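"""Multi-scale deformable attention.

For a query at normalised reference point ``p_hat`` in [0,1]^2, each of
``M`` heads samples ``K`` offset points on each of ``L`` pyramid levels
by bilinear interpolation, combines the sampled (value-projected)
features with non-negative attention weights that sum to one over the
L*K slots of a head, and projects the per-head results back to the model
width.  Sampling locations are ``p_hat * (W_l, H_l) - 0.5 + offset``
in level-pixel units; samples falling outside a map contribute zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..nn import Linear, Module, Tensor, bilinear_sample, concat, softmax

__all__ = ["DeformAttnParams", "ms_deform_attn", "MSDeformAttention"]


@dataclass
class DeformAttnParams:
    """Explicit parameters of one query's deformable-attention evaluation.

    ``offsets`` (M, L, K, 2) in level-pixel units (x, y); ``weights``
    (M, L, K) non-negative, summing to 1 per head; ``value_proj`` a list
    of M matrices (C, C//M) and ``out_proj`` a list of M matrices
    (C//M, C).
    """

    offsets: np.ndarray
    weights: np.ndarray
    value_proj: list
    out_proj: list

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("attention weights must be non-negative")
        per_head = w.reshape(w.shape[0], -1).sum(axis=1)
        if not np.allclose(per_head, 1.0, atol=1e-6):
            raise ValueError(f"attention weights must sum to 1 per head, got {per_head}")


def ms_deform_attn(
    ref_point: np.ndarray,
    pyramid: list[np.ndarray],
    params: DeformAttnParams,
) -> np.ndarray:
    """Evaluate multi-scale deformable attention for a single query.

    ``ref_point`` is the normalised (x, y) in [0,1]^2; ``pyramid`` a list
    of L feature maps (H_l, W_l, C).  Returns the (C,) output vector.
    """
    ref = np.asarray(ref_point, dtype=float)
    if ref.shape != (2,) or ref.min() < 0 or ref.max() > 1:
        raise ValueError("reference point must be (x, y) in [0,1]^2")
    M, L, K, _ = params.offsets.shape
    if L != len(pyramid):
        raise ValueError("offset level count does not match pyramid")
    C = pyramid[0].shape[2]
    out = np.zeros(C)
    for m in range(M):
        Wv = np.asarray(params.value_proj[m], dtype=float)   # (C, C//M)
        Wo = np.asarray(params.out_proj[m], dtype=float)     # (C//M, C)
        if Wv.shape[0] != C or Wo.shape[1] != C:
            raise ValueError("projection shapes do not match feature channels")
        head = np.zeros(Wv.shape[1])
        for l, level in enumerate(pyramid):
            H, W = level.shape[:2]
            for k in range(K):
                loc = ref * np.array([W, H]) - 0.5 + params.offsets[m, l, k]
                sampled = _bilinear_np(level, loc[0], loc[1])
                head = head + params.weights[m, l, k] * (sampled @ Wv)
        out = out + head @ Wo
    return out


def _bilinear_np(level: np.ndarray, x: float, y: float) -> np.ndarray:
    """Vectorised bilinear sample with zero outside the map."""
    H, W, C = level.shape
    x0, y0 = int(np.floor(x)), int(np.floor(y))
    fx, fy = x - x0, y - y0
    acc = np.zeros(C)
    for dy, wy in ((0, 1 - fy), (1, fy)):
        for dx, wx in ((0, 1 - fx), (1, fx)):
            xi, yi = x0 + dx, y0 + dy
            if 0 <= xi < W and 0 <= yi < H:
                acc += wx * wy * level[yi, xi]
    return acc


class MSDeformAttention(Module):
    """Batched deformable-attention layer.

    Offsets and attention weights are linear functions of the query
    feature; weights are normalised by a softmax over the L*K slots of
    each head (offset/weight maps start at zero so initial sampling is an
    average around the reference point).
    """

    def __init__(self, d_model: int, n_heads: int, n_levels: int, n_points: int,
                 rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model = d_model
        self.M = n_heads
        self.L = n_levels
        self.K = n_points
        self.offset_net = Linear(d_model, n_heads * n_levels * n_points * 2, rng,
                                 zero_init=True)
        # spread initial sampling points on a small circle per head/point
        thetas = 2 * np.pi * (np.arange(n_heads * n_points) / (n_heads * n_points))
        init = np.stack([np.cos(thetas), np.sin(thetas)], axis=-1)
        init = np.tile(init.reshape(n_heads, 1, n_points, 2), (1, n_levels, 1, 1))
        self.offset_net.bias.data = init.ravel().copy()
        self.attn_net = Linear(d_model, n_heads * n_levels * n_points, rng,
                               zero_init=True)
        self.value_proj = Linear(d_model, d_model, rng)
        self.out_proj = Linear(d_model, d_model, rng)

    def __call__(self, query: Tensor, ref_points: np.ndarray,
                 value_levels: list[Tensor]) -> Tensor:
        """``query`` (Q, d); ``ref_points`` (Q, 2) normalised; the value
        levels are (H_l, W_l, d) tensors.  Returns (Q, d)."""
        Q = query.shape[0]
        M, L, K, d = self.M, self.L, self.K, self.d_model
        dh = d // M
        offsets = self.offset_net(query).reshape(Q, M, L, K, 2)
        attn = softmax(self.attn_net(query).reshape(Q, M, L * K), axis=-1)
        attn = attn.reshape(Q, M, L, K)

        proj_levels = [
            self.value_proj(v.reshape(-1, d)).reshape(v.shape[0], v.shape[1], d)
            for v in value_levels
        ]
        acc = None  # accumulates (Q, M, dh) over levels
        for l, level in enumerate(proj_levels):
            H, W = level.shape[:2]
            base = ref_points * np.array([W, H]) - 0.5           # (Q, 2)
            base_t = Tensor(np.repeat(base[:, None, None, :], M, axis=1)
                            .repeat(K, axis=2).reshape(-1, 2))
            loc = base_t + offsets[:, :, l].reshape(-1, 2)        # (Q*M*K, 2)
            sampled = bilinear_sample(level, loc)                 # (Q*M*K, d)
            sampled = sampled.reshape(Q, M, K, d)
            # per-head channel slice
            head_slices = []
            for m in range(M):
                s_m = sampled[:, m, :, m * dh:(m + 1) * dh]       # (Q, K, dh)
                w_m = attn[:, m, l].reshape(Q, K, 1)              # (Q, K, 1)
                head_slices.append((s_m * w_m).sum(axis=1))       # (Q, dh)
            level_out = concat([h.reshape(Q, 1, dh) for h in head_slices], axis=1)
            acc = level_out if acc is None else acc + level_out
        return self.out_proj(acc.reshape(Q, d))
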