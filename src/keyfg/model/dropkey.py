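"""DropKey-regularised scaled dot-product attention.

DropKey masks attention *logits* (query-key pairs) to -inf with a fixed
probability before the softmax, rather than zeroing post-softmax weights
as ordinary attention dropout does.  The surviving keys therefore still
receive a proper convex combination, which suppresses over-reliance on
individual keys without destroying row normalisation.  Masking is
applied only during training.
"""

from __future__ import annotations

import logging

import numpy as np

from ..nn import Linear, Module, Tensor, concat, softmax

logger = logging.getLogger(__name__)

__all__ = ["dropkey_attention", "SelfAttention"]

_NEG = -1e9


def dropkey_attention(
    queries: Tensor,
    keys: Tensor,
    values: Tensor,
    drop_ratio: float = 0.0,
    rng: np.random.Generator | None = None,
    training: bool = False,
    attn_mask: np.ndarray | None = None,
) -> Tensor:
    """Scaled dot-product attention with DropKey masking.

    ``attn_mask`` is a boolean (Q, K) array where True BLOCKS the pair
    (used by the denoising branch).  If DropKey would remove every
    surviving key of some row, that row falls back to attention without
    the DropKey mask (the structural ``attn_mask`` is always kept).
    """
    if not 0.0 <= drop_ratio < 1.0:
        raise ValueError("drop_ratio must lie in [0, 1)")
    d = queries.shape[-1]
    logits = (queries @ keys.transpose()) * (1.0 / np.sqrt(d))
    nq, nk = logits.shape
    block = np.zeros((nq, nk), dtype=bool)
    if attn_mask is not None:
        block |= np.asarray(attn_mask, dtype=bool)
    if training and drop_ratio > 0.0:
        if rng is None:
            raise ValueError("rng required for DropKey during training")
        drop = rng.random((nq, nk)) < drop_ratio
        dead = (block | drop).all(axis=1) & ~block.all(axis=1)
        if dead.any():
            logger.warning(
                "DropKey removed all keys for %d row(s); falling back to "
                "unmasked attention for those rows", int(dead.sum())
            )
            drop[dead] = False
        block = block | drop
    logits = logits + Tensor(np.where(block, _NEG, 0.0))
    weights = softmax(logits, axis=-1)
    return weights @ values


class SelfAttention(Module):
    """Multi-head self-attention with DropKey (decoder self-attention)."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 drop_ratio: float = 0.1):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.dh = d_model // n_heads
        self.q_proj = Linear(d_model, d_model, rng)
        self.k_proj = Linear(d_model, d_model, rng)
        self.v_proj = Linear(d_model, d_model, rng)
        self.out_proj = Linear(d_model, d_model, rng)
        self.drop_ratio = drop_ratio

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None,
                 training: bool = False,
                 attn_mask: np.ndarray | None = None) -> Tensor:
        q, k, v = self.q_proj(x), self.k_proj(x), self.v_proj(x)
        n = x.shape[0]
        heads = []
        for m in range(self.n_heads):
            sl = slice(m * self.dh, (m + 1) * self.dh)
            heads.append(
                dropkey_attention(
                    q[:, sl], k[:, sl], v[:, sl],
                    drop_ratio=self.drop_ratio, rng=rng,
                    training=training, attn_mask=attn_mask,
                )
            )
        return self.out_proj(concat(heads, axis=1))
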