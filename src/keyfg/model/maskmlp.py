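"""Dual-branch MaskMLP: instance-aware soft feature masking.

A spatial branch maps each location's channel vector to one logit,
giving an (H, W) spatial weight map; a channel branch pools over space
and maps the pooled vector to C logits, one per channel.  The two are
fused by outer product and squashed through a sigmoid to a soft mask in
(0, 1) that multiplies the feature map elementwise, suppressing occluded
boundaries (spatial) and irrelevant channels (channel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..nn import MLP, Module, Tensor, sigmoid

__all__ = ["SoftMask", "MaskMLP", "maskmlp_mask"]


@dataclass
class SoftMask:
    """Spatial logits (H, W), channel logits (C,), and the fused sigmoid
    mask (H, W, C) with values strictly inside (0, 1)."""

    spatial_logits: Tensor
    channel_logits: Tensor
    mask: Tensor

    def apply(self, feature: Tensor) -> Tensor:
        return feature * self.mask


class MaskMLP(Module):
    def __init__(self, d_model: int, hidden: int, rng: np.random.Generator):
        self.spatial = MLP([d_model, hidden, 1], rng)
        self.channel = MLP([d_model, hidden, d_model], rng)

    def __call__(self, feature: Tensor) -> SoftMask:
        """``feature`` is an (H, W, C) map; returns its soft mask."""
        H, W, C = feature.shape
        flat = feature.reshape(H * W, C)
        w_s = self.spatial(flat).reshape(H, W)           # per-location logit
        pooled = flat.mean(axis=0)                       # spatial pooling
        w_c = self.channel(pooled.reshape(1, C)).reshape(C)
        fused = sigmoid(w_s.reshape(H, W, 1) * w_c.reshape(1, 1, C))
        return SoftMask(spatial_logits=w_s, channel_logits=w_c, mask=fused)


def maskmlp_mask(module: MaskMLP, feature: Tensor) -> SoftMask:
    """Functional wrapper around :class:`MaskMLP`."""
    return module(feature)
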