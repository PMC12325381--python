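"""Backbone feature contract and a desk-scale convolutional stand-in.

The reference backbone is ResNet-50: a 7x7 stride-2 stem, a 3x3 stride-2
max pool, then four stages (conv2_x stride 1, conv3_x..conv5_x stride 2)
with output channels 256/512/1024/2048.  ``backbone_stage_shapes`` is the
pure arithmetic of that chain ("same" padding, ceil division), e.g. a
1333x800 input ends at 42x25x2048.

:class:`TinyBackbone` is a small convolutional network with the identical
stride arithmetic (so token grids and reference-point geometry match the
contract) but desk-scale channel counts, used where pretrained weights
are unavailable and tests must run in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..nn import Conv2d, Module, Tensor, relu

__all__ = ["StageShape", "backbone_stage_shapes", "TinyBackbone", "FeaturePyramid"]

_RESNET50_CHANNELS = {
    "conv1": 64,
    "pool": 64,
    "conv2_x": 256,
    "conv3_x": 512,
    "conv4_x": 1024,
    "conv5_x": 2048,
}
_STAGE_STRIDES = {"conv1": 2, "pool": 2, "conv2_x": 1, "conv3_x": 2,
                  "conv4_x": 2, "conv5_x": 2}


@dataclass(frozen=True)
class StageShape:
    stage: str
    height: int
    width: int
    channels: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0 or self.channels <= 0:
            raise ValueError("stage dimensions must be positive")


def backbone_stage_shapes(input_h: int, input_w: int) -> list[StageShape]:
    """Deterministic shape chain of the ResNet-50 backbone under "same"
    stride arithmetic (ceil division per stride-2 stage)."""
    if input_h < 32 or input_w < 32:
        raise ValueError("input must be at least 32x32")
    h, w = input_h, input_w
    shapes = []
    for stage in ("conv1", "pool", "conv2_x", "conv3_x", "conv4_x", "conv5_x"):
        s = _STAGE_STRIDES[stage]
        h = -(-h // s)
        w = -(-w // s)
        shapes.append(StageShape(stage, h, w, _RESNET50_CHANNELS[stage]))
    return shapes


@dataclass
class FeaturePyramid:
    """Multi-level feature maps sharing a channel width after projection.

    Level l+1's spatial size is the ceil-half of level l's.
    """

    levels: list  # list of Tensor, each (H_l, W_l, C)

    def __post_init__(self) -> None:
        for a, b in zip(self.levels[:-1], self.levels[1:]):
            ha, wa = a.shape[:2]
            hb, wb = b.shape[:2]
            if hb != -(-ha // 2) or wb != -(-wa // 2):
                raise ValueError(
                    f"pyramid levels must halve (ceil): {a.shape} -> {b.shape}"
                )

    @property
    def shapes(self) -> list[tuple[int, int]]:
        return [lvl.shape[:2] for lvl in self.levels]

    @property
    def n_tokens(self) -> int:
        return sum(h * w for h, w in self.shapes)


class TinyBackbone(Module):
    """Four-stage stand-in backbone with ResNet stride arithmetic.

    Produces feature maps at strides 4, 8, 16 and 32 ("res2".."res5");
    the pyramid hands out the deepest ``n_levels`` of res3/res4/res5
    (strides 8/16/32), matching the reference backbone's detection taps.
    """

    STAGE_CHANNELS = (8, 16, 24, 32)  # res2..res5

    def __init__(self, rng: np.random.Generator, bias: bool = True):
        c = self.STAGE_CHANNELS
        self.stem = Conv2d(3, c[0], 3, 2, rng, bias=bias)     # stride 2
        self.pool = Conv2d(c[0], c[0], 3, 2, rng, bias=bias)  # stride 4
        self.res2 = Conv2d(c[0], c[0], 3, 1, rng, bias=bias)  # stride 4
        self.res3 = Conv2d(c[0], c[1], 3, 2, rng, bias=bias)  # stride 8
        self.res4 = Conv2d(c[1], c[2], 3, 2, rng, bias=bias)  # stride 16
        self.res5 = Conv2d(c[2], c[3], 3, 2, rng, bias=bias)  # stride 32

    def __call__(self, image: Tensor) -> dict[str, Tensor]:
        x = relu(self.stem(image))
        x = relu(self.pool(x))
        r2 = relu(self.res2(x))
        r3 = relu(self.res3(r2))
        r4 = relu(self.res4(r3))
        r5 = relu(self.res5(r4))
        return {"res2": r2, "res3": r3, "res4": r4, "res5": r5}

    def feature_levels(self, image: Tensor, n_levels: int) -> list[Tensor]:
        """The shallowest-to-deepest taps used for the pyramid."""
        feats = self(image)
        names = ["res3", "res4", "res5"][:n_levels]
        return [feats[n] for n in names]
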