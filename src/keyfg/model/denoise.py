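"""Denoising-query construction for training stabilisation.

G groups of noised copies of the ground-truth boxes and labels are
appended to the matching queries.  Each noised query must reconstruct
its own ground truth (no Hungarian matching involved), giving the
decoder a stable auxiliary regression task that counteracts the
query-to-ground-truth matching instability.  An attention mask keeps the
denoising part invisible to the matching queries and the groups
invisible to each other, so no ground-truth information leaks into the
main prediction path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DenoisingBatch", "build_denoising_queries"]


@dataclass
class DenoisingBatch:
    """Noised queries plus the decoder self-attention mask.

    Boxes are normalised (cx, cy, w, h); ``attn_mask`` is a boolean
    (T, T) array over [matching | group_0 | ... | group_{G-1}] query
    layout where True blocks attention from row-query to column-key.
    """

    boxes: np.ndarray          # (G * n_gt, 4)
    labels: np.ndarray         # (G * n_gt,)
    gt_index: np.ndarray       # (G * n_gt,) index of the GT each copy noises
    n_groups: int
    n_matching: int
    attn_mask: np.ndarray = field(repr=False, default=None)

    @property
    def n_denoising(self) -> int:
        return self.boxes.shape[0]


def build_denoising_queries(
    gt_boxes: np.ndarray,
    gt_labels: np.ndarray,
    n_classes: int,
    n_matching_queries: int,
    box_noise_scale: float = 0.4,
    label_flip_prob: float = 0.5,
    n_groups: int = 5,
    rng: np.random.Generator | None = None,
) -> DenoisingBatch:
    """Build G groups of noised ground-truth queries.

    Centres are jittered uniformly within +-box_noise_scale * (w, h) / 2,
    sizes multiplied by factors drawn from [1 - s, 1 + s], boxes clamped
    to the unit image; labels flip to a uniformly random *other* class
    with probability ``label_flip_prob``.  With zero ground truths the
    denoising part is empty but the mask still isolates nothing to leak.
    """
    if box_noise_scale < 0:
        raise ValueError("box_noise_scale must be >= 0")
    if not 0.0 <= label_flip_prob <= 1.0:
        raise ValueError("label_flip_prob must lie in [0, 1]")
    rng = rng or np.random.default_rng()
    gt_boxes = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    gt_labels = np.asarray(gt_labels, dtype=int).reshape(-1)
    n_gt = gt_boxes.shape[0]

    all_boxes = []
    all_labels = []
    gt_index = []
    for _g in range(n_groups):
        boxes = gt_boxes.copy()
        if n_gt:
            jitter = rng.uniform(-0.5, 0.5, size=(n_gt, 2)) * box_noise_scale
            boxes[:, :2] += jitter * boxes[:, 2:]
            factors = rng.uniform(1 - box_noise_scale, 1 + box_noise_scale,
                                  size=(n_gt, 2))
            boxes[:, 2:] *= factors
            boxes[:, 2:] = np.clip(boxes[:, 2:], 1e-4, 1.0)
            boxes[:, :2] = np.clip(boxes[:, :2], 0.0, 1.0)
            labels = gt_labels.copy()
            flip = rng.random(n_gt) < label_flip_prob
            if n_classes > 1:
                shift = rng.integers(1, n_classes, size=n_gt)
                labels = np.where(flip, (labels + shift) % n_classes, labels)
        else:
            labels = gt_labels.copy()
        all_boxes.append(boxes)
        all_labels.append(labels)
        gt_index.append(np.arange(n_gt))

    boxes = np.concatenate(all_boxes, axis=0) if n_gt else np.zeros((0, 4))
    labels = np.concatenate(all_labels, axis=0) if n_gt else np.zeros(0, dtype=int)
    gt_index = np.concatenate(gt_index, axis=0) if n_gt else np.zeros(0, dtype=int)

    n_dn = boxes.shape[0]
    T = n_matching_queries + n_dn
    mask = np.zeros((T, T), dtype=bool)
    # matching queries must not see any denoising query
    mask[:n_matching_queries, n_matching_queries:] = True
    # denoising groups must not see each other
    for g in range(n_groups):
        a = n_matching_queries + g * n_gt
        b = a + n_gt
        mask[a:b, n_matching_queries:a] = True
        mask[a:b, b:] = True
    return DenoisingBatch(
        boxes=boxes, labels=labels, gt_index=gt_index,
        n_groups=n_groups, n_matching=n_matching_queries, attn_mask=mask,
    )
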