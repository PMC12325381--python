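"""Box coordinate utilities, in numpy and in autodiff tensors.

Boxes inside the model are normalised (cx, cy, w, h); the COCO boundary
converts to/from pixel [x, y, w, h].
"""

from __future__ import annotations

import numpy as np

from ..nn import Tensor, as_tensor, clip, concat, maximum, minimum

__all__ = ["cxcywh_to_xyxy", "xyxy_to_cxcywh", "box_iou_np", "giou_np",
           "t_cxcywh_to_xyxy", "t_giou", "inverse_sigmoid"]


def cxcywh_to_xyxy(b: np.ndarray) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    cx, cy, w, h = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=-1)


def xyxy_to_cxcywh(b: np.ndarray) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    x0, y0, x1, y1 = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return np.stack([(x0 + x1) / 2, (y0 + y1) / 2, x1 - x0, y1 - y0], axis=-1)


def box_iou_np(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of xyxy boxes: (N, M)."""
    a = np.asarray(a, dtype=float).reshape(-1, 4)
    b = np.asarray(b, dtype=float).reshape(-1, 4)
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)


def giou_np(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise generalised IoU of xyxy boxes: (N, M), in [-1, 1]."""
    a = np.asarray(a, dtype=float).reshape(-1, 4)
    b = np.asarray(b, dtype=float).reshape(-1, 4)
    iou = box_iou_np(a, b)
    tl = np.minimum(a[:, None, :2], b[None, :, :2])
    br = np.maximum(a[:, None, 2:], b[None, :, 2:])
    hull = np.clip(br - tl, 0, None)
    hull_area = hull[..., 0] * hull[..., 1]
    wh_a = np.clip(a[:, 2:] - a[:, :2], 0, None)
    wh_b = np.clip(b[:, 2:] - b[:, :2], 0, None)
    inter_tl = np.maximum(a[:, None, :2], b[None, :, :2])
    inter_br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    inter = np.clip(inter_br - inter_tl, 0, None)
    union = (wh_a[:, 0] * wh_a[:, 1])[:, None] + (wh_b[:, 0] * wh_b[:, 1])[None, :] \
        - inter[..., 0] * inter[..., 1]
    return iou - np.where(hull_area > 0, (hull_area - union) / np.where(hull_area > 0, hull_area, 1.0), 0.0)


# -------------------------------- differentiable versions ----------------


def t_cxcywh_to_xyxy(b: Tensor) -> Tensor:
    cx, cy = b[:, 0], b[:, 1]
    w, h = b[:, 2], b[:, 3]
    n = b.shape[0]
    return concat(
        [
            (cx - w * 0.5).reshape(n, 1),
            (cy - h * 0.5).reshape(n, 1),
            (cx + w * 0.5).reshape(n, 1),
            (cy + h * 0.5).reshape(n, 1),
        ],
        axis=1,
    )


def t_giou(pred_xyxy: Tensor, gt_xyxy: np.ndarray) -> Tensor:
    """Elementwise (matched-pair) GIoU, differentiable in the predictions."""
    gt = as_tensor(gt_xyxy)
    tl = maximum(pred_xyxy[:, :2], gt[:, :2])
    br = minimum(pred_xyxy[:, 2:], gt[:, 2:])
    wh = maximum(br - tl, 0.0)
    inter = wh[:, 0] * wh[:, 1]
    area_p = maximum(pred_xyxy[:, 2] - pred_xyxy[:, 0], 0.0) * maximum(
        pred_xyxy[:, 3] - pred_xyxy[:, 1], 0.0
    )
    area_g = (gt[:, 2] - gt[:, 0]) * (gt[:, 3] - gt[:, 1])
    union = area_p + area_g - inter
    iou = inter / (union + 1e-9)
    htl = minimum(pred_xyxy[:, :2], gt[:, :2])
    hbr = maximum(pred_xyxy[:, 2:], gt[:, 2:])
    hwh = maximum(hbr - htl, 0.0)
    hull = hwh[:, 0] * hwh[:, 1]
    return iou - (hull - union) / (hull + 1e-9)


def inverse_sigmoid(x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    x = np.clip(np.asarray(x, dtype=float), eps, 1 - eps)
    return np.log(x / (1 - x))
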