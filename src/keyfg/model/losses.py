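"""Composite detection loss: five weighted components.

``total = lam_match * L_match + lam_dn * L_dn + lam_mask * L_mask
        + lam_fg * L_fg + lam_enc * L_enc``

* match — sigmoid focal classification over all queries plus L1 and
  GIoU regression over Hungarian-matched pairs (decoder layers are
  deep-supervised: every layer contributes a match-style term);
* dn — the same form over denoising queries, each reconstructing its
  own ground truth without matching;
* mask — binary cross-entropy of the MaskMLP soft masks against
  ground-truth object masks (pooled to each level's grid);
* fg — binary cross-entropy of the FGSP foreground probabilities
  against token-in-box labels (token centre inside any GT box -> 1);
* enc — a match-style loss on the last encoder layer's auxiliary
  class/box predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..nn import Tensor, as_tensor, clip, log, sigmoid
from .boxes import t_cxcywh_to_xyxy, t_giou

__all__ = ["LossWeights", "LossBreakdown", "focal_loss", "bce_with_logits",
           "box_losses", "composite_loss"]


@dataclass(frozen=True)
class LossWeights:
    lam_match: float = 1.0
    lam_dn: float = 1.0
    lam_mask: float = 1.0
    lam_fg: float = 1.0
    lam_enc: float = 1.0

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"loss weight {name} must be non-negative")

    def as_tuple(self):
        return (self.lam_match, self.lam_dn, self.lam_mask, self.lam_fg, self.lam_enc)


@dataclass
class LossBreakdown:
    match: float
    dn: float
    mask: float
    fg: float
    enc: float
    total: Tensor  # differentiable weighted sum

    @property
    def total_value(self) -> float:
        return float(self.total.data)

    def to_dict(self) -> dict:
        return {"match": self.match, "dn": self.dn, "mask": self.mask,
                "fg": self.fg, "enc": self.enc, "total": self.total_value}


def focal_loss(logits: Tensor, targets: np.ndarray, alpha: float = 0.25,
               gamma: float = 2.0, normalizer: float = 1.0) -> Tensor:
    """Sigmoid focal loss summed over entries, divided by ``normalizer``
    (conventionally the number of ground-truth boxes)."""
    t = np.asarray(targets, dtype=float)
    p = sigmoid(logits)
    p = clip(p, 1e-7, 1 - 1e-7)
    tt = as_tensor(t)
    pt = p * tt + (1.0 - p) * (1.0 - tt)
    alpha_t = alpha * t + (1 - alpha) * (1 - t)
    loss = (as_tensor(alpha_t) * ((1.0 - pt) ** gamma) * (-log(pt))).sum()
    return loss / max(normalizer, 1.0)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from logits."""
    t = as_tensor(np.asarray(targets, dtype=float))
    p = clip(sigmoid(logits), 1e-7, 1 - 1e-7)
    return (-(t * log(p) + (1.0 - t) * log(1.0 - p))).mean()


def bce_on_probs(probs: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on probabilities already in (0, 1)."""
    t = as_tensor(np.asarray(targets, dtype=float))
    p = clip(probs, 1e-7, 1 - 1e-7)
    return (-(t * log(p) + (1.0 - t) * log(1.0 - p))).mean()


def box_losses(pred_boxes: Tensor, gt_boxes: np.ndarray) -> tuple[Tensor, Tensor]:
    """L1 and (1 - GIoU) losses over matched pairs, averaged over pairs.

    Both in normalised (cx, cy, w, h); GIoU computed after conversion."""
    gt = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    n = max(gt.shape[0], 1)
    diff = pred_boxes - as_tensor(gt)
    l1 = ((diff * diff) + 1e-12) ** 0.5  # smooth |x|, finite gradient at 0
    l1 = (l1.sum()) / n
    giou = t_giou(t_cxcywh_to_xyxy(pred_boxes), _cxcywh_to_xyxy_np(gt))
    return l1, (1.0 - giou).sum() / n


def _cxcywh_to_xyxy_np(b: np.ndarray) -> np.ndarray:
    cx, cy, w, h = b[:, 0], b[:, 1], b[:, 2], b[:, 3]
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def _set_prediction_loss(
    logits: Tensor, boxes: Tensor, gt_boxes: np.ndarray, gt_labels: np.ndarray,
    matched_pred_idx: np.ndarray, n_classes: int,
    w_cls: float = 1.0, w_l1: float = 5.0, w_giou: float = 2.0,
) -> Tensor:
    """Focal classification over all queries + box regression on matches."""
    Q = logits.shape[0]
    targets = np.zeros((Q, n_classes))
    if matched_pred_idx.size:
        targets[matched_pred_idx, np.asarray(gt_labels, dtype=int)] = 1.0
    n_gt = max(len(np.atleast_1d(gt_labels)), 1)
    cls = focal_loss(logits, targets, normalizer=n_gt)
    if matched_pred_idx.size:
        mb = boxes[matched_pred_idx]
        l1, giou = box_losses(mb, gt_boxes)
    else:
        l1 = giou = as_tensor(0.0)
    return w_cls * cls + w_l1 * l1 + w_giou * giou


def composite_loss(outputs: dict, targets: dict, weights: LossWeights = LossWeights()) -> LossBreakdown:
    """Assemble the five-component weighted loss.

    ``outputs`` carries model tensors (see :mod:`keyfg.model.detector`);
    ``targets`` carries ``boxes`` (G, 4) normalised cxcywh, ``labels``
    (G,), optional ``level_masks`` (ground-truth object masks pooled per
    pyramid level) and ``fg_labels`` per token.  Missing parts contribute
    zero to their component.
    """
    n_classes = outputs["n_classes"]
    gt_boxes = np.asarray(targets.get("boxes", np.zeros((0, 4))), dtype=float).reshape(-1, 4)
    gt_labels = np.asarray(targets.get("labels", np.zeros(0)), dtype=int).reshape(-1)

    zero = as_tensor(0.0)

    # --- match (deep supervision over decoder layers)
    match_t = zero
    layer_outs = outputs.get("decoder_layers", [])
    for lo in layer_outs:
        match_t = match_t + _set_prediction_loss(
            lo["logits"], lo["boxes"], gt_boxes, gt_labels,
            lo["matched_pred_idx"], n_classes,
        )
    if layer_outs:
        match_t = match_t / len(layer_outs)

    # --- denoising
    dn_t = zero
    dn = outputs.get("dn")
    if dn is not None and dn["boxes"].shape[0] > 0 and gt_boxes.shape[0] > 0:
        idx = np.arange(dn["boxes"].shape[0])
        dn_t = _set_prediction_loss(
            dn["logits"], dn["boxes"],
            gt_boxes[dn["gt_index"]], gt_labels[dn["gt_index"]],
            idx, n_classes,
        )

    # --- mask
    mask_t = zero
    soft_masks = outputs.get("soft_masks")
    level_masks = targets.get("level_masks")
    if soft_masks and level_masks is not None:
        parts = []
        for sm, gt_m in zip(soft_masks, level_masks):
            t = np.broadcast_to(np.asarray(gt_m, dtype=float)[..., None],
                                sm.mask.shape)
            parts.append(bce_on_probs(sm.mask, t))
        for p in parts:
            mask_t = mask_t + p
        mask_t = mask_t / len(parts)

    # --- foreground selector
    fg_t = zero
    if "fg_logits" in outputs and "fg_labels" in targets:
        fg_t = bce_with_logits(outputs["fg_logits"], targets["fg_labels"])

    # --- encoder auxiliary
    enc_t = zero
    enc = outputs.get("enc")
    if enc is not None and gt_boxes.shape[0] > 0:
        enc_t = _set_prediction_loss(
            enc["logits"], enc["boxes"], gt_boxes, gt_labels,
            enc["matched_pred_idx"], n_classes,
        )

    lam = weights
    total = (lam.lam_match * match_t + lam.lam_dn * dn_t + lam.lam_mask * mask_t
             + lam.lam_fg * fg_t + lam.lam_enc * enc_t)
    return LossBreakdown(
        match=float(match_t.data), dn=float(dn_t.data), mask=float(mask_t.data),
        fg=float(fg_t.data), enc=float(enc_t.data), total=total,
    )
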