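"""Hungarian bipartite matching between predictions and ground truths.

Set-prediction training needs a one-to-one assignment of ground-truth
objects to predictions; the minimum-cost assignment under a mixed
classification/L1/GIoU cost is found with the Hungarian algorithm
(scipy's linear_sum_assignment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .boxes import cxcywh_to_xyxy, giou_np

__all__ = ["MatchWeights", "hungarian_match", "assign_min_cost"]


def assign_min_cost(cost: np.ndarray) -> np.ndarray:
    """Minimum-cost one-to-one assignment for an (n_pred, n_gt) cost
    matrix; returns the prediction index assigned to each ground truth."""
    cost = np.atleast_2d(np.asarray(cost, dtype=float))
    P, G = cost.shape
    if P < G:
        raise ValueError(f"need at least as many predictions ({P}) as ground truths ({G})")
    rows, cols = linear_sum_assignment(cost)
    pred_idx = np.empty(G, dtype=int)
    pred_idx[cols] = rows
    return pred_idx


@dataclass(frozen=True)
class MatchWeights:
    w_cls: float = 2.0
    w_l1: float = 5.0
    w_giou: float = 2.0


def hungarian_match(
    pred_boxes: np.ndarray,
    pred_probs: np.ndarray,
    gt_boxes: np.ndarray,
    gt_labels: np.ndarray,
    weights: MatchWeights = MatchWeights(),
) -> np.ndarray:
    """Assign each ground truth a distinct prediction at minimum cost.

    Boxes are normalised (cx, cy, w, h); ``pred_probs`` is (P, n_classes)
    with per-class probabilities.  The (P, G) cost is
    ``w_cls * (1 - prob_of_gt_class) + w_l1 * L1(box) + w_giou * (1 - GIoU)``.
    Returns an array ``pred_idx`` of length G: gt j is matched to
    prediction ``pred_idx[j]``.
    """
    pred_boxes = np.asarray(pred_boxes, dtype=float).reshape(-1, 4)
    gt_boxes = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    pred_probs = np.atleast_2d(np.asarray(pred_probs, dtype=float))
    gt_labels = np.asarray(gt_labels, dtype=int).reshape(-1)
    P, G = pred_boxes.shape[0], gt_boxes.shape[0]
    if P < G:
        raise ValueError(f"need at least as many predictions ({P}) as ground truths ({G})")
    if G == 0:
        return np.zeros(0, dtype=int)
    cls_cost = 1.0 - pred_probs[:, gt_labels]                     # (P, G)
    l1_cost = np.abs(pred_boxes[:, None, :] - gt_boxes[None, :, :]).sum(-1)
    giou_cost = 1.0 - giou_np(cxcywh_to_xyxy(pred_boxes), cxcywh_to_xyxy(gt_boxes))
    cost = weights.w_cls * cls_cost + weights.w_l1 * l1_cost + weights.w_giou * giou_cost
    rows, cols = linear_sum_assignment(cost)
    pred_idx = np.empty(G, dtype=int)
    pred_idx[cols] = rows
    return pred_idx
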