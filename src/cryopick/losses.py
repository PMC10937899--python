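"""Set-prediction training objective.

Ground truth for one micrograph is a set of particle boxes, conceptually
padded with "no-particle" entries up to the prediction count N.  Training
first solves a bipartite assignment between true particles and
prediction slots — the cost of pairing truth i with slot j is
``-p_j(particle) + box_loss(b_i, b_j)`` and no-particle padding pairs
cost nothing — then scores the matched configuration with the Hungarian
loss: a negative-log-likelihood classification term over all N slots
(down-weighted by a factor of 10 for no-particle slots, i.e. multiplied
by 0.1, to counter class imbalance) plus an L1 + generalized-IoU box
term over matched pairs only.

Note the deliberate asymmetry: the matching cost uses the raw particle
probability, the loss uses the log-probability.

All loss terms are written with ``autograd.numpy`` so they are
differentiable with respect to predicted logits and boxes; the
assignment itself is solved on detached values with SciPy's
linear-sum-assignment solver (any cost-minimal assignment is acceptable).
Class index 0 is "particle", index 1 is the no-particle class.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np
from autograd.tracer import getval
from scipy.optimize import linear_sum_assignment

__all__ = [
    "MatchResult",
    "LossBreakdown",
    "box_cxcywh_to_xyxy",
    "giou_loss",
    "box_loss",
    "match_cost",
    "hungarian_match",
    "hungarian_loss",
    "annotations_to_boxes",
]

PARTICLE, EMPTY = 0, 1
_MIN_SIDE = 1e-6  # clamp for degenerate zero-area boxes


@dataclass
class MatchResult:
    """Optimal assignment of ground-truth entries to prediction slots.

    ``permutation[i]`` is the slot index for ground-truth entry ``i``;
    entries beyond the true particle count are padding and carry zero
    matching cost.
    """

    permutation: np.ndarray  # (N,) int
    num_true: int
    total_cost: float
    pair_costs: np.ndarray  # (num_true,)


@dataclass
class LossBreakdown:
    class_term: object  # negative log-likelihood over all N slots
    l1_term: object  # unweighted sum of matched L1 distances
    giou_term: object  # unweighted sum of matched GIoU losses
    total: object  # class + lambda_l1 * l1 + lambda_iou * giou
    lambda_iou: float
    lambda_l1: float
    empty_weight: float


def box_cxcywh_to_xyxy(b):
    """(cx, cy, w, h) -> corner coordinates, with w/h clamped positive."""
    cx, cy = b[..., 0], b[..., 1]
    w = anp.maximum(b[..., 2], _MIN_SIDE)
    h = anp.maximum(b[..., 3], _MIN_SIDE)
    return cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2


def giou_loss(b1, b2):
    """Generalized-IoU loss, elementwise over broadcast box arrays.

    ``1 - IoU + |B \\ (b1 u b2)| / |B|`` where B is the smallest box
    enclosing both; ranges over [0, 2].
    """
    x1a, y1a, x2a, y2a = box_cxcywh_to_xyxy(b1)
    x1b, y1b, x2b, y2b = box_cxcywh_to_xyxy(b2)
    area_a = (x2a - x1a) * (y2a - y1a)
    area_b = (x2b - x1b) * (y2b - y1b)
    iw = anp.maximum(anp.minimum(x2a, x2b) - anp.maximum(x1a, x1b), 0.0)
    ih = anp.maximum(anp.minimum(y2a, y2b) - anp.maximum(y1a, y1b), 0.0)
    inter = iw * ih
    union = area_a + area_b - inter
    ew = anp.maximum(x2a, x2b) - anp.minimum(x1a, x1b)
    eh = anp.maximum(y2a, y2b) - anp.minimum(y1a, y1b)
    enclose = ew * eh
    return 1.0 - inter / union + (enclose - union) / enclose


def box_loss(b, b_hat, lambda_iou: float = 2.0, lambda_l1: float = 5.0):
    """Weighted box score: lambda_iou * GIoU-loss + lambda_l1 * L1."""
    l1 = anp.sum(anp.abs(b - b_hat), axis=-1)
    return lambda_iou * giou_loss(b, b_hat) + lambda_l1 * l1


def match_cost(gt_box, particle_prob, pred_box, lambda_iou: float = 2.0,
               lambda_l1: float = 5.0):
    """Pairwise matching cost; a no-particle ground-truth entry costs 0."""
    if gt_box is None:
        return 0.0
    return -particle_prob + box_loss(
        anp.asarray(gt_box), anp.asarray(pred_box), lambda_iou, lambda_l1
    )


def hungarian_match(gt_boxes, class_probs, pred_boxes, lambda_iou: float = 2.0,
                    lambda_l1: float = 5.0) -> MatchResult:
    """Cost-minimal one-to-one assignment of truths to prediction slots."""
    gt_boxes = np.atleast_2d(np.asarray(getval(gt_boxes), dtype=np.float64))
    probs = np.asarray(getval(class_probs), dtype=np.float64)
    boxes = np.asarray(getval(pred_boxes), dtype=np.float64)
    n_slots = boxes.shape[0]
    n_true = 0 if gt_boxes.size == 0 else gt_boxes.shape[0]
    if n_true > n_slots:
        raise ValueError(
            f"{n_true} ground-truth particles exceed {n_slots} prediction slots"
        )
    if n_true == 0:
        return MatchResult(np.arange(n_slots), 0, 0.0, np.zeros(0))
    cost = (
        -probs[None, :, PARTICLE]
        + np.asarray(
            box_loss(gt_boxes[:, None], boxes[None, :], lambda_iou, lambda_l1)
        )
    )
    if not np.all(np.isfinite(cost)):
        raise ValueError("non-finite matching costs")
    rows, cols = linear_sum_assignment(cost)
    order = np.argsort(rows)
    rows, cols = rows[order], cols[order]
    perm = np.full(n_slots, -1, dtype=int)
    perm[:n_true] = cols
    free = sorted(set(range(n_slots)) - set(cols.tolist()))
    perm[n_true:] = free
    pair_costs = cost[rows, cols]
    return MatchResult(perm, n_true, float(pair_costs.sum()), pair_costs)


def hungarian_loss(gt_boxes, class_logits, pred_boxes,
                   match: MatchResult | None = None,
                   lambda_iou: float = 2.0, lambda_l1: float = 5.0,
                   empty_weight: float = 0.1) -> LossBreakdown:
    """Hungarian loss of one micrograph given the optimal assignment.

    Sum over all N slots of the classification NLL (no-particle slots
    multiplied by ``empty_weight``) plus the weighted box loss over
    matched true pairs.  Differentiable in ``class_logits``/``pred_boxes``.
    """
    gt = np.atleast_2d(np.asarray(getval(gt_boxes), dtype=np.float64))
    n_true = 0 if gt.size == 0 else gt.shape[0]
    n_slots = class_logits.shape[0]
    if match is None:
        z = getval(class_logits)
        z = z - z.max(axis=-1, keepdims=True)
        probs = np.exp(z) / np.exp(z).sum(axis=-1, keepdims=True)
        match = hungarian_match(gt_boxes, probs, pred_boxes, lambda_iou, lambda_l1)

    slots_true = match.permutation[:n_true]
    targets = np.full(n_slots, EMPTY, dtype=int)
    targets[slots_true] = PARTICLE
    weights = np.where(targets == EMPTY, empty_weight, 1.0)

    zmax = anp.max(class_logits, axis=-1, keepdims=True)
    logz = zmax + anp.log(anp.sum(anp.exp(class_logits - zmax), axis=-1,
                                  keepdims=True))
    logp = class_logits - logz
    class_term = -anp.sum(weights * logp[np.arange(n_slots), targets])

    if n_true:
        matched = pred_boxes[slots_true]
        gt_arr = anp.asarray(gt)
        l1_term = anp.sum(anp.abs(gt_arr - matched))
        giou_term = anp.sum(giou_loss(gt_arr, matched))
    else:
        l1_term = 0.0
        giou_term = 0.0
    total = class_term + lambda_l1 * l1_term + lambda_iou * giou_term
    return LossBreakdown(class_term, l1_term, giou_term, total,
                         lambda_iou, lambda_l1, empty_weight)


def batch_hungarian_loss(gt_list, class_logits, pred_boxes,
                         lambda_iou: float = 2.0, lambda_l1: float = 5.0,
                         empty_weight: float = 0.1):
    """Hungarian loss summed over a batch, vectorized across images.

    ``gt_list`` holds one (n_i, 4) ground-truth box array per image;
    ``class_logits`` is (B, N, 2) and ``pred_boxes`` (B, N, 4).  The
    matching is solved per image on detached values; the differentiable
    part is then evaluated with a handful of batched tensor operations
    (this is what makes CPU training steps cheap).

    Returns ``(total, parts, n_boxes)`` with ``total`` the batch sum of
    per-image Hungarian losses, ``parts`` the detached (class, l1, giou)
    sums and ``n_boxes`` the number of true particles in the batch.
    """
    b = len(gt_list)
    n_slots = class_logits.shape[1]
    z = getval(class_logits)
    z = z - z.max(axis=-1, keepdims=True)
    probs = np.exp(z) / np.exp(z).sum(axis=-1, keepdims=True)
    det_boxes = getval(pred_boxes)

    targets = np.full((b, n_slots), EMPTY, dtype=int)
    pair_b, pair_s = [], []
    gt_rows = []
    for i, gt in enumerate(gt_list):
        gt = np.atleast_2d(np.asarray(getval(gt), dtype=np.float32))
        n_true = 0 if gt.size == 0 else gt.shape[0]
        if n_true == 0:
            continue
        match = hungarian_match(gt, probs[i], det_boxes[i], lambda_iou,
                                lambda_l1)
        slots = match.permutation[:n_true]
        targets[i, slots] = PARTICLE
        pair_b.append(np.full(n_true, i))
        pair_s.append(slots)
        gt_rows.append(gt)

    weights = np.where(targets == EMPTY, empty_weight, 1.0)
    zmax = anp.max(class_logits, axis=-1, keepdims=True)
    logz = zmax + anp.log(anp.sum(anp.exp(class_logits - zmax), axis=-1,
                                  keepdims=True))
    logp = class_logits - logz
    bi, si = np.meshgrid(np.arange(b), np.arange(n_slots), indexing="ij")
    class_term = -anp.sum(weights * logp[bi, si, targets])

    if gt_rows:
        pb = np.concatenate(pair_b)
        ps = np.concatenate(pair_s)
        gt_cat = np.concatenate(gt_rows, axis=0)
        matched = pred_boxes[pb, ps]
        l1_term = anp.sum(anp.abs(gt_cat - matched))
        giou_term = anp.sum(giou_loss(gt_cat, matched))
        n_boxes = len(gt_cat)
    else:
        l1_term = 0.0
        giou_term = 0.0
        n_boxes = 0
    total = class_term + lambda_l1 * l1_term + lambda_iou * giou_term
    parts = np.array([float(getval(class_term)), float(getval(l1_term)),
                      float(getval(giou_term))])
    return total, parts, n_boxes


def annotations_to_boxes(annotations, image_shape) -> np.ndarray:
    """Ground-truth (center, diameter) records -> normalized (cx, cy, w, h)."""
    h, w = image_shape
    if not annotations:
        return np.zeros((0, 4))
    out = np.array(
        [
            [a.center_x / w, a.center_y / h, a.diameter / w, a.diameter / h]
            for a in annotations
        ],
        dtype=np.float32,
    )
    return out
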