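"""Bipartite matching cost, generalized IoU, and the Hungarian loss."""

import itertools

import numpy as np
import pytest
from autograd import grad

from cryopick.losses import (
    box_loss,
    giou_loss,
    hungarian_loss,
    hungarian_match,
    match_cost,
)


def _xyxy_to_cxcywh(x1, y1, x2, y2):
    return np.array([(x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1])


def brute_force_min_cost(gt_boxes, probs, boxes, lam_iou=2.0, lam_l1=5.0):
    """Exhaustive minimum matching cost over all slot permutations."""
    n, m = len(gt_boxes), len(boxes)
    best = np.inf
    cost = (
        -probs[None, :, 0]
        + np.asarray(box_loss(gt_boxes[:, None], boxes[None, :], lam_iou, lam_l1))
    )
    for perm in itertools.permutations(range(m), n):
        best = min(best, sum(cost[i, p] for i, p in enumerate(perm)))
    return best


class TestMatchCost:
    def test_perfect_prediction_costs_minus_one(self):
        b = np.array([0.5, 0.5, 0.2, 0.2])
        assert match_cost(b, 1.0, b) == pytest.approx(-1.0)

    def test_empty_ground_truth_costs_zero(self):
        assert match_cost(None, 0.99, np.array([0.1, 0.1, 0.5, 0.5])) == 0.0

    def test_weighted_arithmetic_example(self):
        # prob 0.5, L1 distance 0.2, GIoU loss 0.4, lambdas (5, 2)
        # -> -0.5 + (5*0.2 + 2*0.4) = 1.3; engineered via explicit terms
        gt = np.array([0.5, 0.5, 0.2, 0.2])
        pred = np.array([0.55, 0.55, 0.25, 0.25])
        l1 = np.abs(gt - pred).sum()
        g = float(giou_loss(gt, pred))
        expected = -0.5 + 5 * l1 + 2 * g
        assert match_cost(gt, 0.5, pred, 2.0, 5.0) == pytest.approx(expected)
        assert l1 == pytest.approx(0.2)


class TestGiou:
    def test_identical_boxes_zero(self):
        b = np.array([0.4, 0.6, 0.3, 0.2])
        assert float(giou_loss(b, b)) == pytest.approx(0.0, abs=1e-9)

    def test_half_overlap_corner_case(self):
        a = _xyxy_to_cxcywh(0, 0, 2, 2)
        b = _xyxy_to_cxcywh(1, 0, 3, 2)
        # intersection 2, union 6, enclosing 6 -> 1 - 1/3 + 0
        assert float(giou_loss(a, b)) == pytest.approx(2 / 3)

    def test_disjoint_diagonal_corner_case(self):
        a = _xyxy_to_cxcywh(0, 0, 1, 1)
        b = _xyxy_to_cxcywh(2, 2, 3, 3)
        # IoU 0, union 2, enclosing 9 -> 1 + 7/9
        assert float(giou_loss(a, b)) == pytest.approx(16 / 9)

    def test_range_symmetry_translation_invariance(self, rng):
        b1 = np.stack([rng.uniform(0.2, 0.8, 1000), rng.uniform(0.2, 0.8, 1000),
                       rng.uniform(0.01, 0.4, 1000), rng.uniform(0.01, 0.4, 1000)],
                      axis=-1)
        b2 = np.stack([rng.uniform(0.2, 0.8, 1000), rng.uniform(0.2, 0.8, 1000),
                       rng.uniform(0.01, 0.4, 1000), rng.uniform(0.01, 0.4, 1000)],
                      axis=-1)
        losses = np.asarray(giou_loss(b1, b2))
        assert np.all(losses >= 0.0) and np.all(losses <= 2.0)
        np.testing.assert_allclose(losses, np.asarray(giou_loss(b2, b1)),
                                   atol=1e-12)
        shift = np.array([0.13, -0.07, 0.0, 0.0])
        np.testing.assert_allclose(
            np.asarray(giou_loss(b1 + shift, b2 + shift)), losses, atol=1e-9)

    def test_degenerate_zero_size_boxes_finite(self):
        a = np.array([0.5, 0.5, 0.0, 0.0])
        b = np.array([0.6, 0.6, 0.1, 0.1])
        assert np.isfinite(float(giou_loss(a, b)))


class TestBoxLoss:
    def test_zero_iff_identical(self):
        b = np.array([0.3, 0.3, 0.1, 0.1])
        assert float(box_loss(b, b)) == pytest.approx(0.0, abs=1e-9)
        assert float(box_loss(b, b + 0.01)) > 0

    def test_l1_contribution_linear_in_lambda(self):
        b1 = np.array([0.3, 0.3, 0.1, 0.1])
        b2 = np.array([0.4, 0.3, 0.1, 0.1])
        base = float(box_loss(b1, b2, lambda_iou=0.0, lambda_l1=5.0))
        assert float(box_loss(b1, b2, lambda_iou=0.0, lambda_l1=10.0)) == \
            pytest.approx(2 * base)
        assert base == pytest.approx(5 * 0.1)


class TestHungarianMatch:
    def test_coincident_slot_wins(self):
        gt = np.array([[0.5, 0.5, 0.2, 0.2]])
        probs = np.array([[0.5, 0.5], [0.99, 0.01]])
        boxes = np.array([[0.1, 0.1, 0.1, 0.1], [0.5, 0.5, 0.2, 0.2]])
        res = hungarian_match(gt, probs, boxes)
        assert res.permutation[0] == 1

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(25):
            n = rng.integers(1, 6)
            m = rng.integers(n, 7)
            gt = np.stack([rng.uniform(0.2, 0.8, n), rng.uniform(0.2, 0.8, n),
                           rng.uniform(0.05, 0.3, n), rng.uniform(0.05, 0.3, n)],
                          axis=-1)
            logits = rng.normal(size=(m, 2))
            probs = np.exp(logits) / np.exp(logits).sum(-1, keepdims=True)
            boxes = np.stack(
                [rng.uniform(0.2, 0.8, m), rng.uniform(0.2, 0.8, m),
                 rng.uniform(0.05, 0.3, m), rng.uniform(0.05, 0.3, m)], axis=-1)
            res = hungarian_match(gt, probs, boxes)
            assert res.total_cost == pytest.approx(
                brute_force_min_cost(gt, probs, boxes))
            # injectivity over true particles
            assert len(set(res.permutation.tolist())) == m

    def test_no_particles_matches_nothing(self):
        probs = np.full((4, 2), 0.5)
        boxes = np.full((4, 4), 0.4)
        res = hungarian_match(np.zeros((0, 4)), probs, boxes)
        assert res.total_cost == 0.0
        assert res.num_true == 0

    def test_nonfinite_cost_rejected(self):
        gt = np.array([[0.5, 0.5, 0.2, 0.2]])
        probs = np.array([[np.nan, 0.5]])
        boxes = np.array([[0.5, 0.5, 0.2, 0.2]])
        with pytest.raises(ValueError, match="finite"):
            hungarian_match(gt, probs, boxes)


class TestHungarianLoss:
    def _perfect(self, n_true=3, n_slots=6):
        rng = np.random.default_rng(0)
        gt = np.stack([rng.uniform(0.3, 0.7, n_true),
                       rng.uniform(0.3, 0.7, n_true),
                       rng.uniform(0.1, 0.2, n_true),
                       rng.uniform(0.1, 0.2, n_true)], axis=-1)
        boxes = np.full((n_slots, 4), 0.5)
        boxes[:n_true] = gt
        logits = np.zeros((n_slots, 2))
        logits[:n_true, 0] = 50.0  # particle with probability ~1
        logits[n_true:, 1] = 50.0  # no-particle with probability ~1
        return gt, logits, boxes

    def test_perfect_prediction_zero_loss(self):
        gt, logits, boxes = self._perfect()
        lb = hungarian_loss(gt, logits, boxes)
        # ground truth is cast to float32 internally; a few 1e-8-scale
        # rounding residuals survive in the box terms
        assert float(lb.total) == pytest.approx(0.0, abs=1e-5)

    def test_invariant_under_slot_permutation(self, rng):
        gt, logits, boxes = self._perfect()
        ref = float(hungarian_loss(gt, logits, boxes).total)
        for _ in range(5):
            perm = rng.permutation(len(boxes))
            assert float(hungarian_loss(gt, logits[perm], boxes[perm]).total) \
                == pytest.approx(ref, abs=1e-8)  # same matching, exact value

    def test_all_empty_uniform_half_gives_downweighted_log2(self):
        n = 12
        logits = np.zeros((n, 2))  # both classes probability 0.5
        boxes = np.full((n, 4), 0.5)
        lb = hungarian_loss(np.zeros((0, 4)), logits, boxes)
        assert float(lb.total) == pytest.approx(n * 0.1 * np.log(2.0))

    def test_nonnegative_and_zero_only_at_perfection(self, rng):
        gt, logits, boxes = self._perfect()
        noisy = boxes + rng.normal(0, 0.01, boxes.shape)
        assert float(hungarian_loss(gt, logits, noisy).total) > 0

    def test_batched_loss_equals_per_image_sum(self, rng):
        from cryopick.losses import batch_hungarian_loss

        gt_list = [rng.uniform(0.2, 0.8, size=(int(rng.integers(0, 6)), 4))
                   .astype(np.float32) for _ in range(6)]
        logits = rng.normal(size=(6, 9, 2))
        boxes = rng.uniform(0.05, 0.95, size=(6, 9, 4))
        total, parts, n_boxes = batch_hungarian_loss(gt_list, logits, boxes)
        ref = sum(float(hungarian_loss(g, logits[i], boxes[i]).total)
                  for i, g in enumerate(gt_list))
        assert float(total) == pytest.approx(ref, rel=1e-6)
        assert n_boxes == sum(len(g) for g in gt_list)

    def test_gradients_finite_at_random_points(self, rng):
        gt = np.array([[0.4, 0.4, 0.15, 0.15], [0.7, 0.6, 0.1, 0.1]])
        logits = rng.normal(size=(5, 2))
        boxes = rng.uniform(0.05, 0.95, size=(5, 4))
        gl = grad(lambda L: hungarian_loss(gt, L, boxes).total)(logits)
        gb = grad(lambda B: hungarian_loss(gt, logits, B).total)(boxes)
        assert np.all(np.isfinite(gl)) and np.all(np.isfinite(gb))
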