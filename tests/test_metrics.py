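"""Precision/recall/F1 from distance-limited matching, and disk-mask Dice."""

import itertools

import numpy as np
import pytest

from cryopick.io import ParticleAnnotation, StarRecord, write_coord_table, write_star
from cryopick.metrics import dice_score, evaluate, match_picks


def _gt(centers, diameter=10.0, name="m"):
    return [ParticleAnnotation(x, y, diameter, name, particle_id=i + 1)
            for i, (x, y) in enumerate(centers)]


def brute_force_max_matching(pred, gt, tolerance):
    """Exhaustive maximum bipartite matching on the feasibility graph."""
    gt_xy = np.array([[a.center_x, a.center_y] for a in gt])
    lim = np.array([a.diameter for a in gt]) * tolerance
    pred = np.asarray(pred, float).reshape(-1, 2)
    feas = np.linalg.norm(pred[:, None] - gt_xy[None], axis=-1) <= lim[None, :]
    best = 0
    n, m = feas.shape
    for k in range(min(n, m), 0, -1):
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                if all(feas[r, c] for r, c in zip(rows, cols)):
                    return k
    return best


class TestMatchPicks:
    def test_identical_predictions_all_true_positive(self):
        gt = _gt([(10, 10), (30, 30), (50, 12)])
        tp, fp, fn, pairs = match_picks([(10, 10), (30, 30), (50, 12)], gt)
        assert (tp, fp, fn) == (3, 0, 0)
        assert len(pairs) == 3

    def test_no_predictions_all_false_negative(self):
        gt = _gt([(10, 10), (20, 20)])
        assert match_picks(np.zeros((0, 2)), gt) == (0, 0, 2, [])

    def test_partial_match_counts(self):
        gt = _gt([(10, 10), (30, 30), (50, 50), (60, 10)])
        pred = [(11, 10), (30, 31), (5, 60)]  # 2 within half-diameter
        tp, fp, fn, _ = match_picks(pred, gt, 0.5)
        assert (tp, fp, fn) == (2, 1, 2)

    def test_one_to_one_not_double_counted(self):
        gt = _gt([(10, 10)])
        tp, fp, fn, _ = match_picks([(10, 10), (11, 10)], gt, 0.5)
        assert (tp, fp, fn) == (1, 1, 0)

    def test_matches_brute_force_maximum(self, rng):
        for _ in range(15):
            n_gt = int(rng.integers(1, 7))
            n_pred = int(rng.integers(0, 8))
            gt = _gt([(float(x), float(y)) for x, y in
                      rng.uniform(5, 60, size=(n_gt, 2))], diameter=12.0)
            pred = rng.uniform(0, 64, size=(n_pred, 2))
            tp, _, _, _ = match_picks(pred, gt, 0.5)
            assert tp == brute_force_max_matching(pred, gt, 0.5)

    def test_monotonicity_of_precision_and_recall(self):
        gt = _gt([(10, 10), (30, 30), (50, 50)])
        good = [(10, 10), (30, 30)]
        tp, fp, fn, _ = match_picks(good, gt)
        p0 = tp / (tp + fp)
        tp2, fp2, fn2, _ = match_picks(good + [(60, 60)], gt)
        assert tp2 / (tp2 + fp2) <= p0  # spurious pick cannot raise precision
        tp3, _, fn3, _ = match_picks(good + [(50, 50)], gt)
        assert tp3 >= tp  # correct pick cannot lower recall
        assert fn3 <= fn

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            match_picks([(1, 1)], _gt([(1, 1)]), 0.0)


class TestDice:
    def test_identical_centers_full_overlap(self):
        gt = _gt([(20, 20), (40, 40)])
        assert dice_score([(20, 20), (40, 40)], gt, (64, 64)) == 1.0

    def test_empty_predictions_zero(self):
        assert dice_score(np.zeros((0, 2)), _gt([(20, 20)]), (64, 64)) == 0.0

    def test_one_radius_offset_matches_lens_area(self):
        # two unit-radius disks one radius apart overlap in a lens of area
        # 2 r^2 cos^-1(1/2) - (r/2) sqrt(3) r^2; Dice = lens / (pi r^2)
        d = 60.0
        r = d / 2
        gt = _gt([(100.0, 100.0)], diameter=d)
        expected = (2 * np.arccos(0.5) - np.sqrt(3) / 2) * r**2 / (np.pi * r**2)
        got = dice_score([(100.0 + r, 100.0)], gt, (200, 200))
        assert got == pytest.approx(expected, abs=0.02)  # pixelized masks


class TestEvaluate:
    def _write_fixture(self, tmp_path, jitter=0.0, drop=0, spurious=0, seed=0):
        rng = np.random.default_rng(seed)
        gt_dir = tmp_path / "gt"
        records = []
        d = 10.0
        for m in range(3):
            name = f"mic{m}"
            centers = rng.uniform(10, 246, size=(30, 2))
            anns = _gt([tuple(c) for c in centers], diameter=d, name=name)
            write_coord_table(anns, gt_dir / f"{name}.tsv")
            kept = centers[drop:] if drop else centers
            noisy = kept + rng.normal(0, jitter * d, size=kept.shape)
            for x, y in noisy:
                records.append(StarRecord(name, float(x), float(y), 0.9))
            for _ in range(spurious):
                records.append(StarRecord(
                    name, float(rng.uniform(0, 256)), float(rng.uniform(0, 256)),
                    0.5))
        star = tmp_path / "pred.star"
        write_star(records, star)
        return star, gt_dir

    def test_self_evaluation_is_perfect(self, tmp_path):
        star, gt_dir = self._write_fixture(tmp_path)
        report = evaluate(star, gt_dir, (256, 256))
        avg = report.macro_average()
        for key in ("precision", "recall", "f1", "dice"):
            assert avg[key] == pytest.approx(1.0)

    def test_report_has_average_row(self, tmp_path):
        star, gt_dir = self._write_fixture(tmp_path)
        frame = evaluate(star, gt_dir, (256, 256)).to_frame()
        assert len(frame) == 4  # 3 micrographs + Average
        assert frame.iloc[-1]["micrograph"] == "Average"

    def test_csv_serialization(self, tmp_path):
        star, gt_dir = self._write_fixture(tmp_path)
        out = tmp_path / "report.csv"
        evaluate(star, gt_dir, (256, 256), out_csv=out)
        assert out.exists()
        assert "precision" in out.read_text().splitlines()[0]

    def test_f1_harmonic_mean_identity(self, tmp_path):
        star, gt_dir = self._write_fixture(tmp_path, jitter=0.2, spurious=5,
                                           seed=3)
        report = evaluate(star, gt_dir, (256, 256))
        for row in report.per_micrograph:
            if row.precision + row.recall > 0:
                assert row.f1 == pytest.approx(
                    2 * row.precision * row.recall /
                    (row.precision + row.recall))
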