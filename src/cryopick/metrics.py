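"""Scoring picked coordinates against ground truth.

A predicted center counts as a true positive when a one-to-one matching
pairs it with a ground-truth particle at distance no greater than a
fraction of that particle's diameter (default one half — the particle
radius).  The pairing maximizes the number of such pairs (solved as a
rectangular assignment, which for 0/1 feasibility costs is a
maximum-cardinality bipartite matching).  Precision, recall and F1
follow from the TP/FP/FN counts; the Dice score is computed separately
on rendered disk masks (radius = ground-truth diameter / 2 at both the
predicted and true centers), so it is deliberately not identical to the
set-level F1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from cryopick.io import ParticleAnnotation, read_coord_table, read_star

__all__ = ["MetricsReport", "match_picks", "dice_score", "evaluate"]


@dataclass
class MicrographScore:
    name: str
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    dice: float
    undefined_precision: bool = False


@dataclass
class MetricsReport:
    per_micrograph: list[MicrographScore]
    tolerance: float

    @property
    def aggregate(self) -> dict:
        tp = sum(m.tp for m in self.per_micrograph)
        fp = sum(m.fp for m in self.per_micrograph)
        fn = sum(m.fn for m in self.per_micrograph)
        p, r, f1 = _prf(tp, fp, fn)
        return {
            "tp": tp, "fp": fp, "fn": fn,
            "precision": p, "recall": r, "f1": f1,
            "dice": float(np.mean([m.dice for m in self.per_micrograph]))
            if self.per_micrograph else 0.0,
        }

    def macro_average(self) -> dict:
        """Unweighted mean of the per-micrograph metric rows."""
        if not self.per_micrograph:
            return {"precision": 0.0, "recall": 0.0, "f1": 0.0, "dice": 0.0}
        return {
            k: float(np.mean([getattr(m, k) for m in self.per_micrograph]))
            for k in ("precision", "recall", "f1", "dice")
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "micrograph": m.name, "tp": m.tp, "fp": m.fp, "fn": m.fn,
                "precision": m.precision, "recall": m.recall, "f1": m.f1,
                "dice": m.dice, "undefined_precision": m.undefined_precision,
            }
            for m in self.per_micrograph
        ]
        avg = self.macro_average()
        rows.append({"micrograph": "Average", "tp": "", "fp": "", "fn": "",
                     **avg, "undefined_precision": ""})
        return pd.DataFrame(rows)


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def match_picks(pred_centers, gt_annotations: list[ParticleAnnotation],
                tolerance: float = 0.5):
    """(TP, FP, FN, pairs) under distance-limited one-to-one matching.

    ``tolerance`` is a fraction of each ground-truth particle's diameter.
    ``pairs`` lists (pred_index, gt_index) for the true positives.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    pred = np.asarray(pred_centers, dtype=float).reshape(-1, 2)
    n_pred, n_gt = len(pred), len(gt_annotations)
    if n_pred == 0 or n_gt == 0:
        return 0, n_pred, n_gt, []
    gt_xy = np.array([[a.center_x, a.center_y] for a in gt_annotations])
    limits = np.array([a.diameter for a in gt_annotations]) * tolerance
    dist = np.linalg.norm(pred[:, None, :] - gt_xy[None, :, :], axis=-1)
    feasible = dist <= limits[None, :]
    # 0 cost for a feasible pair, 1 otherwise: minimizing the assignment
    # cost maximizes the number of feasible (true-positive) pairs
    cost = np.where(feasible, 0.0, 1.0)
    rows, cols = linear_sum_assignment(cost)
    pairs = [(int(i), int(j)) for i, j in zip(rows, cols) if feasible[i, j]]
    tp = len(pairs)
    return tp, n_pred - tp, n_gt - tp, pairs


def dice_score(pred_centers, gt_annotations: list[ParticleAnnotation],
               image_shape) -> float:
    """Mask overlap: disks of the ground-truth radius at both center sets."""
    h, w = image_shape
    if not gt_annotations and len(pred_centers) == 0:
        return 1.0
    radius = (
        float(np.mean([a.diameter for a in gt_annotations])) / 2.0
        if gt_annotations else 1.0
    )
    yy, xx = np.mgrid[0:h, 0:w]

    def render(centers) -> np.ndarray:
        m = np.zeros((h, w), dtype=bool)
        for cx, cy in centers:
            m |= (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
        return m

    a = render(np.asarray(pred_centers, dtype=float).reshape(-1, 2))
    b = render([(g.center_x, g.center_y) for g in gt_annotations])
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def evaluate(pred_star, gt_dir, image_shape, tolerance: float = 0.5,
             out_csv=None) -> MetricsReport:
    """Score a merged star file against per-micrograph coordinate tables.

    ``gt_dir`` holds one ``<micrograph>.tsv`` center/diameter table per
    micrograph; micrographs present in the ground truth but absent from
    the star file count all their particles as false negatives.
    """
    records = read_star(pred_star)
    by_mic: dict[str, list] = {}
    for r in records:
        by_mic.setdefault(r.micrograph_name, []).append(
            (r.coordinate_x, r.coordinate_y))
    scores = []
    for table in sorted(Path(gt_dir).glob("*.tsv")):
        name = table.stem
        gt = read_coord_table(table)
        pred = np.array(by_mic.get(name, [])).reshape(-1, 2)
        tp, fp, fn, _ = match_picks(pred, gt, tolerance)
        p, r, f1 = _prf(tp, fp, fn)
        scores.append(
            MicrographScore(
                name=name, tp=tp, fp=fp, fn=fn, precision=p, recall=r, f1=f1,
                dice=dice_score(pred, gt, image_shape),
                undefined_precision=(tp + fp == 0),
            )
        )
    report = MetricsReport(per_micrograph=scores, tolerance=tolerance)
    if out_csv:
        report.to_frame().to_csv(out_csv, index=False)
    return report
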