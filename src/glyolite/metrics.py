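"""Detection evaluation: precision / recall / F1 and mAP@0.5.

Matching is greedy by descending confidence at IoU >= 0.5, one detection
per ground-truth box; average precision integrates the precision envelope
at 101 equally spaced recall points (the modern convention; the 11-point
variant is available for comparison).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import _iou_matrix

__all__ = ["ConfusionCounts", "MetricsReport", "precision_recall_f1",
           "average_precision", "map50", "evaluate_detections"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class MetricsReport:
    precision: float
    recall: float
    f1: float
    map50: float | None = None
    degenerate: bool = False

    def rounded(self, nd: int = 3) -> dict:
        d = {
            "precision": round(self.precision, nd),
            "recall": round(self.recall, nd),
            "f1": round(self.f1, nd),
        }
        if self.map50 is not None:
            d["map50"] = round(self.map50, nd)
        return d


def precision_recall_f1(counts: ConfusionCounts) -> MetricsReport:
    """P = TP/(TP+FP); R = TP/(TP+FN); F1 = 2PR/(P+R), 0 when P+R = 0."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    degenerate = tp + fp + fn == 0
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return MetricsReport(p, r, f1, degenerate=degenerate)


def _match_image(dets: np.ndarray, gts: np.ndarray, iou_thres: float):
    """Greedy confidence-ordered matching; returns per-detection TP flags."""
    tp = np.zeros(len(dets), dtype=bool)
    if len(gts) == 0 or len(dets) == 0:
        return tp
    order = np.argsort(-dets[:, 4])
    taken = np.zeros(len(gts), dtype=bool)
    ious = _iou_matrix(dets[:, :4], gts[:, 1:5])
    for i in order:
        cand = np.where((ious[i] >= iou_thres) & ~taken & (gts[:, 0] == dets[i, 5]))[0]
        if len(cand):
            j = cand[np.argmax(ious[i][cand])]
            taken[j] = True
            tp[i] = True
    return tp


def average_precision(recall: np.ndarray, precision: np.ndarray,
                      points: int = 101) -> float:
    """Precision-envelope interpolation at equally spaced recall points.

    Interpolated precision at recall r is the maximum precision attained at
    any recall >= r (zero when no operating point reaches r); AP is its mean
    over the grid, so detections exactly reproducing the ground truth score
    exactly 1.
    """
    recall = np.asarray(recall, dtype=np.float64)
    precision = np.asarray(precision, dtype=np.float64)
    envelope = np.flip(np.maximum.accumulate(np.flip(precision)))
    grid = np.linspace(0, 1, points)
    idx = np.searchsorted(recall, grid, side="left")
    vals = np.where(idx < len(recall), envelope[np.minimum(idx, len(recall) - 1)], 0.0)
    return float(vals.mean())


def map50(detections, ground_truth, iou_thres: float = 0.5,
          points: int = 101) -> float:
    """Mean AP at IoU 0.5 over classes.

    ``detections``: per-image (N, 6) arrays (x1, y1, x2, y2, score, class).
    ``ground_truth``: per-image (M, 5) arrays (class, x1, y1, x2, y2).
    """
    all_tp, all_score, all_cls = [], [], []
    n_gt_per_class = {}
    for dets, gts in zip(detections, ground_truth):
        dets = np.asarray(dets, dtype=np.float64).reshape(-1, 6)
        gts = np.asarray(gts, dtype=np.float64).reshape(-1, 5)
        for c in gts[:, 0]:
            n_gt_per_class[c] = n_gt_per_class.get(c, 0) + 1
        tp = _match_image(dets, gts, iou_thres)
        all_tp.append(tp)
        all_score.append(dets[:, 4])
        all_cls.append(dets[:, 5])
    if not n_gt_per_class:
        return 0.0
    tp = np.concatenate(all_tp) if all_tp else np.zeros(0, bool)
    score = np.concatenate(all_score) if all_score else np.zeros(0)
    cls = np.concatenate(all_cls) if all_cls else np.zeros(0)
    aps = []
    for c, n_gt in n_gt_per_class.items():
        sel = cls == c
        if not sel.any():
            aps.append(0.0)
            continue
        order = np.argsort(-score[sel])
        tpc = tp[sel][order]
        cum_tp = np.cumsum(tpc)
        cum_fp = np.cumsum(~tpc)
        recall = cum_tp / n_gt
        precision = cum_tp / np.maximum(cum_tp + cum_fp, 1e-12)
        aps.append(average_precision(recall, precision, points))
    return float(np.mean(aps))


def evaluate_detections(detections, ground_truth,
                        iou_thres: float = 0.5) -> MetricsReport:
    """Confusion counts at the detections' shipped confidences plus mAP@0.5."""
    tp = fp = n_gt = 0
    for dets, gts in zip(detections, ground_truth):
        dets = np.asarray(dets, dtype=np.float64).reshape(-1, 6)
        gts = np.asarray(gts, dtype=np.float64).reshape(-1, 5)
        flags = _match_image(dets, gts, iou_thres)
        tp += int(flags.sum())
        fp += int((~flags).sum())
        n_gt += len(gts)
    rep = precision_recall_f1(ConfusionCounts(tp, fp, n_gt - tp))
    rep.map50 = map50(detections, ground_truth, iou_thres)
    return rep
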