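"""Detection metrics: IoU, greedy matching, precision/recall, AP and mAP.

AP integrates precision over recall using the standard 101-point
interpolation of the precision envelope; mAP@0.5:0.95 averages the class
means over IoU thresholds 0.50, 0.55, ..., 0.95.  Classes without ground
truth are excluded from the class mean.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

IOU_THRESHOLDS = np.round(np.arange(0.5, 0.96, 0.05), 2)


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0


def iou(a, b) -> float:
    """Intersection-over-union of two xyxy boxes."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a[2] <= a[0] or a[3] <= a[1] or b[2] <= b[0] or b[3] <= b[1]:
        raise ValueError("degenerate box (needs x2 > x1 and y2 > y1)")
    ix = min(a[2], b[2]) - max(a[0], b[0])
    iy = min(a[3], b[3]) - max(a[1], b[1])
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = ((a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter)
    return float(inter / union)


def iou_matrix(a, b):
    """Pairwise IoU between (N,4) and (M,4) xyxy boxes."""
    a = np.asarray(a, dtype=float).reshape(-1, 4)
    b = np.asarray(b, dtype=float).reshape(-1, 4)
    ix = (np.minimum(a[:, None, 2], b[None, :, 2])
          - np.maximum(a[:, None, 0], b[None, :, 0])).clip(0)
    iy = (np.minimum(a[:, None, 3], b[None, :, 3])
          - np.maximum(a[:, None, 1], b[None, :, 1])).clip(0)
    inter = ix * iy
    area_a = ((a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1]))[:, None]
    area_b = ((b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1]))[None, :]
    return inter / np.maximum(area_a + area_b - inter, 1e-12)


def match_detections(det_boxes, det_conf, gt_boxes, iou_thr: float) -> ConfusionCounts:
    """Greedy one-to-one matching of same-class detections to ground truth.

    Detections are processed in descending confidence; each becomes a true
    positive iff its best still-unmatched ground-truth IoU reaches the
    threshold.  Unmatched ground truths are false negatives.
    """
    flags = match_flags(det_boxes, det_conf, gt_boxes, iou_thr)
    tp = int(flags.sum())
    return ConfusionCounts(tp=tp, fp=len(flags) - tp, fn=len(gt_boxes) - tp)


def match_flags(det_boxes, det_conf, gt_boxes, iou_thr: float):
    """Per-detection TP flags (confidence-descending order of the input)."""
    det_boxes = np.asarray(det_boxes, dtype=float).reshape(-1, 4)
    gt_boxes = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    order = np.argsort(-np.asarray(det_conf, dtype=float))
    flags = np.zeros(len(det_boxes), dtype=bool)
    if len(gt_boxes) == 0 or len(det_boxes) == 0:
        return flags
    mat = iou_matrix(det_boxes, gt_boxes)
    taken = np.zeros(len(gt_boxes), dtype=bool)
    for i in order:
        row = np.where(taken, -1.0, mat[i])
        j = row.argmax()
        if row[j] >= iou_thr:
            flags[i] = True
            taken[j] = True
    return flags


def precision_recall(c: ConfusionCounts):
    """(precision, recall) with the 0/0 -> 0 convention."""
    p = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    r = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    return p, r


def pr_curve(conf, tp_flags, n_gt: int):
    """Confidence-ordered cumulative (precision, recall) pairs."""
    order = np.argsort(-np.asarray(conf, dtype=float))
    tp = np.asarray(tp_flags, dtype=float)[order]
    ctp = np.cumsum(tp)
    cfp = np.cumsum(1.0 - tp)
    prec = ctp / np.maximum(ctp + cfp, 1e-12)
    rec = ctp / max(n_gt, 1)
    return prec, rec


def average_precision(conf, tp_flags, n_gt: int) -> float:
    """101-point interpolated area under the precision envelope."""
    if n_gt == 0:
        return float("nan")
    if len(conf) == 0:
        return 0.0
    prec, rec = pr_curve(conf, tp_flags, n_gt)
    # precision envelope: best precision at recall >= r
    env = np.maximum.accumulate(prec[::-1])[::-1]
    grid = np.linspace(0, 1, 101)
    interp = np.zeros_like(grid)
    for i, r in enumerate(grid):
        mask = rec >= r - 1e-12
        interp[i] = env[mask].max() if mask.any() else 0.0
    return float(interp.mean())


def map_metrics(detections, ground_truths, nc: int):
    """mAP@0.5 and mAP@0.5:0.95 over a list of images.

    ``detections``: per image ``(boxes, classes, confidences)``;
    ``ground_truths``: per image ``(boxes, classes)``.
    """
    ap = np.full((len(IOU_THRESHOLDS), nc), np.nan)
    for c in range(nc):
        n_gt = sum(int((np.asarray(g[1]) == c).sum()) for g in ground_truths)
        if n_gt == 0:
            continue
        for t, thr in enumerate(IOU_THRESHOLDS):
            confs, flags = [], []
            for (db, dc, dconf), (gb, gc) in zip(detections, ground_truths):
                db = np.asarray(db, dtype=float).reshape(-1, 4)
                dc = np.asarray(dc)
                dconf = np.asarray(dconf, dtype=float)
                gb = np.asarray(gb, dtype=float).reshape(-1, 4)
                gc = np.asarray(gc)
                sel, gsel = dc == c, gc == c
                f = match_flags(db[sel], dconf[sel], gb[gsel], thr)
                confs.append(dconf[sel])
                flags.append(f)
            conf = np.concatenate(confs) if confs else np.empty(0)
            flag = np.concatenate(flags) if flags else np.empty(0, bool)
            ap[t, c] = average_precision(conf, flag, n_gt)
    valid = ~np.isnan(ap[0])
    map50 = float(ap[0, valid].mean()) if valid.any() else 0.0
    map5095 = float(np.nanmean(ap[:, valid], axis=1).mean()) if valid.any() else 0.0
    return map50, map5095
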