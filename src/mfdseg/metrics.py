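"""Detection/segmentation evaluation: greedy matching, PR curves, AP50.

Single-class evaluation as used for canopy delineation: detections are
matched one-to-one to ground truths per image by descending confidence
(each detection takes the highest-IoU unmatched truth at or above the IoU
threshold; ties go to the lower truth index), the PR curve is swept over
confidence, AP50 integrates the all-point (continuous) interpolated curve,
and the reported precision/recall operating point is the curve's maximum-F1
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["Detection", "box_iou", "mask_iou", "match_predictions", "evaluate", "ap50"]


@dataclass
class Detection:
    """One predicted instance (pixel coordinates)."""

    box: tuple[float, float, float, float]  # x1, y1, x2, y2
    confidence: float
    class_id: int = 0
    mask: np.ndarray | None = None  # bool, image- or prototype-resolution

    def __post_init__(self):
        x1, y1, x2, y2 = self.box
        if not (x2 > x1 and y2 > y1):
            raise ValueError(f"degenerate box {self.box}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


def box_iou(a, b) -> float:
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Pixel-set IoU of two boolean masks (same shape)."""
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return float(inter) / union if union else 0.0


def _pair_iou(det, gt, mode: str) -> float:
    if mode == "box":
        return box_iou(det.box, gt.box_pixels() if hasattr(gt, "box_pixels") else gt.box)
    if det.mask is None:
        raise ValueError("mask-mode matching needs detection masks")
    return mask_iou(det.mask, gt.mask)


def match_predictions(dets, gts, iou_threshold: float = 0.5, mode: str = "box"):
    """Greedy one-to-one matching within a single image.

    Returns a list of ``(det_index, gt_index, iou)`` triples, in the order
    detections were matched (descending confidence; stable for equal
    confidence).
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    taken = set()
    matches = []
    for di in order:
        best_iou, best_gi = 0.0, -1
        for gi, gt in enumerate(gts):
            if gi in taken:
                continue
            iou = _pair_iou(dets[di], gt, mode)
            # strictly-greater keeps ties on the lower ground-truth index
            if iou >= iou_threshold and iou > best_iou:
                best_iou, best_gi = iou, gi
        if best_gi >= 0:
            taken.add(best_gi)
            matches.append((di, best_gi, best_iou))
    return matches


def ap50(tp_flags: np.ndarray, confidences: np.ndarray, n_gt: int) -> float:
    """All-point interpolated average precision from per-detection TP flags."""
    if n_gt == 0 or len(tp_flags) == 0:
        return 0.0
    order = np.argsort(-confidences, kind="stable")
    tp = np.asarray(tp_flags, dtype=float)[order]
    fp = 1.0 - tp
    ctp, cfp = np.cumsum(tp), np.cumsum(fp)
    recall = ctp / n_gt
    precision = ctp / (ctp + cfp)
    # precision envelope, integrated over every recall step
    r = np.concatenate(([0.0], recall, [recall[-1]]))
    p = np.concatenate(([1.0], precision, [0.0]))
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    idx = np.nonzero(r[1:] != r[:-1])[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


def evaluate(dets_per_image, gts_per_image, iou_threshold: float = 0.5,
             mode: str = "box"):
    """Dataset-level (precision, recall, AP50) at the best-F1 operating point.

    ``dets_per_image`` and ``gts_per_image`` are parallel lists over images.
    With no ground truths and no detections the metrics are undefined and
    reported as zero with a warning.
    """
    n_gt = sum(len(g) for g in gts_per_image)
    confs, tps = [], []
    for dets, gts in zip(dets_per_image, gts_per_image):
        matched = {di for di, _, _ in match_predictions(dets, gts, iou_threshold, mode)}
        for di, d in enumerate(dets):
            confs.append(d.confidence)
            tps.append(1.0 if di in matched else 0.0)
    confs = np.asarray(confs)
    tps = np.asarray(tps)
    if n_gt == 0 and len(confs) == 0:
        warnings.warn("no ground truths and no detections: metrics undefined, reporting 0")
        return 0.0, 0.0, 0.0
    if len(confs) == 0:
        return 0.0, 0.0, 0.0
    ap = ap50(tps, confs, n_gt)
    order = np.argsort(-confs, kind="stable")
    tp_sorted = tps[order]
    ctp = np.cumsum(tp_sorted)
    npred = np.arange(1, len(tp_sorted) + 1)
    precision = ctp / npred
    recall = ctp / max(n_gt, 1)
    f1 = 2 * precision * recall / np.maximum(precision + recall, 1e-12)
    best = int(np.argmax(f1))
    return float(precision[best]), float(recall[best]), ap
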