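"""Segmentation and measurement accuracy metrics.

Pixel overlap between a predicted and a reference mask is scored with the
Dice coefficient; detection of individual nuclei with a one-to-one greedy
IoU matching yielding F1, recall and precision; measurement accuracy of
image-level parameters with the root-mean-squared error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nucleomorph.core_io import LabelMask

__all__ = ["DetectionMatch", "dice", "match_instances", "parameter_rmse"]


@dataclass
class DetectionMatch:
    tp: int
    fp: int
    fn: int
    iou_min: float
    precision_defined: bool = True

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 0.0


def _foreground(mask: LabelMask | np.ndarray) -> np.ndarray:
    arr = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    return arr > 0


def dice(mask_a: LabelMask | np.ndarray, mask_b: LabelMask | np.ndarray) -> float:
    """Dice score 2|A∩B| / (|A|+|B|) of the two foregrounds.

    Instance labels are ignored (the union of instances is compared).
    Two empty masks score 1 by convention.
    """
    a, b = _foreground(mask_a), _foreground(mask_b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


def _pairwise_iou(pred: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """IoU for every overlapping (pred, gt) instance pair via a contingency table."""
    pred_ids, pred_inv = np.unique(pred, return_inverse=True)
    gt_ids, gt_inv = np.unique(gt, return_inverse=True)
    table = np.zeros((pred_ids.size, gt_ids.size), dtype=np.int64)
    np.add.at(table, (pred_inv.ravel(), gt_inv.ravel()), 1)
    pred_areas = table.sum(axis=1)
    gt_areas = table.sum(axis=0)
    ious = np.zeros_like(table, dtype=float)
    inter = table.astype(float)
    union = pred_areas[:, None] + gt_areas[None, :] - inter
    np.divide(inter, union, out=ious, where=union > 0)
    # background rows/columns do not participate in matching
    if pred_ids.size and pred_ids[0] == 0:
        ious[0, :] = 0
    if gt_ids.size and gt_ids[0] == 0:
        ious[:, 0] = 0
    return ious, pred_ids, gt_ids


def match_instances(
    pred: LabelMask | np.ndarray,
    gt: LabelMask | np.ndarray,
    iou_min: float = 0.5,
) -> DetectionMatch:
    """Greedy one-to-one instance matching by descending IoU.

    Pairs with IoU >= ``iou_min`` are accepted in order of decreasing IoU,
    each instance participating at most once; accepted pairs are true
    positives, unmatched predictions false positives, unmatched reference
    instances false negatives.  With no predictions at all, precision is
    reported as 0 and flagged undefined.
    """
    if not 0 < iou_min <= 1:
        raise ValueError("iou_min must be in (0, 1]")
    p = pred.labels if isinstance(pred, LabelMask) else np.asarray(pred)
    g = gt.labels if isinstance(gt, LabelMask) else np.asarray(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    ious, pred_ids, gt_ids = _pairwise_iou(p, g)
    n_pred = int((pred_ids > 0).sum())
    n_gt = int((gt_ids > 0).sum())

    order = np.argsort(ious, axis=None)[::-1]
    used_p: set[int] = set()
    used_g: set[int] = set()
    tp = 0
    for flat in order:
        i, j = np.unravel_index(flat, ious.shape)
        if ious[i, j] < iou_min:
            break
        if i in used_p or j in used_g:
            continue
        used_p.add(int(i))
        used_g.add(int(j))
        tp += 1
    return DetectionMatch(
        tp=tp,
        fp=n_pred - tp,
        fn=n_gt - tp,
        iou_min=iou_min,
        precision_defined=n_pred > 0,
    )


def parameter_rmse(
    estimates: np.ndarray | list, truth: np.ndarray | list
) -> tuple[float, int]:
    """Root-mean-squared error of paired image-level parameter values.

    Pairs with a missing value on either side are skipped; the number of
    valid pairs is returned alongside.  No valid pair at all is an error.
    """
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("estimates and truth must have the same length")
    valid = ~(np.isnan(est) | np.isnan(tru))
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no valid pairs")
    diff = est[valid] - tru[valid]
    return float(np.sqrt(np.mean(diff**2))), n
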