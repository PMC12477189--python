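"""Detection-quality metrics: precision, recall, AP/mAP, confusion matrix.

Matching is the standard greedy scheme: predictions in confidence-descending
order claim the highest-IoU unmatched ground-truth box of the same class
with IoU at or above the threshold.  TP counts the correct matches, FP the
unmatched predictions, FN the unmatched ground truths; P = TP/(TP+FP),
R = TP/(TP+FN).  AP integrates the precision-recall curve with all-points
interpolation (the precision envelope is made non-increasing and integrated
over recall), and mAP averages AP over classes - at IoU 0.5 for mAP50 and
over IoU thresholds 0.50:0.05:0.95 for mAP50-95.

The confusion matrix uses class-agnostic matching so that a leaf predicted
as a petiole is attributed to the [leaf][petiole] cell; unmatched ground
truths and predictions go to a background row/column.

IoU is computed in normalized coordinates: anisotropic scaling multiplies
all areas by the same factor, so the value is identical in pixel space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .annotations import NormalizedBox, PixelBox
from .errors import ConfigError

IOU_THRESHOLDS_50_95 = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))

#: One evaluated image: (predictions with confidences, ground truths).
ImagePair = tuple[Sequence[NormalizedBox], Sequence[NormalizedBox]]


def iou(a: PixelBox, b: PixelBox) -> float:
    """Intersection-over-union of two pixel boxes."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def _iou_norm(a: NormalizedBox, b: NormalizedBox) -> float:
    ix = max(0.0, min(a.cx + a.w / 2, b.cx + b.w / 2) - max(a.cx - a.w / 2, b.cx - b.w / 2))
    iy = max(0.0, min(a.cy + a.h / 2, b.cy + b.h / 2) - max(a.cy - a.h / 2, b.cy - b.h / 2))
    inter = ix * iy
    union = a.w * a.h + b.w * b.h - inter
    return inter / union if union > 0 else 0.0


@dataclass
class MatchResult:
    """Outcome of greedy prediction/ground-truth matching on one image.

    ``order`` lists prediction indices in evaluation (confidence-descending)
    order, ``tp`` flags each ordered prediction, ``matched_gt`` gives the
    claimed ground-truth index (or None), and ``gt_matched`` flags each
    ground truth.
    """

    order: list[int]
    tp: np.ndarray
    matched_gt: list[int | None]
    gt_matched: np.ndarray
    confidences: np.ndarray

    @property
    def n_tp(self) -> int:
        return int(self.tp.sum())

    @property
    def n_fp(self) -> int:
        return int(len(self.tp) - self.tp.sum())

    @property
    def n_fn(self) -> int:
        return int(len(self.gt_matched) - self.gt_matched.sum())


def match_detections(
    preds: Sequence[NormalizedBox],
    gts: Sequence[NormalizedBox],
    iou_threshold: float = 0.5,
    per_class: bool = True,
) -> MatchResult:
    """Greedily match predictions to ground truths on one image.

    Predictions are visited in confidence-descending order (ties broken by
    input order, boxes without confidence treated as confidence 1); each
    claims the unmatched ground truth with the highest IoU >= threshold
    (ties by lower ground-truth index).  With ``per_class`` matching is
    restricted to same-class pairs; class-agnostic matching feeds the
    confusion matrix.
    """
    confs = np.array([1.0 if p.confidence is None else p.confidence for p in preds])
    order = list(np.argsort(-confs, kind="stable"))
    gt_matched = np.zeros(len(gts), dtype=bool)
    tp = np.zeros(len(preds), dtype=bool)
    matched_gt: list[int | None] = []
    for rank, pi in enumerate(order):
        p = preds[pi]
        best_j, best_iou = None, -1.0
        for j, g in enumerate(gts):
            if gt_matched[j]:
                continue
            if per_class and g.class_id != p.class_id:
                continue
            v = _iou_norm(p, g)
            # strict > keeps the lower ground-truth index on IoU ties
            if v >= iou_threshold and v > best_iou:
                best_j, best_iou = j, v
        if best_j is not None:
            gt_matched[best_j] = True
            tp[rank] = True
        matched_gt.append(best_j)
    return MatchResult(
        order=order,
        tp=tp,
        matched_gt=matched_gt,
        gt_matched=gt_matched,
        confidences=confs[order],
    )


def precision_recall(match: MatchResult) -> tuple[float, float]:
    """Overall precision and recall of a match (0 when the denominator is 0)."""
    tp, fp, fn = match.n_tp, match.n_fp, match.n_fn
    p = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    r = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    return p, r


@dataclass
class PRData:
    """Cumulative precision-recall arrays (confidence-descending) and their AP."""

    precision: np.ndarray
    recall: np.ndarray
    ap: float


def average_precision(tp_flags: np.ndarray, n_gt: int) -> PRData:
    """All-points interpolated AP from ordered TP flags and the GT count.

    ``tp_flags`` must already be in global confidence-descending order.
    The precision envelope is made non-increasing from the right, then
    integrated over the recall steps.
    """
    tp_flags = np.asarray(tp_flags, dtype=float)
    if n_gt == 0:
        return PRData(np.array([]), np.array([]), ap=0.0)
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(1.0 - tp_flags)
    denom = tp_cum + fp_cum
    precision = np.divide(tp_cum, denom, out=np.zeros_like(tp_cum), where=denom > 0)
    recall = tp_cum / n_gt

    # envelope + step integration
    mrec = np.concatenate(([0.0], recall, [recall[-1] if len(recall) else 0.0]))
    mpre = np.concatenate(([0.0], precision, [0.0]))
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    ap = float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))
    return PRData(precision=precision, recall=recall, ap=ap)


def _class_ap(pairs: Sequence[ImagePair], class_id: int, iou_threshold: float) -> PRData | None:
    """AP for one class at one IoU threshold over a set of images.

    Returns None when the class has no ground truth anywhere (excluded from
    mAP, matching common evaluator behavior).
    """
    confs: list[float] = []
    flags: list[bool] = []
    n_gt = 0
    for preds, gts in pairs:
        cls_preds = [p for p in preds if p.class_id == class_id]
        cls_gts = [g for g in gts if g.class_id == class_id]
        n_gt += len(cls_gts)
        m = match_detections(cls_preds, cls_gts, iou_threshold, per_class=True)
        confs.extend(m.confidences)
        flags.extend(m.tp)
    if n_gt == 0:
        return None
    order = np.argsort(-np.asarray(confs), kind="stable")
    return average_precision(np.asarray(flags)[order], n_gt)


@dataclass
class MeanAPResult:
    per_class_ap50: dict[int, float]
    map50: float
    map50_95: float


def mean_ap(
    pairs: Sequence[ImagePair],
    class_ids: Sequence[int] | None = None,
    thresholds: Sequence[float] = IOU_THRESHOLDS_50_95,
) -> MeanAPResult:
    """mAP50 and mAP50-95 over a set of evaluated images."""
    if class_ids is None:
        class_ids = sorted({g.class_id for _, gts in pairs for g in gts})
    if not class_ids:
        raise ConfigError("no classes to evaluate")
    ap50: dict[int, float] = {}
    ap_all: list[float] = []
    for cid in class_ids:
        per_thr = []
        for thr in thresholds:
            pr = _class_ap(pairs, cid, thr)
            if pr is None:
                per_thr = None
                break
            per_thr.append(pr.ap)
        if per_thr is None:
            continue
        ap50[cid] = per_thr[0]
        ap_all.append(float(np.mean(per_thr)))
    if not ap50:
        raise ConfigError("no evaluated class has ground truth")
    return MeanAPResult(
        per_class_ap50=ap50,
        map50=float(np.mean(list(ap50.values()))),
        map50_95=float(np.mean(ap_all)),
    )


def confusion_matrix(
    pairs: Sequence[ImagePair],
    class_ids: Sequence[int],
    iou_threshold: float = 0.45,
    confidence_threshold: float = 0.25,
    normalize: bool = False,
) -> np.ndarray:
    """Background-augmented confusion matrix over classes.

    Rows index the true class (plus a final background row), columns the
    predicted class (plus background).  Matching is class-agnostic: matched
    pairs increment [gt_class][pred_class]; unmatched ground truths fall in
    the background column, unmatched predictions in the background row.
    With ``normalize`` each nonzero row is scaled to sum to 1.
    """
    k = len(class_ids)
    index = {cid: i for i, cid in enumerate(class_ids)}
    mat = np.zeros((k + 1, k + 1), dtype=float)
    for preds, gts in pairs:
        kept = [p for p in preds if (p.confidence is None or p.confidence >= confidence_threshold)]
        m = match_detections(kept, gts, iou_threshold, per_class=False)
        for rank, pi in enumerate(m.order):
            gj = m.matched_gt[rank]
            if gj is None:
                mat[k, index[kept[pi].class_id]] += 1
            else:
                mat[index[gts[gj].class_id], index[kept[pi].class_id]] += 1
        for j, g in enumerate(gts):
            if not m.gt_matched[j]:
                mat[index[g.class_id], k] += 1
    if normalize:
        sums = mat.sum(axis=1, keepdims=True)
        mat = np.divide(mat, sums, out=np.zeros_like(mat), where=sums > 0)
    return mat


def conv_flops(c_in: int, c_out: int, k: int, h_out: int, w_out: int) -> int:
    """FLOPs of one convolution layer: 2 * C_in * C_out * K^2 * H_out * W_out.

    The factor of 2 counts the multiply and the add of each
    multiply-accumulate.
    """
    args = (c_in, c_out, k, h_out, w_out)
    if any((not isinstance(a, (int, np.integer))) or a <= 0 for a in args):
        raise ConfigError(f"all arguments must be positive integers: {args}")
    return 2 * c_in * c_out * k * k * h_out * w_out
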