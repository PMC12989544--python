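"""Inner-IoU box geometry and detection-evaluation math.

Inner-IoU computes intersection-over-union not on the boxes themselves but on
"inner" boxes obtained by shrinking ground-truth and predicted boxes about
their centers by a ratio ``r`` (r < 1 shrinks, r = 1 recovers plain IoU,
r > 1 expands). Because the shrunk boxes overlap only when the originals are
well aligned, it is a stricter localization criterion for small targets such
as tea buds.

Also provided: precision/recall from detection counts, average precision as
the discrete sum over a PR curve, and a greedy score-ordered matcher for
CSV detection files.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidBoxError, InvalidCurveError, UndefinedMetricError

__all__ = [
    "BoundingBox", "InnerBox", "DetectionCounts", "PRCurve",
    "inner_box", "inner_iou", "standard_iou",
    "precision_recall", "average_precision",
    "match_detections", "evaluate_detections",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box given by center (xc, yc) and positive size (w, h).

    Image convention: y grows downward, so "top" is the smaller y.
    Coordinates are continuous (no pixel rounding).
    """

    xc: float
    yc: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise InvalidBoxError(f"box width/height must be positive, got w={self.w}, h={self.h}")


@dataclass(frozen=True)
class InnerBox:
    """Edge representation (left, right, top, bottom) of a shrunk box."""

    bl: float
    br: float
    bt: float
    bb: float


@dataclass(frozen=True)
class DetectionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("detection counts must be non-negative")


def inner_box(box: BoundingBox, r: float) -> InnerBox:
    """Shrink (or expand) a box about its center by ratio ``r``."""
    if r <= 0:
        raise InvalidBoxError(f"ratio must be positive, got {r}")
    hw, hh = box.w * r / 2.0, box.h * r / 2.0
    return InnerBox(bl=box.xc - hw, br=box.xc + hw, bt=box.yc - hh, bb=box.yc + hh)


def inner_iou(gt: BoundingBox, pred: BoundingBox, r: float) -> float:
    """IoU of the ratio-``r`` inner boxes of ``gt`` and ``pred``.

    Each linear overlap extent is clamped below at zero so disjoint inner
    boxes give an intersection of 0 (and the result stays in [0, 1]).
    """
    g, p = inner_box(gt, r), inner_box(pred, r)
    dx = max(0.0, min(g.br, p.br) - max(g.bl, p.bl))
    dy = max(0.0, min(g.bb, p.bb) - max(g.bt, p.bt))
    inter = dx * dy
    # the inner areas w*h*r^2 are computed from the same edge differences as
    # the intersection, so identical boxes give exactly 1
    union = (g.br - g.bl) * (g.bb - g.bt) + (p.br - p.bl) * (p.bb - p.bt) - inter
    return min(1.0, inter / union)


def standard_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Classic intersection-over-union of two axis-aligned boxes."""
    return inner_iou(a, b, r=1.0)


def precision_recall(c: DetectionCounts) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); zero denominators are undefined."""
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: tp + fp == 0")
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("recall undefined: tp + fn == 0")
    return c.tp / (c.tp + c.fp), c.tp / (c.tp + c.fn)


def average_precision(curve: Sequence[tuple[float, float]],
                      interpolated: bool = False) -> float:
    """Discrete average precision over a (recall, precision) curve.

    AP = sum_i P(R_i) * (R_i - R_{i-1}) with R_0 = 0. With ``interpolated``
    the precision at each recall is replaced by the running maximum of
    precision at that recall or higher (the all-point interpolation used by
    mainstream detector tooling) before summing.
    """
    if len(curve) == 0:
        raise InvalidCurveError("empty PR curve")
    rec = np.asarray([r for r, _ in curve], dtype=float)
    prec = np.asarray([p for _, p in curve], dtype=float)
    if np.any(np.diff(rec) < 0):
        raise InvalidCurveError("recalls must be non-decreasing")
    if interpolated:
        prec = np.maximum.accumulate(prec[::-1])[::-1]
    deltas = np.diff(np.concatenate([[0.0], rec]))
    return float(np.sum(prec * deltas))


def match_detections(pred: Iterable[tuple[BoundingBox, float]],
                     gt: Sequence[BoundingBox],
                     iou_threshold: float = 0.5,
                     r: float = 1.0) -> DetectionCounts:
    """Greedy one-to-one matching of predictions to ground truth.

    Predictions are taken in decreasing score order; each claims the
    unmatched ground-truth box of highest inner-IoU, provided it reaches
    ``iou_threshold``. Remaining predictions are FP, remaining GT are FN.
    """
    ordered = sorted(pred, key=lambda bs: -bs[1])
    taken = np.zeros(len(gt), dtype=bool)
    tp = 0
    for box, _ in ordered:
        best_j, best_iou = -1, iou_threshold
        for j, g in enumerate(gt):
            if taken[j]:
                continue
            iou = inner_iou(g, box, r)
            if iou >= best_iou:
                best_j, best_iou = j, iou
        if best_j >= 0:
            taken[best_j] = True
            tp += 1
    return DetectionCounts(tp=tp, fp=len(ordered) - tp, fn=int((~taken).sum()))


def evaluate_detections(pred_df: pd.DataFrame, gt_df: pd.DataFrame,
                        iou_threshold: float = 0.5, r: float = 1.0) -> dict:
    """Evaluate CSV-style detection tables (per-image greedy matching).

    ``pred_df`` columns: image_id, xc, yc, w, h, score.
    ``gt_df`` columns: image_id, xc, yc, w, h.
    Returns precision, recall, ap and the pooled counts. The PR curve is
    built by sweeping the score threshold over the pooled, score-sorted
    predictions with per-image one-to-one matching.
    """
    gt_boxes = {
        img: [BoundingBox(*row) for row in grp[["xc", "yc", "w", "h"]].to_numpy()]
        for img, grp in gt_df.groupby("image_id")
    }
    n_gt = sum(len(v) for v in gt_boxes.values())
    preds = pred_df.sort_values("score", ascending=False, kind="stable")

    taken: dict[object, np.ndarray] = {k: np.zeros(len(v), dtype=bool) for k, v in gt_boxes.items()}
    is_tp = []
    for _, row in preds.iterrows():
        img = row["image_id"]
        box = BoundingBox(row["xc"], row["yc"], row["w"], row["h"])
        gts = gt_boxes.get(img, [])
        best_j, best_iou = -1, iou_threshold
        for j, g in enumerate(gts):
            if taken[img][j]:
                continue
            iou = inner_iou(g, box, r)
            if iou >= best_iou:
                best_j, best_iou = j, iou
        if best_j >= 0:
            taken[img][best_j] = True
            is_tp.append(True)
        else:
            is_tp.append(False)

    tp_cum = np.cumsum(is_tp) if is_tp else np.zeros(0)
    n_pred = len(is_tp)
    counts = DetectionCounts(tp=int(tp_cum[-1]) if n_pred else 0,
                             fp=n_pred - (int(tp_cum[-1]) if n_pred else 0),
                             fn=n_gt - (int(tp_cum[-1]) if n_pred else 0))
    if n_pred and n_gt:
        recalls = tp_cum / n_gt
        precisions = tp_cum / np.arange(1, n_pred + 1)
        ap = average_precision(list(zip(recalls, precisions)))
        p, rcl = precision_recall(counts)
    else:
        ap, p, rcl = 0.0, float("nan"), float("nan")
    return {"precision": p, "recall": rcl, "ap": ap, "map": ap, "counts": counts}
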