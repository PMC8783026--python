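"""Detection-accuracy scoring of predicted versus true defect sets.

True and predicted defect positions are compared through their equalised
50 nm x 50 nm bounding boxes.  Each true box is paired with its closest
prediction (greedy one-to-one assignment by ascending center distance); a pair
whose intersection-over-union exceeds the IoU threshold (0.5 by default)
counts as a true positive.  Unpaired or poorly-overlapping true defects are
false negatives, surplus predictions are false positives.  The counts are
summarised by precision, recall, F1 and the density ratio
``Q_N = N_def(pred) / N_def(true)``.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.spatial.distance import cdist

from .defect_sets import BoundingBox, DefectSet, defect_density
from .exceptions import GeometryError

DEFAULT_IOU_THRESHOLD = 0.5


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union (Jaccard index) of two rectangles, in [0, 1]."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


@dataclasses.dataclass(frozen=True)
class MatchResult:
    """One-to-one pairing of true and predicted defects.

    ``pairs`` holds (true index, predicted index, IoU) for every assigned pair,
    including pairs whose IoU fell at or below the threshold (those do not
    count as true positives but still consume both indices).
    """

    pairs: tuple[tuple[int, int, float], ...]
    tp: int
    fp: int
    fn: int
    iou_threshold: float = DEFAULT_IOU_THRESHOLD


@dataclasses.dataclass(frozen=True)
class AccuracyMetrics:
    precision: float
    recall: float
    f1: float
    q_n: float


def match_defects(
    true_set: DefectSet,
    pred_set: DefectSet,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> MatchResult:
    """Greedily assign predictions to true defects by ascending center distance.

    Assignment is one-to-one: each true defect and each prediction is consumed
    by at most one pair.  Candidate pairs are visited in order of increasing
    Euclidean center distance (ties broken by lower true, then lower predicted
    index).  A pair is a true positive only if its bounding-box IoU is strictly
    above ``iou_threshold``.
    """
    if not (
        np.isclose(true_set.field_width, pred_set.field_width)
        and np.isclose(true_set.field_height, pred_set.field_height)
    ):
        raise GeometryError("true and predicted sets are on different fields")
    n_true, n_pred = len(true_set), len(pred_set)
    if n_true == 0 or n_pred == 0:
        return MatchResult((), 0, n_pred, n_true, iou_threshold)

    dist = cdist(true_set.coordinates, pred_set.coordinates)
    order = np.lexsort(
        (
            np.tile(np.arange(n_pred), n_true),
            np.repeat(np.arange(n_true), n_pred),
            dist.ravel(),
        )
    )
    true_used = np.zeros(n_true, bool)
    pred_used = np.zeros(n_pred, bool)
    pairs: list[tuple[int, int, float]] = []
    tp = 0
    for flat in order:
        ti, pi = divmod(int(flat), n_pred)
        if true_used[ti] or pred_used[pi]:
            continue
        true_used[ti] = pred_used[pi] = True
        val = iou(true_set.defects[ti].bounding_box, pred_set.defects[pi].bounding_box)
        pairs.append((ti, pi, val))
        if val > iou_threshold:
            tp += 1
        if true_used.all() or pred_used.all():
            break
    return MatchResult(
        tuple(pairs),
        tp=tp,
        fp=n_pred - tp,
        fn=n_true - tp,
        iou_threshold=iou_threshold,
    )


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def accuracy_metrics(
    match: MatchResult,
    true_set: DefectSet,
    pred_set: DefectSet,
) -> AccuracyMetrics:
    """Precision, recall, F1 and density ratio Q_N from a match result.

    Degenerate denominators (empty prediction or true set) yield NaN for the
    affected ratios, with a warning.
    """
    tp, fp, fn = match.tp, match.fp, match.fn
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        warnings.warn("empty prediction set: precision undefined", stacklevel=2)
        precision = float("nan")
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        warnings.warn("empty true set: recall undefined", stacklevel=2)
        recall = float("nan")
    f1 = f1_score(precision, recall) if np.isfinite(precision) and np.isfinite(recall) else float("nan")
    if len(true_set) > 0:
        q_n = defect_density(pred_set) / defect_density(true_set)
    else:
        q_n = float("nan")
    return AccuracyMetrics(precision=precision, recall=recall, f1=f1, q_n=q_n)


def evaluate(
    true_set: DefectSet,
    pred_set: DefectSet,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> tuple[MatchResult, AccuracyMetrics]:
    """Convenience wrapper: match then score."""
    match = match_defects(true_set, pred_set, iou_threshold)
    return match, accuracy_metrics(match, true_set, pred_set)
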