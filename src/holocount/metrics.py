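"""Segmentation and counting evaluation metrics.

Pixel metrics (sensitivity, accuracy, Dice) come from the pixelwise confusion
counts; boundary metrics are the Hausdorff distance and its 95th-percentile
variant between the object boundaries of prediction and truth; cell-level
counting is scored with a centroid matching rule: a predicted component is
"correct" when its (rounded) centroid lies inside a ground-truth cell that no
other predicted component has claimed yet, otherwise it is "over-counted";
ground-truth cells left unclaimed are "missed".
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist

from . import counting

__all__ = [
    "ConfusionCounts",
    "CountReport",
    "confusion",
    "sensitivity",
    "accuracy",
    "dsc",
    "boundary_points",
    "hausdorff",
    "hausdorff95",
    "match_cells",
    "throughput",
    "evaluate_image",
    "evaluate_set",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class CountReport:
    """Cell-level counting bookkeeping; gt_total = correct + missed."""

    correct: int
    over: int
    missed: int
    gt_total: int


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise TP/FP/TN/FN between two same-sized binary masks."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"prediction shape {pred.shape} != truth shape {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); defined as 1.0 when the truth has no foreground."""
    if c.tp + c.fn == 0:
        return 1.0
    return c.tp / (c.tp + c.fn)


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / N."""
    return (c.tp + c.tn) / c.total


def dsc(c: ConfusionCounts) -> float:
    """Dice similarity 2TP / (2TP + FP + FN); 1.0 when both masks are empty."""
    den = 2 * c.tp + c.fp + c.fn
    if den == 0:
        return 1.0
    return 2 * c.tp / den


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """(K, 2) row/col coordinates of foreground pixels with at least one
    background 4-neighbour (pixels on the image frame count as boundary)."""
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return np.argwhere(mask & ~eroded)


def _directed_distances(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """min-over-y Euclidean distance for every point of x."""
    return cdist(x, y).min(axis=1)


def _hausdorff_pair(
    pred_mask: np.ndarray, truth_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray] | float:
    x = boundary_points(pred_mask)
    y = boundary_points(truth_mask)
    if len(x) == 0 and len(y) == 0:
        return 0.0
    if len(x) == 0 or len(y) == 0:
        h, w = np.asarray(pred_mask).shape
        warnings.warn(
            "one mask has no boundary; returning the image-diagonal sentinel",
            RuntimeWarning,
            stacklevel=3,
        )
        return float(np.hypot(h, w))
    return _directed_distances(x, y), _directed_distances(y, x)


def hausdorff(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    """Symmetric Hausdorff distance between the two boundary point sets, in
    pixels: max(hd(X,Y), hd(Y,X)) with hd the directed max-min distance."""
    r = _hausdorff_pair(pred_mask, truth_mask)
    if isinstance(r, float):
        return r
    dxy, dyx = r
    return float(max(dxy.max(), dyx.max()))


def hausdorff95(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    """95th-percentile Hausdorff distance: the max of the two directed
    95th-percentile distances; more robust to single-pixel outliers."""
    r = _hausdorff_pair(pred_mask, truth_mask)
    if isinstance(r, float):
        return r
    dxy, dyx = r
    return float(max(np.percentile(dxy, 95), np.percentile(dyx, 95)))


def _round_half_up(v: float) -> int:
    return int(np.floor(v + 0.5))


def match_cells(pred_labels: np.ndarray, truth_labels: np.ndarray) -> CountReport:
    """Centroid matching rule between post-processed label maps.

    Predicted components are visited in descending area (ties: lower label)
    so the largest claimant of a truth cell is the one counted correct.  The
    centroid is the mean pixel coordinate rounded half-up; a concave
    component's centroid may fall outside the component and is tested as-is.
    """
    pred_labels = np.asarray(pred_labels)
    truth_labels = np.asarray(truth_labels)
    if pred_labels.shape != truth_labels.shape:
        raise ValueError("label maps must have the same shape")
    n_pred = int(pred_labels.max(initial=0))
    gt_total = int(truth_labels.max(initial=0))
    correct = over = 0
    if n_pred:
        areas = np.bincount(pred_labels.ravel(), minlength=n_pred + 1)
        order = sorted(range(1, n_pred + 1), key=lambda lab: (-areas[lab], lab))
        centroids = ndimage.center_of_mass(
            np.ones_like(pred_labels), pred_labels, order
        )
        claimed: set[int] = set()
        for (cy, cx) in centroids:
            r, c = _round_half_up(cy), _round_half_up(cx)
            hit = 0
            if 0 <= r < truth_labels.shape[0] and 0 <= c < truth_labels.shape[1]:
                hit = int(truth_labels[r, c])
            if hit > 0 and hit not in claimed:
                claimed.add(hit)
                correct += 1
            else:
                over += 1
    return CountReport(
        correct=correct, over=over, missed=gt_total - correct, gt_total=gt_total
    )


def throughput(total_cells_counted: int, elapsed: float) -> float:
    """Counted cells per second (hardware-dependent; reported only)."""
    if elapsed <= 0:
        raise ValueError("elapsed time must be positive")
    return total_cells_counted / elapsed


def evaluate_image(
    prob: np.ndarray,
    truth_mask: np.ndarray,
    post_cfg: counting.PostprocessConfig = counting.PostprocessConfig(),
) -> dict:
    """All metrics for one probability map / truth mask pair.

    Pixel and boundary metrics compare the thresholded prediction with the
    raw truth; the morphological opening and border exclusion belong to the
    counting chain only, which is applied to the prediction (full chain) and
    to the truth (same border/small-component exclusion) for a fair count.
    """
    truth_mask = np.asarray(truth_mask, dtype=bool)
    pred_mask = counting.binarize(prob, post_cfg.threshold)
    c = confusion(pred_mask, truth_mask)
    count, pred_labels = counting.count_from_probability(prob, post_cfg)
    truth_labels = counting.postprocess_truth(truth_mask, post_cfg)
    report = match_cells(pred_labels, truth_labels)
    return {
        "dsc": dsc(c),
        "sensitivity": sensitivity(c),
        "accuracy": accuracy(c),
        "hd": hausdorff(pred_mask, truth_mask),
        "hd95": hausdorff95(pred_mask, truth_mask),
        "count": count,
        "correct": report.correct,
        "over": report.over,
        "missed": report.missed,
        "gt_total": report.gt_total,
    }


def evaluate_set(
    probs: list[np.ndarray],
    truth_masks: list[np.ndarray],
    post_cfg: counting.PostprocessConfig = counting.PostprocessConfig(),
    elapsed: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-image metric table plus mean/std summary over the set.

    When ``elapsed`` (seconds spent producing the predictions) is given, the
    summary also reports throughput in cells/s.
    """
    if len(probs) != len(truth_masks):
        raise ValueError("need one truth mask per prediction")
    t0 = time.perf_counter()
    rows = [
        evaluate_image(p, t, post_cfg) for p, t in zip(probs, truth_masks)
    ]
    table = pd.DataFrame(rows)
    summary = {
        col: {"mean": float(table[col].mean()), "std": float(table[col].std(ddof=0))}
        for col in table.columns
    }
    total_counted = int(table["count"].sum())
    if elapsed is None:
        elapsed = time.perf_counter() - t0
    summary["throughput"] = {
        "mean": throughput(total_counted, elapsed),
        "std": 0.0,
    }
    return table, summary
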