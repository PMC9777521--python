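"""Generalized dice loss and segmentation evaluation metrics.

The loss follows the class-weighted dice formulation used for heavily
imbalanced segmentation: with predicted per-class probabilities ``P`` and
one-hot ground truth ``G`` (class axis first, all other axes flattened into
the element axis),

    L = 1 - 2 * sum_i w_i sum_j P_ij G_ij
          / sum_i w_i sum_j (P_ij^2 + G_ij^2),

where the class weights are the inverse squared class areas,
``w_i = 1 / sum_j G_ij^2`` (for binary ``G`` this is the reciprocal of the
class pixel count).  A small smoothing constant guards empty intersections.

The metric suite covers the usual segmentation scores: per-class precision,
recall, F1, IoU, global/mean accuracy, mean/weighted IoU, boundary-F1 (BF)
score, dice, plus confusion-category overlays and per-volume dice
distribution summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "DICE_EPS",
    "SegScores",
    "dice_weights",
    "generalized_dice_loss",
    "one_hot",
    "confusion_counts",
    "segmentation_scores",
    "render_overlay",
    "per_volume_dice",
    "DiceSummary",
]

DICE_EPS = 1e-5  # smoothing added to the loss numerator and denominator


# ---------------------------------------------------------------------------
# Generalized dice loss
# ---------------------------------------------------------------------------

def _flatten_classes(a: np.ndarray) -> np.ndarray:
    """Collapse all axes after the leading class axis into one element axis."""
    a = np.asarray(a, dtype=np.float64)
    return a.reshape(a.shape[0], -1)


def one_hot(mask: np.ndarray, num_classes: int) -> np.ndarray:
    """Integer label mask -> one-hot array with leading class axis."""
    mask = np.asarray(mask)
    out = np.zeros((num_classes,) + mask.shape, dtype=np.float64)
    for c in range(num_classes):
        out[c] = mask == c
    return out


def dice_weights(G: np.ndarray) -> np.ndarray:
    """Inverse-squared-area class weights ``w_i = 1 / sum_j G_ij^2``.

    A class absent from ``G`` (zero denominator) receives weight 0 so it
    contributes nothing to the loss.
    """
    g = _flatten_classes(G)
    area = (g ** 2).sum(axis=1)
    w = np.zeros_like(area)
    present = area > 0
    w[present] = 1.0 / area[present]
    return w


def generalized_dice_loss(
    P: np.ndarray,
    G: np.ndarray,
    weights: np.ndarray | None = None,
    eps: float = DICE_EPS,
) -> float:
    """Class-weighted dice loss between probabilities ``P`` and one-hot ``G``.

    Both arrays carry the class axis first; any remaining axes (batch,
    spatial) are flattened into the element axis.  When ``weights`` is not
    supplied it is computed from ``G`` via :func:`dice_weights`.
    """
    p = _flatten_classes(P)
    g = _flatten_classes(G)
    if p.shape != g.shape:
        raise ValueError(f"P shape {p.shape} != G shape {g.shape}")
    if not np.any(g):
        raise ValueError("ground truth contains no class at all")
    w = dice_weights(G) if weights is None else np.asarray(weights, dtype=np.float64)
    if w.shape != (p.shape[0],):
        raise ValueError("weights must hold one value per class")
    num = 2.0 * float((w * (p * g).sum(axis=1)).sum()) + eps
    den = float((w * (p ** 2 + g ** 2).sum(axis=1)).sum()) + eps
    return 1.0 - num / den


# ---------------------------------------------------------------------------
# Confusion counts and scores
# ---------------------------------------------------------------------------

def confusion_counts(
    pred_mask: np.ndarray, gt_mask: np.ndarray, positive_class: int = 1
) -> tuple[int, int, int, int]:
    """Pixelwise (TP, FP, FN, TN) treating ``positive_class`` as foreground."""
    pred_mask = np.asarray(pred_mask)
    gt_mask = np.asarray(gt_mask)
    if pred_mask.shape != gt_mask.shape:
        raise ValueError(
            f"extent mismatch: pred {pred_mask.shape} vs gt {gt_mask.shape}"
        )
    p = pred_mask == positive_class
    g = gt_mask == positive_class
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return tp, fp, fn, tn


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Inner boundary: foreground pixels with a face-connected background
    neighbour (pixels on the array edge count as boundary)."""
    mask = mask.astype(bool)
    if not mask.any():
        return np.zeros_like(mask)
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~interior


def _bf_score(pred: np.ndarray, gt: np.ndarray, tolerance: float) -> float | None:
    """Boundary F1: precision/recall of boundary pixels matched within a
    Euclidean distance ``tolerance``.  ``None`` when both boundaries are
    empty (score undefined)."""
    pb = _boundary(pred)
    gb = _boundary(gt)
    n_p, n_g = int(pb.sum()), int(gb.sum())
    if n_p == 0 and n_g == 0:
        return None
    if n_p == 0 or n_g == 0:
        return 0.0
    dist_to_g = ndimage.distance_transform_edt(~gb)
    dist_to_p = ndimage.distance_transform_edt(~pb)
    precision = float(np.count_nonzero(dist_to_g[pb] <= tolerance)) / n_p
    recall = float(np.count_nonzero(dist_to_p[gb] <= tolerance)) / n_g
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass
class SegScores:
    """Full per-image (or per-volume) metric record.

    Per-class entries are ``NaN`` where undefined (class absent from both
    masks, or a ratio with zero denominator); aggregate means skip undefined
    entries.  All values lie in [0, 1]; multiply by 100 for the conventional
    percentage form.
    """

    classes: list[int]
    precision: dict[int, float]
    recall: dict[int, float]
    f1: dict[int, float]
    iou: dict[int, float]
    dice: dict[int, float]
    bf_score: dict[int, float]
    global_accuracy: float
    mean_accuracy: float
    mean_iou: float
    weighted_iou: float
    mean_bf_score: float

    def as_row(self) -> dict[str, float]:
        """Flatten to one CSV-friendly record."""
        row: dict[str, float] = {
            "global_accuracy": self.global_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "mean_iou": self.mean_iou,
            "weighted_iou": self.weighted_iou,
            "mean_bf_score": self.mean_bf_score,
        }
        for c in self.classes:
            for name, d in [
                ("precision", self.precision),
                ("recall", self.recall),
                ("f1", self.f1),
                ("iou", self.iou),
                ("dice", self.dice),
                ("bf_score", self.bf_score),
            ]:
                row[f"{name}_class{c}"] = d[c]
        return row


def _nanmean(values: list[float]) -> float:
    finite = [v for v in values if not np.isnan(v)]
    return float(np.mean(finite)) if finite else float("nan")


def segmentation_scores(
    pred_mask: np.ndarray,
    gt_mask: np.ndarray,
    bf_tolerance: float | None = None,
    num_classes: int | None = None,
) -> SegScores:
    """Compute the full metric record for one predicted/true mask pair.

    ``bf_tolerance`` is the boundary-match distance in pixels; when omitted
    it defaults to 0.75% of the mask diagonal.  ``num_classes`` fixes the
    class set (otherwise the union of labels present in either mask is
    used).  Classes absent from both masks are excluded from every mean.
    """
    pred_mask = np.asarray(pred_mask)
    gt_mask = np.asarray(gt_mask)
    if pred_mask.shape != gt_mask.shape:
        raise ValueError(
            f"extent mismatch: pred {pred_mask.shape} vs gt {gt_mask.shape}"
        )
    if num_classes is None:
        classes = sorted(set(np.unique(gt_mask)) | set(np.unique(pred_mask)))
    else:
        classes = list(range(num_classes))
    classes = [int(c) for c in classes]
    if bf_tolerance is None:
        bf_tolerance = 0.0075 * float(np.sqrt(sum(s ** 2 for s in gt_mask.shape)))

    total = gt_mask.size
    nan = float("nan")
    precision: dict[int, float] = {}
    recall: dict[int, float] = {}
    f1: dict[int, float] = {}
    iou: dict[int, float] = {}
    dice: dict[int, float] = {}
    bf: dict[int, float] = {}
    freq: dict[int, float] = {}
    for c in classes:
        tp, fp, fn, _ = confusion_counts(pred_mask, gt_mask, positive_class=c)
        if tp + fp + fn == 0:  # class absent from both masks
            precision[c] = recall[c] = f1[c] = iou[c] = dice[c] = bf[c] = nan
            freq[c] = 0.0
            continue
        precision[c] = tp / (tp + fp) if tp + fp else nan
        recall[c] = tp / (tp + fn) if tp + fn else nan
        # defined whenever the class appears in either mask; equals the
        # harmonic mean of precision and recall when both are defined
        f1[c] = 2 * tp / (2 * tp + fp + fn)
        iou[c] = tp / (tp + fp + fn)
        dice[c] = 2 * tp / (2 * tp + fp + fn)
        score = _bf_score(pred_mask == c, gt_mask == c, bf_tolerance)
        bf[c] = nan if score is None else score
        freq[c] = (tp + fn) / total

    present = [c for c in classes if freq[c] > 0]
    weighted = sum(freq[c] * iou[c] for c in present)
    weight_total = sum(freq[c] for c in present)
    return SegScores(
        classes=classes,
        precision=precision,
        recall=recall,
        f1=f1,
        iou=iou,
        dice=dice,
        bf_score=bf,
        global_accuracy=float(np.count_nonzero(pred_mask == gt_mask)) / total,
        mean_accuracy=_nanmean([recall[c] for c in classes]),
        mean_iou=_nanmean([iou[c] for c in classes]),
        weighted_iou=weighted / weight_total if weight_total else float("nan"),
        mean_bf_score=_nanmean([bf[c] for c in classes]),
    )


# ---------------------------------------------------------------------------
# Confusion overlay
# ---------------------------------------------------------------------------

_OVERLAY_COLORS = {
    "tp": (0, 255, 255),     # cyan
    "fp": (255, 0, 255),     # magenta
    "fn": (255, 255, 0),     # yellow
    "tn": (0, 0, 0),         # black
}


def render_overlay(pred_mask: np.ndarray, gt_mask: np.ndarray) -> np.ndarray:
    """RGB confusion overlay: TP cyan, FP magenta, FN yellow, TN black.

    Both masks must be binary (labels in {0, 1}) and 2D.
    """
    pred_mask = np.asarray(pred_mask)
    gt_mask = np.asarray(gt_mask)
    if pred_mask.shape != gt_mask.shape:
        raise ValueError("extent mismatch between prediction and ground truth")
    for name, m in [("prediction", pred_mask), ("ground truth", gt_mask)]:
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} mask is not binary")
    p = pred_mask.astype(bool)
    g = gt_mask.astype(bool)
    out = np.zeros(pred_mask.shape + (3,), dtype=np.uint8)
    out[p & g] = _OVERLAY_COLORS["tp"]
    out[p & ~g] = _OVERLAY_COLORS["fp"]
    out[~p & g] = _OVERLAY_COLORS["fn"]
    out[~p & ~g] = _OVERLAY_COLORS["tn"]
    return out


# ---------------------------------------------------------------------------
# Per-volume dice distribution
# ---------------------------------------------------------------------------

@dataclass
class DiceSummary:
    """Boxplot-style summary of a per-volume dice distribution for one class:
    median, quartiles, whiskers at the most extreme non-outliers under the
    1.5 * IQR rule, and the outlying values themselves."""

    values: list[float]
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float] = field(default_factory=list)


def per_volume_dice(
    pred_volumes: list[np.ndarray],
    gt_volumes: list[np.ndarray],
    num_classes: int | None = None,
) -> dict[int, DiceSummary]:
    """Dice per volume per class with a boxplot summary per class.

    Dice for class ``c`` on one volume is ``2 TP / (2 TP + FP + FN)``;
    volumes where the class is absent from both masks are skipped for that
    class.
    """
    if len(pred_volumes) == 0 or len(pred_volumes) != len(gt_volumes):
        raise ValueError("need >= 1 aligned (pred, gt) volume pair")
    if num_classes is None:
        labels: set[int] = set()
        for g in gt_volumes:
            labels |= set(int(v) for v in np.unique(g))
        for p in pred_volumes:
            labels |= set(int(v) for v in np.unique(p))
        classes = sorted(labels)
    else:
        classes = list(range(num_classes))

    out: dict[int, DiceSummary] = {}
    for c in classes:
        vals: list[float] = []
        for p, g in zip(pred_volumes, gt_volumes):
            tp, fp, fn, _ = confusion_counts(p, g, positive_class=c)
            if 2 * tp + fp + fn == 0:
                continue
            vals.append(2 * tp / (2 * tp + fp + fn))
        if not vals:
            continue
        arr = np.asarray(vals, dtype=np.float64)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inliers = arr[(arr >= lo_fence) & (arr <= hi_fence)]
        out[c] = DiceSummary(
            values=vals,
            median=float(med),
            q1=float(q1),
            q3=float(q3),
            whisker_low=float(inliers.min()),
            whisker_high=float(inliers.max()),
            outliers=[float(v) for v in arr[(arr < lo_fence) | (arr > hi_fence)]],
        )
    return out
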