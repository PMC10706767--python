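"""Segmentation evaluation: Dice, top-margin error, pooled ROC/AUC, sweeps.

The tumor-margin error is the clinically decisive quantity here: the
absolute vertical distance, in millimeters, between the topmost tumor pixel
of the ground truth and of the prediction. With the transducer on the
resection plane, this is the error in the predicted distance from the cut
surface to the tumor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve

from .image import DEFAULT_ROW_SPACING_MM

__all__ = [
    "MarginMeasurement",
    "SweepResult",
    "dice_coefficient",
    "tumor_margin_error",
    "roc_auc",
    "threshold_sweep",
]


def _as_binary_pair(truth: np.ndarray, pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {pred.shape}")
    return truth > 0, pred > 0


def dice_coefficient(truth: np.ndarray, pred: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|).

    Two empty masks agree perfectly (Dice 1); one empty mask against a
    non-empty one scores 0.
    """
    t, p = _as_binary_pair(truth, pred)
    total = int(t.sum()) + int(p.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((t & p).sum()) / total


@dataclass(frozen=True)
class MarginMeasurement:
    """Top tumor rows of ground truth and prediction, and their distance in mm."""

    tm_gt: int
    tm_pred: int | None
    error_mm: float
    row_spacing_mm: float
    no_tumor_predicted: bool = False


def tumor_margin_error(
    truth: np.ndarray,
    pred: np.ndarray,
    row_spacing_mm: float = DEFAULT_ROW_SPACING_MM,
) -> MarginMeasurement:
    """Absolute vertical distance between the topmost tumor pixels, in mm.

    The top margin of each mask is the global minimum foreground row index.
    An empty prediction has no margin; it is flagged and penalized with the
    worst realizable error — the distance from the true top row to the
    bottom of the image — so that averages over a test set stay defined.
    An empty ground truth is an error: there is no margin to measure.
    """
    t, p = _as_binary_pair(truth, pred)
    t_rows = np.nonzero(t.any(axis=1))[0]
    if t_rows.size == 0:
        raise ValueError("ground truth has no tumor; margin undefined")
    tm_gt = int(t_rows[0])
    p_rows = np.nonzero(p.any(axis=1))[0]
    if p_rows.size == 0:
        worst = (t.shape[0] - 1 - tm_gt) * row_spacing_mm
        return MarginMeasurement(tm_gt, None, float(worst), row_spacing_mm, True)
    tm_p = int(p_rows[0])
    return MarginMeasurement(tm_gt, tm_p, abs(tm_gt - tm_p) * row_spacing_mm, row_spacing_mm)


def roc_auc(
    truths: list[np.ndarray] | np.ndarray,
    probs: list[np.ndarray] | np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Pixel-pooled ROC analysis over a set of images.

    All pixels of all images are pooled into one binary classification
    problem (one ROC per method, not a per-image average). Returns
    ``(auc, fpr, tpr)``; the curve points support plotting.
    """
    if isinstance(truths, np.ndarray) and truths.ndim == 2:
        truths, probs = [truths], [probs]
    y = np.concatenate([(np.asarray(t) > 0).ravel() for t in truths])
    s = np.concatenate([np.asarray(p, dtype=np.float64).ravel() for p in probs])
    if y.all() or not y.any():
        raise ValueError("pooled pixels contain a single class; AUC undefined")
    fpr, tpr, _ = roc_curve(y, s)
    return float(np.trapezoid(tpr, fpr)), fpr, tpr


@dataclass
class SweepResult:
    """Dice and margin error as functions of the binarization threshold."""

    thresholds: np.ndarray
    mean_dice: np.ndarray
    sd_dice: np.ndarray
    mean_margin_error_mm: np.ndarray
    sd_margin_error_mm: np.ndarray
    per_image_dice: np.ndarray  # (n_thresholds, n_images)
    per_image_margin_mm: np.ndarray
    row_spacing_mm: float

    @property
    def best_dice_threshold(self) -> float:
        return float(self.thresholds[int(np.argmax(self.mean_dice))])

    @property
    def best_margin_threshold(self) -> float:
        return float(self.thresholds[int(np.argmin(self.mean_margin_error_mm))])


def threshold_sweep(
    truths: list[np.ndarray],
    probs: list[np.ndarray],
    thresholds: np.ndarray | list[float],
    row_spacing_mm: float = DEFAULT_ROW_SPACING_MM,
    postprocess: bool = False,
) -> SweepResult:
    """Evaluate Dice and margin error at every output-probability threshold.

    Probability maps are binarized at ``p >= threshold`` (threshold 0 keeps
    every pixel, threshold above 1 none), optionally cleaned with the
    standard post-processing (largest component + closing), and scored
    against the ground truths. Choosing the operating threshold trades the
    best Dice against the best margin error; both optima are exposed on the
    result.
    """
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if thresholds.size == 0:
        raise ValueError("threshold list is empty")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    if len(truths) != len(probs) or len(truths) == 0:
        raise ValueError("need matching, non-empty truth/probability lists")

    from .postprocess import close_mask, largest_component

    n_t, n_i = thresholds.size, len(truths)
    dice = np.zeros((n_t, n_i))
    margin = np.zeros((n_t, n_i))
    for j, (truth, pmap) in enumerate(zip(truths, probs)):
        pmap = np.asarray(pmap, dtype=np.float64)
        for i, thr in enumerate(thresholds):
            pred = pmap >= thr
            if postprocess:
                pred = close_mask(largest_component(pred))
            dice[i, j] = dice_coefficient(truth, pred)
            margin[i, j] = tumor_margin_error(truth, pred, row_spacing_mm).error_mm
    return SweepResult(
        thresholds=thresholds,
        mean_dice=dice.mean(axis=1),
        sd_dice=dice.std(axis=1),
        mean_margin_error_mm=margin.mean(axis=1),
        sd_margin_error_mm=margin.std(axis=1),
        per_image_dice=dice,
        per_image_margin_mm=margin,
        row_spacing_mm=row_spacing_mm,
    )
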