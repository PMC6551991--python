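"""Agreement statistics between reference and predicted segmentations.

Overlap metrics (Dice = 2TP/(2TP+FP+FN), sensitivity = TP/(TP+FN),
precision = TP/(TP+FP)), volume agreement with the undersegmentation sign
convention (reference minus prediction), two-way absolute-agreement
intraclass correlation ICC(2,1), cutoff classification accuracy with
Cohen's kappa, and midline-shift differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volume import mask_volume_ml

__all__ = [
    "ConfusionCounts",
    "overlap_metrics",
    "volume_agreement",
    "icc_absolute",
    "classification_accuracy",
    "shift_agreement",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be >= 0")


def overlap_metrics(ref: np.ndarray, pred: np.ndarray):
    """Dice, precision, sensitivity and the confusion counts.

    Conventions for empty masks: both empty means perfect agreement (all 1);
    empty reference with non-empty prediction gives sensitivity NaN
    (undefined), precision 0, Dice 0.
    """
    ref = np.asarray(ref, dtype=bool)
    pred = np.asarray(pred, dtype=bool)
    if ref.shape != pred.shape:
        raise ValueError("shape mismatch between reference and prediction")
    tp = int(np.logical_and(ref, pred).sum())
    fp = int(np.logical_and(~ref, pred).sum())
    fn = int(np.logical_and(ref, ~pred).sum())
    counts = ConfusionCounts(tp, fp, fn)
    if tp + fp + fn == 0:  # both masks empty
        return 1.0, 1.0, 1.0, counts
    dice = 2.0 * tp / (2.0 * tp + fp + fn)
    precision = tp / (tp + fp) if (tp + fp) > 0 else np.nan
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else np.nan
    return dice, precision, sensitivity, counts


def volume_agreement(ref: np.ndarray, pred: np.ndarray, spacing):
    """(volume difference, absolute volume difference) in mL.

    Difference is reference minus prediction: positive = undersegmentation
    by the automated method.
    """
    ref = np.asarray(ref, dtype=bool)
    pred = np.asarray(pred, dtype=bool)
    if ref.shape != pred.shape:
        raise ValueError("shape mismatch")
    diff = mask_volume_ml(ref, spacing) - mask_volume_ml(pred, spacing)
    return diff, abs(diff)


def icc_absolute(x, y) -> float:
    """ICC(2,1): two-way random, single measurement, absolute agreement.

    Computed from the ANOVA mean squares of the n x 2 measurement table:
    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired measurements")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    data = np.stack([x, y], axis=1)
    k = 2
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("zero total variance")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("degenerate ANOVA table")
    return float((msr - mse) / denom)


def classification_accuracy(ref_vals, pred_vals, cutoff: float):
    """Fraction of cases where both measurements fall on the same side of the
    cutoff, plus Cohen's kappa of the 2x2 table.

    Values exactly at the cutoff classify as 'not greater'. Kappa is NaN
    (with a warning) when either rater uses only one class.
    """
    ref_vals = np.asarray(ref_vals, dtype=float)
    pred_vals = np.asarray(pred_vals, dtype=float)
    if ref_vals.shape != pred_vals.shape or ref_vals.size == 0:
        raise ValueError("paired non-empty series required")
    a = ref_vals > cutoff
    b = pred_vals > cutoff
    accuracy = float((a == b).mean())
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        warnings.warn("kappa undefined for a single-class table; reporting NaN")
        kappa = float("nan")
    else:
        from sklearn.metrics import cohen_kappa_score

        kappa = float(cohen_kappa_score(a, b))
    return accuracy, kappa


def shift_agreement(ref_mm: float, pred_mm: float):
    """(difference in shift, absolute difference) in mm, reference minus
    prediction."""
    if not (np.isfinite(ref_mm) and np.isfinite(pred_mm)):
        raise ValueError("values must be finite")
    diff = float(ref_mm) - float(pred_mm)
    return diff, abs(diff)
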