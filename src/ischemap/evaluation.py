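"""Transition-zone ground truth and segmentation metrics.

Quantitative evaluation happens inside a region of interest spanning the
gradual perfusion transition: two dominant intensity levels are selected
automatically (an Otsu split into the dominant low/high populations, with
contour levels interpolated between the class medians, repeated over
bootstrap resamples and averaged), pixels below the low level are labelled
abnormal, above the high level normal, and the band in between is a
*buffer* where both labels count as correct — it is excluded from the confusion counts
entirely.  Metrics follow the usual confusion-matrix definitions

    AC = (TP+TN)/(TP+TN+FP+FN)     DC = 2TP/(2TP+FP+FN)
    SE = TP/(TP+FN)   SP = TN/(TN+FP)   PE = TP/(TP+FP)

plus the ROC area computed by a trapezoidal threshold sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from ischemap.errors import ValidationError

LABEL_NORMAL, LABEL_ABNORMAL, LABEL_BUFFER = 0, 1, 2
DEFAULT_EVAL_WINDOW = (80, 100)        # rows x cols


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    dice: float
    sensitivity: float
    specificity: float
    precision: float
    auc: float | None = None


@dataclass
class TransitionZoneGT:
    roi: tuple                         # (r0, r1, c0, c1)
    labels: np.ndarray                 # ROI-shaped, values in {0, 1, 2}
    n_repeats: int
    thresholds: tuple                  # (low, high) averaged levels


def _window_slices(eval_window, shape):
    """An eval window is (r0, r1, c0, c1) bounds or None for the full image."""
    if eval_window is None:
        return slice(0, shape[0]), slice(0, shape[1])
    r0, r1, c0, c1 = eval_window
    if r1 <= r0 or c1 <= c0:
        raise ValidationError("empty evaluation window")
    return slice(r0, r1), slice(c0, c1)


def confusion(pred_mask: np.ndarray, gt_labels: np.ndarray,
              eval_window=None) -> ConfusionCounts:
    """Pixel confusion counts inside the window, buffer pixels excluded."""
    pred = np.asarray(pred_mask).astype(bool)
    gt = np.asarray(gt_labels)
    if pred.shape != gt.shape:
        raise ValidationError("prediction and ground truth shapes differ")
    rs, cs = _window_slices(eval_window, pred.shape)
    p = pred[rs, cs]
    g = gt[rs, cs]
    if p.size == 0:
        raise ValidationError("empty evaluation window")
    keep = g != LABEL_BUFFER
    p, g = p[keep], g[keep] == LABEL_ABNORMAL
    return ConfusionCounts(tp=int(np.sum(p & g)), tn=int(np.sum(~p & ~g)),
                           fp=int(np.sum(p & ~g)), fn=int(np.sum(~p & g)))


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: division by zero, returning 0.0",
                      RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, Dice, sensitivity, specificity and precision from counts."""
    if counts.total == 0:
        raise ValidationError("all-zero confusion counts")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    return MetricsReport(
        accuracy=(tp + tn) / counts.total,
        dice=_safe_div(2 * tp, 2 * tp + fp + fn, "dice"),
        sensitivity=_safe_div(tp, tp + fn, "sensitivity"),
        specificity=_safe_div(tn, tn + fp, "specificity"),
        precision=_safe_div(tp, tp + fp, "precision"),
    )


def auc(prob_map: np.ndarray, gt_labels: np.ndarray,
        eval_window=None) -> float:
    """ROC area via a trapezoidal sweep over the unique score values."""
    scores = np.asarray(prob_map, dtype=np.float64)
    gt = np.asarray(gt_labels)
    rs, cs = _window_slices(eval_window, scores.shape)
    s = scores[rs, cs].ravel()
    g = gt[rs, cs].ravel()
    keep = g != LABEL_BUFFER
    s, g = s[keep], (g[keep] == LABEL_ABNORMAL)
    n_pos, n_neg = int(g.sum()), int((~g).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ground truth must contain both classes")
    order = np.argsort(-s, kind="stable")
    s_sorted, g_sorted = s[order], g[order]
    tp = np.cumsum(g_sorted)
    fp = np.cumsum(~g_sorted)
    # collapse ties: keep the last index of each distinct score
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.concatenate([distinct, [len(s_sorted) - 1]])
    tpr = np.concatenate([[0.0], tp[idx] / n_pos])
    fpr = np.concatenate([[0.0], fp[idx] / n_neg])
    return float(np.trapezoid(tpr, fpr))


def contour_ground_truth(lsci: np.ndarray, roi: tuple,
                         n_repeats: int = 3,
                         seed: int = 0,
                         median_size: int = 3) -> TransitionZoneGT:
    """Two dominant intensity levels inside the ROI -> normal/abnormal/buffer.

    ``lsci`` is a perfusion-oriented image (brighter = better perfused).
    The ROI is median-filtered first (``median_size``; suppresses thin
    bright vessel traces so the *area-dominant* perfusion levels drive the
    contours).  The dominant low/high populations are split by Otsu's
    threshold and the two contour levels are interpolated between the class
    medians m₁ < m₂ (low level = ¾m₁+¼m₂, high level = ¼m₁+¾m₂), which
    brackets the transition band robustly even when the upper population
    has a heavy vascular tail.  With ``n_repeats`` > 1 the ROI pixels are
    bootstrap-resampled and the two levels averaged over repeats, emulating
    repeated automatic annotation.  Pixels below the low level are
    abnormal, above the high level normal, in between buffer.
    """
    if n_repeats < 1:
        raise ValidationError("n_repeats must be >= 1")
    img = np.asarray(lsci, dtype=np.float64)
    r0, r1, c0, c1 = roi
    if not (0 <= r0 < r1 <= img.shape[0] and 0 <= c0 < c1 <= img.shape[1]):
        raise ValidationError("ROI out of bounds")
    patch = img[r0:r1, c0:c1]
    if median_size > 1:
        from scipy.ndimage import median_filter

        patch = median_filter(patch, size=median_size, mode="nearest")
    vals = patch.ravel()
    if vals.max() - vals.min() <= 1e-12:
        raise ValidationError("constant ROI: no separable intensity levels")
    rng = np.random.default_rng(seed)
    lows, highs = [], []
    for rep in range(n_repeats):
        sample = vals if n_repeats == 1 else \
            rng.choice(vals, size=vals.size, replace=True)
        if sample.max() - sample.min() <= 1e-12:
            sample = vals
        split = threshold_otsu(sample)
        m1 = np.median(sample[sample < split])
        m2 = np.median(sample[sample >= split])
        lows.append(0.75 * m1 + 0.25 * m2)
        highs.append(0.25 * m1 + 0.75 * m2)
    low, high = float(np.mean(lows)), float(np.mean(highs))
    labels = np.full(patch.shape, LABEL_BUFFER, dtype=np.int8)
    labels[patch < low] = LABEL_ABNORMAL
    labels[patch > high] = LABEL_NORMAL
    return TransitionZoneGT(roi=roi, labels=labels, n_repeats=n_repeats,
                            thresholds=(low, high))
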