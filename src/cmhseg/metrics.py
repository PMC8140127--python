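"""Evaluation statistics: pixel confusion, ROC/AUC, Dice, ICC, Bland–Altman.

Sensitivity/specificity are computed from pixel counts pooled across the
dataset (one confusion table for the whole image set); per-image averaging
is available via a flag on :func:`roc_sweep`. The ICC is the single-measure
two-way random-effects absolute-agreement form ICC(A,1) with the
McGraw & Wong F-distribution 95% confidence interval. Bland–Altman
differences are expressed in percent of the pair mean by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .io_formats import BinaryMask, CalibratedImage
from .postprocess import FilterChainSpec, run_partial_chain

__all__ = [
    "ConfusionCounts",
    "RocCurve",
    "AgreementReport",
    "confusion",
    "pool_confusion",
    "sensitivity_specificity",
    "roc_sweep",
    "dice",
    "icc_absolute_agreement",
    "bland_altman",
    "percent_error",
    "agreement_report",
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

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass(frozen=True)
class RocCurve:
    """Swept-parameter operating points and the trapezoidal AUC.

    ``points`` holds (parameter, sensitivity, specificity) per grid value;
    the AUC integrates sensitivity over 1−specificity with (0,0) and (1,1)
    anchor points appended.
    """

    points: tuple[tuple[float, float, float], ...]
    auc: float


@dataclass(frozen=True)
class AgreementReport:
    """Area-agreement summary between a method and the ground truth."""

    icc: float
    icc_ci95: tuple[float, float]
    ba_mean_diff_pct: float
    ba_loa_pct: tuple[float, float]
    dice_per_image: tuple[float, ...]

    @property
    def mean_dice(self) -> float:
        return float(np.mean(self.dice_per_image))


# ---------------------------------------------------------------------------
# confusion counts and rates
# ---------------------------------------------------------------------------

def confusion(pred: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    """Per-pixel confusion counts of a predicted vs a truth mask."""
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth differ in shape")
    p, t = pred.values, truth.values
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, fp, tn, fn)


def pool_confusion(counts: Sequence[ConfusionCounts]) -> ConfusionCounts:
    """Sum confusion counts across images (pixel pooling)."""
    out = ConfusionCounts(0, 0, 0, 0)
    for c in counts:
        out = out + c
    return out


def sensitivity_specificity(c: ConfusionCounts) -> tuple[float, float]:
    """(tp/(tp+fn), tn/(tn+fp)); raises on an undefined denominator."""
    if c.tp + c.fn == 0:
        raise ValueError("sensitivity undefined: no positive truth pixels")
    if c.tn + c.fp == 0:
        raise ValueError("specificity undefined: no negative truth pixels")
    return c.tp / (c.tp + c.fn), c.tn / (c.tn + c.fp)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def _auc_trapezoid(sens: np.ndarray, spec: np.ndarray) -> float:
    fpr = np.concatenate(([0.0], 1.0 - spec, [1.0]))
    tpr = np.concatenate(([0.0], sens, [1.0]))
    order = np.lexsort((tpr, fpr))
    return float(np.trapezoid(tpr[order], fpr[order]))


def roc_sweep(
    images: Sequence[CalibratedImage],
    truths: Sequence[BinaryMask],
    segmenter: Callable[[CalibratedImage, float], BinaryMask],
    grid: Sequence[float],
    chain_spec: FilterChainSpec | None = None,
    apply_partial_chain: bool = True,
    per_image_average: bool = False,
) -> RocCurve:
    """Sweep a segmentation parameter and trace the ROC curve.

    For every grid value each image is segmented, the first two
    post-processing steps (speckle and isolated-speckle removal) are applied
    — the state in which the study evaluates its ROC curves — and pixel
    counts are pooled across the dataset into one operating point. Set
    ``apply_partial_chain=False`` for the raw sweep, whose nested masks give
    a monotone curve, and ``per_image_average=True`` to average per-image
    rates instead of pooling counts.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("parameter grid is empty")
    if len(images) == 0 or len(images) != len(truths):
        raise ValueError("need a non-empty, matched image/truth dataset")
    points = []
    for param in grid:
        per_image = []
        for img, gt in zip(images, truths):
            seg = segmenter(img, float(param))
            if apply_partial_chain:
                seg = run_partial_chain(seg, chain_spec)
            per_image.append(confusion(seg, gt))
        if per_image_average:
            rates = np.array([sensitivity_specificity(c) for c in per_image])
            sens, spec = map(float, rates.mean(axis=0))
        else:
            sens, spec = sensitivity_specificity(pool_confusion(per_image))
        points.append((float(param), sens, spec))
    arr = np.array(points)
    return RocCurve(tuple(map(tuple, points)),
                    _auc_trapezoid(arr[:, 1], arr[:, 2]))


# ---------------------------------------------------------------------------
# overlap and area agreement
# ---------------------------------------------------------------------------

def dice(pred: BinaryMask, truth: BinaryMask) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); two empty masks agree perfectly (1)."""
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth differ in shape")
    a, b = pred.values, truth.values
    denom = int(np.count_nonzero(a)) + int(np.count_nonzero(b))
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(a & b) / denom


def icc_absolute_agreement(area_matrix: np.ndarray,
                           confidence: float = 0.95
                           ) -> tuple[float, tuple[float, float]]:
    """Single-measure two-way random-effects absolute-agreement ICC(A,1).

    ``area_matrix`` is n_subjects × k_raters with no missing cells. The
    point estimate comes from the two-way ANOVA mean squares

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)

    and the confidence interval from the McGraw & Wong F-distribution
    method. Degenerate input (zero variance everywhere) has no defined ICC.
    """
    x = np.asarray(area_matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("area matrix must be 2-D (subjects × raters)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)      # subjects
    ssc = n * np.sum((col_means - grand) ** 2)      # raters
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("degenerate variance: ICC undefined")
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    if mse == 0 or icc >= 1.0:
        # perfect agreement: interval collapses
        return float(icc), (float(icc), float(icc))
    a = k * icc / (n * (1.0 - icc))
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
    f_l = stats.f.ppf(1.0 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1.0 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return float(icc), (float(lower), float(upper))


def bland_altman(areas_a: Sequence[float], areas_b: Sequence[float],
                 percent: bool = True) -> tuple[float, float, float]:
    """Bland–Altman mean difference and 95% limits of agreement.

    With ``percent`` (the default) each pair's difference is expressed as a
    percentage of the pair mean, matching an agreement plot whose x-axis is
    the pair mean; pairs with zero mean are excluded with a warning. Limits
    of agreement are mean ± 1.96 × SD of the differences.
    """
    a = np.asarray(areas_a, dtype=float)
    b = np.asarray(areas_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors of equal length required")
    if percent:
        means = (a + b) / 2.0
        ok = means != 0
        if not ok.all():
            warnings.warn(f"excluding {int((~ok).sum())} zero-mean pair(s) "
                          "from percent Bland–Altman")
        diffs = (a[ok] - b[ok]) / means[ok] * 100.0
    else:
        diffs = a - b
    if diffs.size == 0:
        raise ValueError("no usable pairs")
    mean_diff = float(diffs.mean())
    sd = float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0
    return mean_diff, mean_diff - 1.96 * sd, mean_diff + 1.96 * sd


def percent_error(a_seg: float, a_gt: float) -> float:
    """Signed percent error of a segmented area vs the ground-truth area."""
    if a_gt == 0:
        raise ValueError("ground-truth area is zero: percent error undefined")
    return (a_seg - a_gt) / a_gt * 100.0


def agreement_report(pred_masks: Sequence[BinaryMask],
                     truth_masks: Sequence[BinaryMask]) -> AgreementReport:
    """Full area-agreement summary of one method against ground truth."""
    if len(pred_masks) != len(truth_masks) or not pred_masks:
        raise ValueError("need matched, non-empty mask lists")
    areas_pred = np.array([m.total_area_um2 for m in pred_masks])
    areas_true = np.array([m.total_area_um2 for m in truth_masks])
    icc, ci = icc_absolute_agreement(np.column_stack([areas_pred, areas_true]))
    mean_diff, lo, hi = bland_altman(areas_pred, areas_true, percent=True)
    dices = tuple(dice(p, t) for p, t in zip(pred_masks, truth_masks))
    return AgreementReport(icc, ci, mean_diff, (lo, hi), dices)
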