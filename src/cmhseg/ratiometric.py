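"""Ratiometric segmentation of Prussian blue pixels.

The per-pixel statistic is

    segmentation ratio = I_red * I_green / I_blue ** 2

Prussian blue deposits are blue-dominant, so their ratio is small; the
Nuclear Fast Red counterstain is red-dominant with moderate blue, giving a
ratio near or above 1. Pixels whose ratio falls *below* a threshold are
segmented. The statistic is invariant to a uniform rescaling of all three
channels, which makes it robust to exposure changes.

Threshold calibration follows the study protocol: for each image, sweep a
threshold grid, post-process every candidate mask with the full filter
chain, and keep the threshold minimizing the absolute percent error between
segmented and ground-truth area; the dataset-level optimum is the median of
the per-image minimizers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import BinaryMask, CalibratedImage
from .metrics import percent_error
from .postprocess import FilterChainSpec, run_chain

__all__ = [
    "RATIO_SENTINEL",
    "RatioMap",
    "ThresholdSelection",
    "default_threshold_grid",
    "compute_ratio",
    "segment_by_ratio",
    "segment_image",
    "select_optimal_threshold",
]

#: Ratio assigned to pixels with zero blue intensity. Prussian blue pixels
#: have *high* blue intensity, so a zero-blue pixel (pure black included)
#: must never pass a below-threshold test; the sentinel exceeds any sane
#: threshold grid.
RATIO_SENTINEL = 1e12


@dataclass(frozen=True)
class RatioMap:
    """Per-pixel segmentation-ratio values on a calibrated grid."""

    values: np.ndarray
    pixel_size_um: float
    source_id: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ThresholdSelection:
    """Result of the dataset-level threshold calibration.

    ``per_image_best`` maps each image's identifier to the grid threshold
    minimizing its absolute area percent error; ``optimal_threshold`` is the
    median of those per-image minimizers.
    """

    per_image_best: dict[str, float]
    optimal_threshold: float


def default_threshold_grid(lo: float = 0.05, hi: float = 5.0,
                           n: int = 101) -> np.ndarray:
    """Geometric grid of candidate thresholds spanning ``[lo, hi]``."""
    return np.geomspace(lo, hi, n)


def compute_ratio(image: CalibratedImage) -> RatioMap:
    """Compute the segmentation ratio I_R·I_G/I_B² at every pixel."""
    px = image.pixels.astype(np.float64)
    r, g, b = px[..., 0], px[..., 1], px[..., 2]
    values = np.full(r.shape, RATIO_SENTINEL, dtype=np.float64)
    ok = b > 0
    np.divide(r * g, b * b, out=values, where=ok)
    return RatioMap(values, image.pixel_size_um, image.source_id)


def segment_by_ratio(ratio_map: RatioMap, threshold: float) -> BinaryMask:
    """Mask of pixels whose ratio is strictly below ``threshold``."""
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    return BinaryMask(ratio_map.values < threshold, ratio_map.pixel_size_um,
                      ratio_map.source_id)


def segment_image(image: CalibratedImage, threshold: float) -> BinaryMask:
    """Convenience: :func:`compute_ratio` then :func:`segment_by_ratio`."""
    return segment_by_ratio(compute_ratio(image), threshold)


def select_optimal_threshold(
    images: Sequence[CalibratedImage],
    truths: Sequence[BinaryMask],
    grid: Sequence[float] | None = None,
    chain_spec: FilterChainSpec | None = None,
    rois: Sequence[BinaryMask | None] | None = None,
) -> ThresholdSelection:
    """Calibrate the segmentation-ratio threshold against ground truth.

    For each image the candidate mask at every grid threshold is passed
    through the full post-processing chain before its area is compared to
    the ground-truth area. Ties in the per-image argmin go to the smallest
    threshold (the more conservative segmentation). Images with zero
    ground-truth area carry no area-error signal and are excluded with a
    warning.
    """
    grid = np.sort(np.asarray(
        default_threshold_grid() if grid is None else grid, dtype=float))
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if len(images) != len(truths):
        raise ValueError("images and truths differ in length")
    if chain_spec is None:
        chain_spec = FilterChainSpec(method="ratiometric")
    if rois is None:
        rois = [None] * len(images)

    per_image_best: dict[str, float] = {}
    for idx, (img, gt, roi) in enumerate(zip(images, truths, rois)):
        key = img.source_id or f"image_{idx}"
        gt_area = gt.total_area_um2
        if gt_area == 0:
            warnings.warn(f"{key}: zero ground-truth area, excluded from "
                          "threshold calibration")
            continue
        rmap = compute_ratio(img)
        errors = np.empty(grid.size)
        for j, t in enumerate(grid):
            seg = run_chain(segment_by_ratio(rmap, t), chain_spec, roi=roi)
            errors[j] = abs(percent_error(seg.total_area_um2, gt_area))
        per_image_best[key] = float(grid[int(np.argmin(errors))])

    if not per_image_best:
        raise ValueError("no image with nonzero ground-truth area")
    optimal = float(np.median(list(per_image_best.values())))
    return ThresholdSelection(per_image_best, optimal)
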