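"""Ordered connected-component filter chain for segmented masks.

Every segmentation (ground truth, ratiometric, phasor) passes through the
same chain of physically calibrated filters, in this order:

1. remove components smaller than 5 µm² (speckle);
2. remove components smaller than 50 µm² whose nearest neighbouring
   component is farther than 50 µm away (isolated speckle);
3. ratiometric/phasor only: remove components larger than 6000 µm²
   (stain pools and slide artifacts far above plausible deposit size);
4. phasor only: fill enclosed holes smaller than 1.73 µm²;
5. ratiometric/phasor only, when a region-of-interest mask is supplied:
   intersect with the coarse manual ROI.

All inequalities are strict. Foreground components use 8-connectivity and
holes 4-connectivity (the standard dual pairing).
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

from .io_formats import BinaryMask

__all__ = [
    "LabeledRegions",
    "FilterChainSpec",
    "label_regions",
    "remove_small",
    "remove_isolated_small",
    "remove_large",
    "fill_small_holes",
    "apply_roi_check",
    "run_chain",
    "run_partial_chain",
]

_METHODS = ("truth", "ratiometric", "phasor", "deep_learning")

# 4-connected structuring element: a pixel is a boundary pixel when one of
# its 4-neighbours lies outside the region
_CROSS = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class LabeledRegions:
    """Connected components of a mask with per-region physical areas."""

    labels: np.ndarray            # H×W ints, 0 = background
    areas_um2: np.ndarray         # area of region i at index i-1
    boundary: np.ndarray          # H×W bool: region pixels with an exterior 4-neighbour
    pixel_size_um: float
    source_id: str = ""

    @property
    def n_regions(self) -> int:
        return len(self.areas_um2)

    def mask(self, keep: np.ndarray | None = None) -> BinaryMask:
        """Rebuild a mask from all regions, or from ``keep[label-1]`` flags."""
        if keep is None:
            values = self.labels > 0
        else:
            lut = np.concatenate(([False], np.asarray(keep, dtype=bool)))
            values = lut[self.labels]
        return BinaryMask(values, self.pixel_size_um, self.source_id)

    def boundary_coords(self, label: int) -> np.ndarray:
        """(N, 2) row/col coordinates of one region's boundary pixels."""
        return np.argwhere(self.boundary & (self.labels == label))


@dataclass(frozen=True)
class FilterChainSpec:
    """Filter parameters (µm / µm²) and the method tag scoping them.

    The defaults are the study's empirically chosen values; ``method``
    selects which rules apply (``max_area_um2`` only for ratiometric and
    phasor, hole filling only for phasor, the ROI check never for
    deep_learning).
    """

    method: str = "truth"
    min_area_um2: float = 5.0
    isolated_max_area_um2: float = 50.0
    isolation_distance_um: float = 50.0
    max_area_um2: float = 6000.0
    hole_fill_max_um2: float = 1.73

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        for name in ("min_area_um2", "isolated_max_area_um2",
                     "isolation_distance_um", "max_area_um2",
                     "hole_fill_max_um2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def label_regions(mask: BinaryMask, connectivity: int = 8) -> LabeledRegions:
    """Connected components of a mask (8-connectivity by default)."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labels = measure.label(mask.values, connectivity=1 if connectivity == 4 else 2)
    n = int(labels.max())
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    areas = counts.astype(np.float64) * mask.pixel_area_um2
    interior = ndimage.binary_erosion(mask.values, structure=_CROSS,
                                      border_value=0)
    boundary = mask.values & ~interior
    return LabeledRegions(labels, areas, boundary, mask.pixel_size_um,
                          mask.source_id)


def remove_small(regions: LabeledRegions,
                 min_area_um2: float = 5.0) -> BinaryMask:
    """Drop regions with area strictly less than ``min_area_um2``."""
    return regions.mask(keep=regions.areas_um2 >= min_area_um2)


def remove_isolated_small(regions: LabeledRegions,
                          max_area_um2: float = 50.0,
                          min_distance_um: float = 50.0) -> BinaryMask:
    """Drop small regions farther than ``min_distance_um`` from all others.

    A region is removed iff its area is strictly below ``max_area_um2`` AND
    the minimum boundary-to-boundary Euclidean distance to every other
    region strictly exceeds ``min_distance_um``. With a single region the
    rule is vacuous (there is no closest spot) and the region is kept.
    """
    n = regions.n_regions
    if n <= 1:
        return regions.mask()
    keep = np.ones(n, dtype=bool)
    small = np.flatnonzero(regions.areas_um2 < max_area_um2)
    if small.size == 0:
        return regions.mask()
    coords = np.argwhere(regions.boundary)
    blabels = regions.labels[coords[:, 0], coords[:, 1]]
    for i in small:
        label = i + 1
        own = blabels == label
        others = coords[~own]
        tree = cKDTree(others)
        d_px, _ = tree.query(coords[own], k=1)
        if d_px.min() * regions.pixel_size_um > min_distance_um:
            keep[i] = False
    return regions.mask(keep=keep)


def remove_large(regions: LabeledRegions,
                 max_area_um2: float = 6000.0) -> BinaryMask:
    """Drop regions with area strictly greater than ``max_area_um2``."""
    return regions.mask(keep=regions.areas_um2 <= max_area_um2)


def fill_small_holes(mask: BinaryMask,
                     max_hole_um2: float = 1.73) -> BinaryMask:
    """Fill enclosed background components smaller than ``max_hole_um2``.

    Holes are 4-connected background components with no path to the image
    border; border-touching background is exterior and never filled.
    """
    bg_labels = measure.label(~mask.values, connectivity=1)
    if bg_labels.max() == 0:
        return mask
    border = np.unique(np.concatenate([
        bg_labels[0], bg_labels[-1], bg_labels[:, 0], bg_labels[:, -1]]))
    counts = np.bincount(bg_labels.ravel())
    areas = counts * mask.pixel_area_um2
    fill = (areas < max_hole_um2)
    fill[border] = False
    fill[0] = False
    return mask.with_values(mask.values | fill[bg_labels])


def apply_roi_check(mask: BinaryMask, roi: BinaryMask) -> BinaryMask:
    """Keep only segmented pixels inside the coarse manual ROI."""
    if roi.shape != mask.shape:
        raise ValueError("ROI shape does not match mask")
    return mask.with_values(mask.values & roi.values)


def run_partial_chain(mask: BinaryMask,
                      spec: FilterChainSpec | None = None) -> BinaryMask:
    """First two chain steps only (the state in which ROC curves are swept)."""
    if spec is None:
        spec = FilterChainSpec()
    out = remove_small(label_regions(mask), spec.min_area_um2)
    out = remove_isolated_small(label_regions(out), spec.isolated_max_area_um2,
                                spec.isolation_distance_um)
    return out


def run_chain(mask: BinaryMask, spec: FilterChainSpec,
              roi: BinaryMask | None = None) -> BinaryMask:
    """Apply the full ordered filter chain for the spec's method tag."""
    out = run_partial_chain(mask, spec)
    if spec.method in ("ratiometric", "phasor"):
        out = remove_large(label_regions(out), spec.max_area_um2)
    if spec.method == "phasor":
        out = fill_small_holes(out, spec.hole_fill_max_um2)
    if roi is not None and spec.method != "deep_learning":
        out = apply_roi_check(out, roi)
    return out
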