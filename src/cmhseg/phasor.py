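"""RGB spectral-phasor segmentation.

Each pixel's three channel intensities are projected onto the first Fourier
harmonic across the channel index l = 1 (red), 2 (green), 3 (blue):

    H = sum_l I_l * cos(2*pi*l/3)        (real part)
    S = sum_l I_l * sin(2*pi*l/3)        (imaginary part)

With the intensities normalized to unit pixel sum, (H, S) is a chromaticity
coordinate inside the equilateral triangle whose vertices are the pure
channels on the unit circle: red at angle 2π/3, green at 4π/3, blue at 0.
Prussian blue pixels cluster near the blue vertex (H → 1, S ≈ 0); the pink
Nuclear Fast Red counterstain sits at moderate S > 0 and small H; achromatic
pixels (shadows, greys) collapse to the origin.

Segmentation gates a 2-D histogram of phasor space: the "bluest" occupied
bin is found by minimizing the row/column index ratio x/y, a circular gate
of swept radius is centred on it, and pixels whose phasor falls inside the
gate are remapped to an image-space mask. The dataset-level optimal radius
is the mean of per-image minimizers of the absolute area percent error.
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
    "PhasorField",
    "PhasorHistogram",
    "PhasorGate",
    "RadiusSelection",
    "default_radius_grid",
    "compute_phasor",
    "build_histogram",
    "find_bluest_bin",
    "bin_center",
    "gate_from_image",
    "segment_by_phasor",
    "segment_image",
    "select_optimal_radius",
]

# first-harmonic projection weights for l = 1 (red), 2 (green), 3 (blue)
_ANGLES = 2.0 * np.pi * np.arange(1, 4) / 3.0
_COS = np.cos(_ANGLES)  # (-1/2, -1/2, 1)
_SIN = np.sin(_ANGLES)  # (+sqrt(3)/2, -sqrt(3)/2, 0)


@dataclass(frozen=True)
class PhasorField:
    """Per-pixel phasor coordinates H (real) and S (imaginary)."""

    H: np.ndarray
    S: np.ndarray
    normalized: bool
    pixel_size_um: float
    source_id: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.H.shape


@dataclass(frozen=True)
class PhasorHistogram:
    """2-D binned phasor density.

    Rows (1-based index x) run from S = +1 at row 1 down to S = −1; columns
    (1-based index y) run from H = −1 at column 1 up to H = +1. This fixed
    orientation makes the x/y-minimizing search land on high-H bins, i.e.
    the blue vertex.
    """

    counts: np.ndarray
    h_edges: np.ndarray
    s_edges: np.ndarray

    @property
    def bluest_bin(self) -> tuple[int, int]:
        return find_bluest_bin(self)


@dataclass(frozen=True)
class PhasorGate:
    """Circular gate in phasor space: centre (H0, S0) and radius."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("gate radius must be > 0")


@dataclass(frozen=True)
class RadiusSelection:
    """Per-image best gate radii and their arithmetic mean."""

    per_image_best: dict[str, float]
    optimal_radius: float


def default_radius_grid(lo: float = 0.0125, hi: float = 0.5,
                        n: int = 40) -> np.ndarray:
    """Linear grid of gate radii spanning (0, 0.5] in phasor units."""
    return np.linspace(lo, hi, n)


def compute_phasor(image: CalibratedImage, normalize: bool = True) -> PhasorField:
    """Project each pixel's RGB intensities onto the first Fourier harmonic.

    With ``normalize`` (the default) each channel is divided by the pixel's
    total intensity first, making the coordinates independent of brightness;
    zero-total pixels map to the origin. Without it the literal unnormalized
    sums are returned and scale linearly with intensity.
    """
    px = image.pixels.astype(np.float64)
    if normalize:
        total = px.sum(axis=2, keepdims=True)
        px = np.divide(px, total, out=np.zeros_like(px), where=total > 0)
    H = px @ _COS
    S = px @ _SIN
    return PhasorField(H, S, normalize, image.pixel_size_um, image.source_id)


def build_histogram(field: PhasorField, bins: int | tuple[int, int] = 256
                    ) -> PhasorHistogram:
    """Bin a normalized phasor field over the fixed [−1, 1]² range."""
    if not field.normalized:
        raise ValueError("histogram requires a normalized phasor field "
                         "(unbounded axes otherwise)")
    if isinstance(bins, int):
        bins = (bins, bins)
    rows, cols = bins
    if rows <= 0 or cols <= 0:
        raise ValueError("bin counts must be positive")
    counts, s_edges, h_edges = np.histogram2d(
        field.S.ravel(), field.H.ravel(), bins=(rows, cols),
        range=[[-1.0, 1.0], [-1.0, 1.0]])
    # histogram2d orders rows by ascending S; flip so row 1 is S = +1
    counts = counts[::-1].astype(np.int64)
    return PhasorHistogram(counts, h_edges, s_edges)


def find_bluest_bin(hist: PhasorHistogram) -> tuple[int, int]:
    """Occupied bin minimizing x/y over 1-based (row x, column y) indices.

    Ties go to the larger column (bluer H), then the smaller row.
    """
    x, y = np.nonzero(hist.counts)
    if x.size == 0:
        raise ValueError("empty phasor histogram")
    x = x + 1  # 1-based
    y = y + 1
    ratio = x / y
    best = ratio.min()
    tie = ratio == best
    xt, yt = x[tie], y[tie]
    pick = np.lexsort((xt, -yt))[0]  # max y, then min x
    return int(xt[pick]), int(yt[pick])


def bin_center(hist: PhasorHistogram, xy: tuple[int, int]) -> tuple[float, float]:
    """Phasor coordinates (H0, S0) of a 1-based (row, column) bin."""
    x, y = xy
    h0 = 0.5 * (hist.h_edges[y - 1] + hist.h_edges[y])
    # row 1 holds the top S bin, i.e. the last s_edges interval
    rows = hist.counts.shape[0]
    s0 = 0.5 * (hist.s_edges[rows - x] + hist.s_edges[rows - x + 1])
    return float(h0), float(s0)


def gate_from_image(image: CalibratedImage, radius: float,
                    bins: int | tuple[int, int] = 256,
                    normalize: bool = True) -> tuple[PhasorField, PhasorGate]:
    """Locate the bluest phasor bin of an image and centre a gate on it."""
    field = compute_phasor(image, normalize=normalize)
    hist = build_histogram(field, bins=bins)
    center = bin_center(hist, find_bluest_bin(hist))
    return field, PhasorGate(center, radius)


def segment_by_phasor(field: PhasorField, gate: PhasorGate) -> BinaryMask:
    """Remap pixels whose phasor lies inside the circular gate (inclusive)."""
    h0, s0 = gate.center
    inside = (field.H - h0) ** 2 + (field.S - s0) ** 2 <= gate.radius ** 2
    return BinaryMask(inside, field.pixel_size_um, field.source_id)


def segment_image(image: CalibratedImage, radius: float,
                  bins: int | tuple[int, int] = 256,
                  normalize: bool = True) -> BinaryMask:
    """Full phasor segmentation of one image at a given gate radius."""
    field, gate = gate_from_image(image, radius, bins=bins, normalize=normalize)
    return segment_by_phasor(field, gate)


def select_optimal_radius(
    images: Sequence[CalibratedImage],
    truths: Sequence[BinaryMask],
    radii: Sequence[float] | None = None,
    chain_spec: FilterChainSpec | None = None,
    rois: Sequence[BinaryMask | None] | None = None,
    bins: int | tuple[int, int] = 256,
) -> RadiusSelection:
    """Calibrate the gate radius against ground truth.

    Mirrors the ratiometric calibration, except the dataset-level optimum is
    the arithmetic *mean* of the per-image best radii. Candidate masks are
    fully post-processed before the area comparison; zero-ground-truth
    images are excluded with a warning.
    """
    radii = np.sort(np.asarray(
        default_radius_grid() if radii is None else radii, dtype=float))
    if radii.size == 0:
        raise ValueError("radius grid is empty")
    if len(images) != len(truths):
        raise ValueError("images and truths differ in length")
    if chain_spec is None:
        chain_spec = FilterChainSpec(method="phasor")
    if rois is None:
        rois = [None] * len(images)

    per_image_best: dict[str, float] = {}
    for idx, (img, gt, roi) in enumerate(zip(images, truths, rois)):
        key = img.source_id or f"image_{idx}"
        gt_area = gt.total_area_um2
        if gt_area == 0:
            warnings.warn(f"{key}: zero ground-truth area, excluded from "
                          "radius calibration")
            continue
        field, gate0 = gate_from_image(img, radii[0], bins=bins)
        dist2 = (field.H - gate0.center[0]) ** 2 + (field.S - gate0.center[1]) ** 2
        errors = np.empty(radii.size)
        for j, r in enumerate(radii):
            mask = BinaryMask(dist2 <= r * r, img.pixel_size_um, img.source_id)
            seg = run_chain(mask, chain_spec, roi=roi)
            errors[j] = abs(percent_error(seg.total_area_um2, gt_area))
        per_image_best[key] = float(radii[int(np.argmin(errors))])

    if not per_image_best:
        raise ValueError("no image with nonzero ground-truth area")
    optimal = float(np.mean(list(per_image_best.values())))
    return RadiusSelection(per_image_best, optimal)
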