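"""Calibrated images, binary masks, and their on-disk formats.

Containers carry a physical pixel size (µm per pixel edge) so that every
downstream area rule — the 5/50/6000 µm² component filters, the hole-fill
bound, per-annotator areas — operates in physical units rather than pixels.
Masks round-trip losslessly through two formats: {0,255} PNG rasters and a
row-major run-length encoding stored as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "CalibratedImage",
    "BinaryMask",
    "AnnotationSet",
    "RunLengthMask",
    "read_image",
    "write_image",
    "read_mask_png",
    "write_mask_png",
    "rle_encode",
    "rle_decode",
    "read_rle_json",
    "write_rle_json",
    "write_area_table",
    "AREA_TABLE_COLUMNS",
]


@dataclass(frozen=True)
class CalibratedImage:
    """An RGB brightfield image with a physical pixel-size calibration.

    Parameters
    ----------
    pixels : (H, W, 3) ndarray of unsigned integers
        Channel order is red, green, blue.
    pixel_size_um : float
        Physical edge length of one pixel in µm; one pixel covers
        ``pixel_size_um ** 2`` µm².
    source_id : str
        Free-text identifier (file name, synthetic seed tag, ...).
    """

    pixels: np.ndarray
    pixel_size_um: float
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected 3 channels, got array of shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("pixel intensities must be integers")
        if px.size and px.min() < 0:
            raise ValueError("pixel intensities must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def pixel_area_um2(self) -> float:
        return float(self.pixel_size_um) ** 2


@dataclass(frozen=True)
class BinaryMask:
    """A per-pixel foreground/background labeling on a calibrated grid."""

    values: np.ndarray
    pixel_size_um: float
    source_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {v.shape}")
        if v.dtype != bool:
            if not np.isin(np.unique(v), (0, 1)).all():
                raise ValueError("mask values must be boolean or 0/1")
            v = v.astype(bool)
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area_um2(self) -> float:
        return float(self.pixel_size_um) ** 2

    @property
    def total_area_um2(self) -> float:
        """Foreground area in µm² (true-pixel count × pixel area)."""
        return float(np.count_nonzero(self.values)) * self.pixel_area_um2

    def with_values(self, values: np.ndarray, suffix: str = "") -> "BinaryMask":
        return BinaryMask(values, self.pixel_size_um, self.source_id + suffix)


@dataclass(frozen=True)
class AnnotationSet:
    """Masks from K independent annotators of the same image."""

    masks: tuple[BinaryMask, ...]

    def __post_init__(self) -> None:
        masks = tuple(self.masks)
        if len(masks) < 1:
            raise ValueError("an AnnotationSet needs at least one mask")
        ref = masks[0]
        for m in masks[1:]:
            if m.shape != ref.shape:
                raise ValueError("annotator masks differ in shape")
            if m.pixel_size_um != ref.pixel_size_um:
                raise ValueError("annotator masks differ in calibration")
        object.__setattr__(self, "masks", masks)

    def __len__(self) -> int:
        return len(self.masks)

    def __iter__(self):
        return iter(self.masks)

    @property
    def pixel_size_um(self) -> float:
        return self.masks[0].pixel_size_um

    @property
    def shape(self) -> tuple[int, int]:
        return self.masks[0].shape

    def stack(self) -> np.ndarray:
        """K×H×W boolean array of all annotator masks."""
        return np.stack([m.values for m in self.masks])


@dataclass(frozen=True)
class RunLengthMask:
    """Run-length coded mask: runs of true pixels in row-major flat order.

    Each run is a ``(start_offset, length)`` pair with 0-based offsets into
    the flattened H×W grid. Runs are sorted and non-overlapping.
    """

    shape: tuple[int, int]
    runs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        h, w = self.shape
        if h < 0 or w < 0:
            raise ValueError("shape must be non-negative")
        n = h * w
        runs = tuple((int(s), int(l)) for s, l in self.runs)
        prev_end = 0
        for s, l in runs:
            if l <= 0:
                raise ValueError("run lengths must be positive")
            if s < prev_end:
                raise ValueError("runs must be sorted and non-overlapping")
            if s + l > n:
                raise ValueError(f"run ({s},{l}) exceeds grid of {n} pixels")
            prev_end = s + l
        object.__setattr__(self, "shape", (int(h), int(w)))
        object.__setattr__(self, "runs", runs)


# ---------------------------------------------------------------------------
# image IO
# ---------------------------------------------------------------------------

def read_image(path: str | Path, pixel_size_um: float) -> CalibratedImage:
    """Read a 3-channel TIFF/PNG as a :class:`CalibratedImage`.

    The stored channel order is taken as red, green, blue (the convention of
    both formats as written by imageio/tifffile).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    px = np.asarray(iio.imread(path))
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(
            f"expected 3 channels in {path.name}, got shape {px.shape}"
        )
    return CalibratedImage(px, pixel_size_um, source_id=path.name)


def write_image(image: CalibratedImage, path: str | Path) -> None:
    arr = image.pixels
    if arr.dtype not in (np.uint8, np.uint16):
        arr = arr.astype(np.uint16 if arr.max(initial=0) > 255 else np.uint8)
    iio.imwrite(Path(path), arr)


def read_mask_png(path: str | Path, pixel_size_um: float) -> BinaryMask:
    """Read a {0,255} PNG mask; any other pixel value is an error."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        raise ValueError(f"mask {path.name} must be single-channel")
    bad = np.setdiff1d(np.unique(arr), [0, 255])
    if bad.size:
        raise ValueError(
            f"mask {path.name} is not binary: found values {bad.tolist()}"
        )
    return BinaryMask(arr == 255, pixel_size_um, source_id=path.name)


def write_mask_png(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit PNG with true → 255, false → 0."""
    iio.imwrite(Path(path), mask.values.astype(np.uint8) * 255)


# ---------------------------------------------------------------------------
# run-length coding
# ---------------------------------------------------------------------------

def rle_encode(mask: BinaryMask) -> RunLengthMask:
    """Encode a mask as row-major runs of true pixels."""
    flat = mask.values.ravel()
    # transitions of the padded 0/1 signal give run starts and ends
    diff = np.diff(np.concatenate(([0], flat.view(np.uint8), [0])).astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    runs = tuple((int(s), int(e - s)) for s, e in zip(starts, ends))
    return RunLengthMask(mask.shape, runs)


def rle_decode(rle: RunLengthMask, pixel_size_um: float,
               source_id: str = "") -> BinaryMask:
    """Decode runs back to a raster mask (inverse of :func:`rle_encode`)."""
    h, w = rle.shape
    flat = np.zeros(h * w, dtype=bool)
    for s, l in rle.runs:
        flat[s:s + l] = True
    return BinaryMask(flat.reshape(h, w), pixel_size_um, source_id)


def write_rle_json(rle: RunLengthMask, path: str | Path) -> None:
    payload = {"shape": list(rle.shape), "runs": [list(r) for r in rle.runs]}
    Path(path).write_text(json.dumps(payload))


def read_rle_json(path: str | Path) -> RunLengthMask:
    payload = json.loads(Path(path).read_text())
    return RunLengthMask(tuple(payload["shape"]),
                         tuple(tuple(r) for r in payload["runs"]))


# ---------------------------------------------------------------------------
# tabular results
# ---------------------------------------------------------------------------

AREA_TABLE_COLUMNS = (
    "image_id",
    "method",
    "parameter",
    "segmented_area_um2",
    "ground_truth_area_um2",
    "percent_difference",
)


def write_area_table(records: Iterable[dict], path: str | Path) -> pd.DataFrame:
    """Write one row per (image, method) of segmented vs ground-truth area.

    Returns the DataFrame that was written. An empty record list produces a
    header-only CSV.
    """
    df = pd.DataFrame(list(records), columns=AREA_TABLE_COLUMNS)
    df.to_csv(path, index=False)
    return df
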