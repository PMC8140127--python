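"""Multi-annotator consensus ground truth by per-pixel majority voting."""

from __future__ import annotations

import numpy as np

from .io_formats import AnnotationSet, BinaryMask

__all__ = ["majority_vote", "annotator_areas", "annotator_area_matrix"]


def majority_vote(annotations: AnnotationSet, min_votes: int = 2) -> BinaryMask:
    """Pixel is consensus-positive iff at least ``min_votes`` annotators
    marked it.

    The default of 2 matches the study's rule for four annotators; with
    ``min_votes=1`` this is the union of the masks and with
    ``min_votes=len(annotations)`` their intersection.
    """
    k = len(annotations)
    if not 1 <= min_votes <= k:
        raise ValueError(f"min_votes must be in [1, {k}], got {min_votes}")
    votes = annotations.stack().sum(axis=0)
    return BinaryMask(votes >= min_votes, annotations.pixel_size_um,
                      source_id="consensus")


def annotator_areas(annotations: AnnotationSet) -> np.ndarray:
    """Each annotator's total marked area in µm² for one image (length K)."""
    return np.array([m.total_area_um2 for m in annotations])


def annotator_area_matrix(annotation_sets: list[AnnotationSet]) -> np.ndarray:
    """n_images × K area matrix across a dataset, the input to the ICC."""
    if not annotation_sets:
        raise ValueError("no annotation sets given")
    k = len(annotation_sets[0])
    if any(len(a) != k for a in annotation_sets):
        raise ValueError("annotation sets differ in annotator count")
    return np.stack([annotator_areas(a) for a in annotation_sets])
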