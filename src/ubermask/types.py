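"""Core raster / instance data model shared by all modules.

Conventions: all coordinates are 0-based ``(row, col)``; bounding boxes and
tile bounds are half-open ``(row0, col0, row1, col1)``.  A *label mask* is a
2D non-negative integer raster where 0 is background and each positive value
identifies one nucleus instance; the raster encoding guarantees instances
within one mask never overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np


def validate_image(pixels: np.ndarray) -> np.ndarray:
    """Validate a 2D intensity plane: 2D, numeric, finite."""
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D image plane, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty image plane")
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"non-numeric image payload of dtype {arr.dtype}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image plane contains non-finite values")
    return arr


def validate_mask(labels: np.ndarray) -> np.ndarray:
    """Validate a 2D instance label mask: 2D, integer, all values >= 0."""
    arr = np.asarray(labels)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D label mask, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.round(arr)):
            arr = arr.astype(np.int64)
        else:
            raise ValueError(f"label mask must be integer-valued, got {arr.dtype}")
    if arr.size and arr.min() < 0:
        raise ValueError("label mask contains negative values")
    return arr


@dataclass(frozen=True)
class NucleusRecord:
    """One segmented nucleus instance.

    ``equivalent_radius`` is the radius of the circle with the same area,
    ``sqrt(area / pi)``; it is always derived from ``area``.
    """

    label: int
    method: str
    centroid: tuple[float, float]
    area: int
    bbox: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if self.area < 1:
            raise ValueError("nucleus area must be >= 1 pixel")
        r0, c0, r1, c1 = self.bbox
        cr, cc = self.centroid
        if not (r0 <= cr < r1 and c0 <= cc < c1):
            raise ValueError("centroid must lie inside the bounding box")

    @property
    def equivalent_radius(self) -> float:
        return math.sqrt(self.area / math.pi)


@dataclass
class MethodMaskSet:
    """Named collection of co-registered label masks from different segmenters.

    Method order is significant: deterministic tie-breaking in consensus
    voting prefers the earlier method.
    """

    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not self.masks:
            raise ValueError("MethodMaskSet requires at least one method")
        self.masks = {name: validate_mask(m) for name, m in self.masks.items()}
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"masks must share a common shape, got {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.masks.values())).shape

    @property
    def methods(self) -> list[str]:
        return list(self.masks.keys())

    def __getitem__(self, method: str) -> np.ndarray:
        return self.masks[method]

    def __iter__(self) -> Iterator[str]:
        return iter(self.masks)

    def __len__(self) -> int:
        return len(self.masks)


@dataclass(frozen=True)
class ProvenancedNucleus:
    """A harvested nucleus: its record plus the winning method and the exact
    pixel set (row indices, col indices) it occupies in the source mask."""

    record: NucleusRecord
    method: str
    pixels: tuple[np.ndarray, np.ndarray]

    @property
    def area(self) -> int:
        return self.record.area

    @property
    def centroid(self) -> tuple[float, float]:
        return self.record.centroid


@dataclass
class MatchResult:
    """Instance-matching outcome between a predicted and a ground-truth mask.

    Every prediction is either a TP or an FP (``tp + fp == n_pred``); split
    and merge errors are subclasses of FP.  ``assignments`` maps each
    predicted label to ``(class, matched_gt_label_or_None)`` with class in
    {"TP", "FP", "FP_split", "FP_merge"}.
    """

    tp: int
    fp: int
    fn: int
    split_errors: int
    merge_errors: int
    assignments: dict[int, tuple[str, int | None]] = field(default_factory=dict)
    unmatched_gt: set[int] = field(default_factory=set)


@dataclass(frozen=True)
class ScoreSet:
    """Recall, precision, F1 and Jaccard computed from TP/FP/FN counts."""

    recall: float
    precision: float
    f1: float
    jaccard: float


@dataclass
class SyntheticScene:
    """Ground truth label mask plus the rendered intensity image and the
    parameters that generated them."""

    gt_mask: np.ndarray
    image: np.ndarray
    params: Mapping[str, object]
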