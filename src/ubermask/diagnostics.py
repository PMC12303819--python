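"""Ground-truth-free diagnostic summaries of a segmentation.

When no annotation exists, the plausibility of a mask is judged from the
population statistics of its instances: the nucleus area distribution, a
k-nearest-neighbor density map highlighting crowded tissue regions, and
per-channel mean-intensity catalogs that flag unusually bright nuclei.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import build_catalog
from .types import NucleusRecord, validate_mask


@dataclass(frozen=True)
class DensityPoint:
    """Local nucleus density at one nucleus: ``N / (pi R^2)`` per px^2,
    with N the neighbor count and R the mean centroid distance to those
    neighbors."""

    label: int
    centroid: tuple[float, float]
    density: float


def area_histogram(
    records: Sequence[NucleusRecord], bins: int | Sequence[float] = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of nucleus areas; counts always sum to the record count."""
    if not records:
        raise ValueError("area_histogram requires at least one record")
    areas = np.array([r.area for r in records], dtype=float)
    counts, edges = np.histogram(areas, bins=bins)
    return counts, edges


def knn_density(
    records: Sequence[NucleusRecord], n_neighbors: int = 50
) -> list[DensityPoint]:
    """Per-nucleus crowding estimate from the N nearest neighbors.

    For each nucleus, R is the mean Euclidean centroid distance to its N
    nearest neighbors and the density is ``N / (pi R^2)`` — nuclei per
    square pixel within the disc that, on average, contains those
    neighbors.  Requires more than N records.
    """
    if len(records) <= n_neighbors:
        raise ValueError(
            f"knn_density needs more than {n_neighbors} records, got {len(records)}"
        )
    centers = np.array([r.centroid for r in records])
    tree = cKDTree(centers)
    # k+1 because the nearest hit is the point itself
    dists, _ = tree.query(centers, k=n_neighbors + 1)
    mean_r = dists[:, 1:].mean(axis=1)
    return [
        DensityPoint(
            label=rec.label,
            centroid=rec.centroid,
            density=n_neighbors / (math.pi * float(r) ** 2),
        )
        for rec, r in zip(records, mean_r)
    ]


def intensity_catalog(
    mask: np.ndarray,
    channels: dict[str, np.ndarray],
    bright_percentile: float = 68.0,
    method: str = "",
    percentile_over_pixels: bool = False,
) -> pd.DataFrame:
    """Per-nucleus per-channel mean intensities with bright-nucleus flags.

    A nucleus is flagged ``bright_<channel>`` when its mean intensity
    strictly exceeds the ``bright_percentile``-th percentile of the
    channel across the whole sample.  By default the percentile is taken
    over the population of per-nucleus means (it is nuclei being
    flagged); ``percentile_over_pixels=True`` switches to the raw pixel
    distribution instead.
    """
    mask = validate_mask(mask)
    catalog = build_catalog(mask, method=method, channels=channels)
    for name, ch in channels.items():
        col = f"mean_intensity_{name}"
        if len(catalog):
            ref = (
                np.percentile(np.asarray(ch), bright_percentile)
                if percentile_over_pixels
                else np.percentile(catalog[col], bright_percentile)
            )
            catalog[f"bright_{name}"] = catalog[col] > ref
        else:
            catalog[f"bright_{name}"] = pd.Series(dtype=bool)
    return catalog
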