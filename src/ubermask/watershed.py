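"""Classical watershed nuclear segmenter.

Nuclei are separated from background by smoothing plus Otsu thresholding
(Voronoi-Otsu style binarization), markers are placed at maxima of the
distance-to-background transform, and instances are grown by watershed on
the negated distance transform.  A variant runs the same machinery on an
externally supplied probability map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature, filters, measure, segmentation

from .types import validate_image


@dataclass
class WatershedConfig:
    """spot_sigma smooths the distance transform before maxima detection;
    outline_sigma smooths the intensity before thresholding; maxima closer
    than min_peak_distance are suppressed; final instances smaller than
    min_area pixels are dropped."""

    spot_sigma: float = 2.0
    outline_sigma: float = 1.0
    min_peak_distance: int = 5
    min_area: int = 4

    def __post_init__(self) -> None:
        if self.spot_sigma < 0 or self.outline_sigma < 0:
            raise ValueError("sigmas must be >= 0")
        if self.min_peak_distance < 1:
            raise ValueError("min_peak_distance must be >= 1")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")


def voronoi_otsu_binarize(
    img: np.ndarray, cfg: WatershedConfig | None = None
) -> np.ndarray:
    """Foreground/background split: Otsu threshold of the outline-smoothed
    image.  Returns a {0, 1} mask; a constant image yields all background
    with a warning."""
    cfg = cfg or WatershedConfig()
    img = validate_image(img).astype(np.float64)
    if np.ptp(img) == 0:
        warnings.warn("constant image: no foreground found", stacklevel=2)
        return np.zeros(img.shape, dtype=np.int32)
    smoothed = (
        ndimage.gaussian_filter(img, sigma=cfg.outline_sigma, mode="nearest")
        if cfg.outline_sigma > 0
        else img
    )
    if np.ptp(smoothed) == 0:
        warnings.warn("constant image after smoothing: no foreground", stacklevel=2)
        return np.zeros(img.shape, dtype=np.int32)
    threshold = filters.threshold_otsu(smoothed)
    return (smoothed > threshold).astype(np.int32)


def _markers_from_distance(
    binary: np.ndarray, cfg: WatershedConfig
) -> tuple[np.ndarray, np.ndarray, int]:
    """Distance transform of the foreground plus labeled maxima markers."""
    distance = ndimage.distance_transform_edt(binary)
    height = (
        ndimage.gaussian_filter(distance, sigma=cfg.spot_sigma, mode="nearest")
        if cfg.spot_sigma > 0
        else distance
    )
    peaks = feature.peak_local_max(
        height,
        min_distance=cfg.min_peak_distance,
        labels=binary.astype(bool).astype(np.int32),
        exclude_border=False,
    )
    markers = np.zeros(binary.shape, dtype=np.int32)
    # peaks come sorted by descending height then raster order -> deterministic
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    return distance, markers, len(peaks)


def segment_watershed(
    img: np.ndarray, cfg: WatershedConfig | None = None
) -> np.ndarray:
    """Segment nuclei: binarize, place one marker per retained maximum of the
    distance-to-background transform, grow instances by watershed restricted
    to the foreground, then drop instances below ``min_area``."""
    cfg = cfg or WatershedConfig()
    binary = voronoi_otsu_binarize(img, cfg)
    return _watershed_from_binary(binary, cfg)


def _watershed_from_binary(binary: np.ndarray, cfg: WatershedConfig) -> np.ndarray:
    if not binary.any():
        return np.zeros(binary.shape, dtype=np.int32)
    distance, markers, n_peaks = _markers_from_distance(binary, cfg)
    if n_peaks == 0:
        return np.zeros(binary.shape, dtype=np.int32)
    labels = segmentation.watershed(-distance, markers, mask=binary.astype(bool))
    if cfg.min_area > 1:
        for rp in measure.regionprops(labels):
            if rp.area < cfg.min_area:
                labels[labels == rp.label] = 0
    return labels.astype(np.int32)


def segment_probability_map(
    prob: np.ndarray, cfg: WatershedConfig | None = None
) -> np.ndarray:
    """Run the watershed segmenter on a [0, 1] probability map (e.g. the
    nucleus-class output of a pixel classifier) instead of raw intensity."""
    prob = validate_image(prob).astype(np.float64)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    return segment_watershed(prob, cfg)
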