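"""Synthetic scene generation and segmenter-failure simulation.

Renders fields of non-overlapping elliptical nuclei (roughly 6-16 px in
diameter, matching the ~10 px cell scale of imaging mass cytometry at
1 um/px) on a noisy background, and degrades the ground-truth mask the way
imperfect segmenters do: merging neighbors (under-segmentation), splitting
instances, jittering boundaries, dropping detections or shifting them —
optionally restricted to a region of the image so that different "methods"
fail in different places.  Everything is a pure function of its
configuration, seed included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy import ndimage
from skimage import draw, measure

from .types import MethodMaskSet, SyntheticScene, validate_mask

RegionPredicate = Callable[[float, float, tuple[int, int]], bool]

_REGIONS: dict[str, RegionPredicate] = {
    "all": lambda r, c, shape: True,
    "left": lambda r, c, shape: c < shape[1] / 2,
    "right": lambda r, c, shape: c >= shape[1] / 2,
    "top": lambda r, c, shape: r < shape[0] / 2,
    "bottom": lambda r, c, shape: r >= shape[0] / 2,
}


@dataclass
class SceneConfig:
    """Ground-truth field parameters.

    Axis ranges are semi-axes in pixels (defaults give 6-16 px diameters);
    intensity peaks are in photon counts so Poisson noise applies directly;
    ``background`` is the flat background count level; hot pixels are
    isolated spikes of ``hot_amplitude`` times the image maximum injected
    at ``hot_pixel_rate`` per pixel.
    """

    shape: tuple[int, int] = (256, 256)
    n_nuclei: int = 100
    minor_axis: tuple[float, float] = (3.0, 5.0)
    major_axis: tuple[float, float] = (3.0, 8.0)
    peak: tuple[float, float] = (50.0, 100.0)
    background: float = 4.0
    poisson_noise: bool = True
    gaussian_sigma: float = 0.0
    hot_pixel_rate: float = 1e-4
    hot_amplitude: float = 20.0
    min_center_separation: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.min_center_separation < 1:
            raise ValueError("min_center_separation must be >= 1")


@dataclass
class DegradationConfig:
    """One simulated failure mode applied to a fraction of the nuclei.

    ``rate`` is the fraction of (region-eligible) nuclei affected;
    ``magnitude`` the pixel scale of boundary jitter / shifts; ``region``
    restricts degradation to nuclei whose centroid satisfies the predicate
    ("all", "left", "right", "top", "bottom", or a callable)."""

    mode: Literal["perfect", "merge", "split", "jitter", "dropout", "shift"] = "perfect"
    rate: float = 0.0
    magnitude: float = 2.0
    region: str | RegionPredicate = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate <= 1.0):
            raise ValueError("rate must lie in [0, 1]")


def generate_scene(cfg: SceneConfig) -> SyntheticScene:
    """Render a ground-truth nucleus field and its intensity image.

    Nuclei are placed by bounded rejection sampling (non-overlapping, with
    a minimum center separation); each is an ellipse of random semi-axes
    and orientation with a smooth squared-cosine radial intensity profile.
    Poisson photon noise, optional Gaussian read noise and hot pixels are
    added on top of a flat background.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.shape
    mask = np.zeros((h, w), dtype=np.int32)
    signal = np.zeros((h, w), dtype=np.float64)
    centers: list[tuple[float, float]] = []
    placed = 0
    tries = 0
    max_tries = max(1000, 500 * cfg.n_nuclei)
    params = []
    while placed < cfg.n_nuclei:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {cfg.n_nuclei} nuclei in shape {cfg.shape} "
                f"after {max_tries} attempts"
            )
        b = rng.uniform(*cfg.minor_axis)  # minor semi-axis
        a = rng.uniform(*cfg.major_axis)  # major semi-axis
        if a < b:
            a, b = b, a
        theta = rng.uniform(0, math.pi)
        margin = a + 1
        cr = rng.uniform(margin, h - margin)
        cc = rng.uniform(margin, w - margin)
        if any(
            math.hypot(cr - r0, cc - c0) < cfg.min_center_separation
            for r0, c0 in centers
        ):
            continue
        rr, cc_px = draw.ellipse(cr, cc, a, b, shape=(h, w), rotation=theta)
        if rr.size == 0 or np.any(mask[rr, cc_px] > 0):
            continue
        placed += 1
        mask[rr, cc_px] = placed
        centers.append((cr, cc))
        # squared-cosine falloff of the normalized elliptical radius
        dr, dc = rr - cr, cc_px - cc
        x = dr * math.cos(theta) + dc * math.sin(theta)
        y = -dr * math.sin(theta) + dc * math.cos(theta)
        rho = np.sqrt((x / a) ** 2 + (y / b) ** 2)
        peak = rng.uniform(*cfg.peak)
        signal[rr, cc_px] += peak * np.cos(np.clip(rho, 0, 1) * math.pi / 2) ** 2
        params.append(
            {"center": (cr, cc), "axes": (a, b), "theta": theta, "peak": peak}
        )

    expected = signal + cfg.background
    image = (
        rng.poisson(expected).astype(np.float64) if cfg.poisson_noise else expected
    )
    if cfg.gaussian_sigma > 0:
        image = image + rng.normal(0, cfg.gaussian_sigma, size=image.shape)
        image = np.clip(image, 0, None)
    if cfg.hot_pixel_rate > 0:
        hot = rng.random(image.shape) < cfg.hot_pixel_rate
        image = np.where(hot, cfg.hot_amplitude * max(image.max(), 1.0), image)
    return SyntheticScene(
        gt_mask=mask,
        image=image,
        params={"config": cfg, "nuclei": params},
    )


def _region_predicate(region: str | RegionPredicate) -> RegionPredicate:
    if callable(region):
        return region
    try:
        return _REGIONS[region]
    except KeyError:
        raise ValueError(
            f"unknown region {region!r}; expected one of {sorted(_REGIONS)}"
        ) from None


def _select_instances(
    mask: np.ndarray, cfg: DegradationConfig, rng: np.random.Generator
) -> tuple[list[int], dict[int, tuple[float, float]]]:
    pred = _region_predicate(cfg.region)
    centroids = {
        rp.label: (float(rp.centroid[0]), float(rp.centroid[1]))
        for rp in measure.regionprops(mask)
    }
    eligible = sorted(
        lab for lab, (r, c) in centroids.items() if pred(r, c, mask.shape)
    )
    k = int(round(cfg.rate * len(eligible)))
    if k == 0:
        return [], centroids
    chosen = rng.choice(len(eligible), size=k, replace=False)
    return sorted(eligible[int(i)] for i in chosen), centroids


def degrade(gt: np.ndarray, cfg: DegradationConfig) -> np.ndarray:
    """Simulate one segmenter failure mode on a ground-truth mask.

    merge: fuse each selected nucleus with its nearest neighbor (a bridge
    of background pixels is painted between them, emulating an
    under-segmented blob); split: bisect across the major axis; jitter:
    dilate or erode the boundary by up to ``magnitude`` px; dropout:
    delete; shift: translate by up to ``magnitude`` px per axis.  The
    result is always a valid label mask of the same shape.
    """
    gt = validate_mask(gt)
    out = gt.copy()
    if cfg.mode == "perfect" or cfg.rate == 0.0:
        return out
    rng = np.random.default_rng(cfg.seed)
    selected, centroids = _select_instances(gt, cfg, rng)
    if not selected:
        return out

    if cfg.mode == "dropout":
        out[np.isin(out, selected)] = 0
        return out

    if cfg.mode == "merge":
        used: set[int] = set()
        for lab in selected:
            if lab in used:
                continue
            r0, c0 = centroids[lab]
            partners = [
                (math.hypot(r0 - r, c0 - c), other)
                for other, (r, c) in centroids.items()
                if other != lab and other not in used
            ]
            if not partners:
                continue
            _, partner = min(partners)
            out[out == partner] = lab
            rr, cc = draw.line(
                int(round(r0)),
                int(round(c0)),
                int(round(centroids[partner][0])),
                int(round(centroids[partner][1])),
            )
            bridge = np.zeros(out.shape, dtype=bool)
            inb = (rr >= 0) & (rr < out.shape[0]) & (cc >= 0) & (cc < out.shape[1])
            bridge[rr[inb], cc[inb]] = True
            bridge = ndimage.binary_dilation(bridge, iterations=1)
            out[bridge & (out == 0)] = lab
            used.update((lab, partner))
        return out

    if cfg.mode == "split":
        next_label = int(out.max()) + 1
        for lab in selected:
            coords = np.argwhere(gt == lab)
            if coords.shape[0] < 2:
                continue
            rp = measure.regionprops((gt == lab).astype(np.int32))[0]
            theta = rp.orientation
            # major-axis direction in (row, col); cut across it
            axis = np.array([-math.cos(theta), math.sin(theta)])
            rel = coords - np.array(rp.centroid)
            side = rel @ axis > 0
            if side.all() or (~side).all():
                side = rel[:, 0] > 0
                if side.all() or (~side).all():
                    continue
            half = coords[side]
            out[half[:, 0], half[:, 1]] = next_label
            next_label += 1
        return out

    if cfg.mode == "jitter":
        mag = max(1, int(round(cfg.magnitude)))
        for lab in selected:
            k = int(rng.integers(1, mag + 1))
            grow = bool(rng.integers(0, 2))
            inst = out == lab
            if grow:
                grown = ndimage.binary_dilation(inst, iterations=k)
                out[grown & (out == 0)] = lab
            else:
                shrunk = ndimage.binary_erosion(inst, iterations=k)
                if shrunk.any():
                    out[inst & ~shrunk] = 0
        return out

    if cfg.mode == "shift":
        mag = max(1, int(round(cfg.magnitude)))
        for lab in selected:
            dr = int(rng.integers(-mag, mag + 1))
            dc = int(rng.integers(-mag, mag + 1))
            coords = np.argwhere(out == lab)
            out[coords[:, 0], coords[:, 1]] = 0
            nr = coords[:, 0] + dr
            nc = coords[:, 1] + dc
            ok = (nr >= 0) & (nr < out.shape[0]) & (nc >= 0) & (nc < out.shape[1])
            nr, nc = nr[ok], nc[ok]
            free = out[nr, nc] == 0
            out[nr[free], nc[free]] = lab
        return out

    raise ValueError(f"unknown degradation mode {cfg.mode!r}")


@dataclass
class BenchmarkFixture:
    """One benchmark scene plus a named set of simulated method masks."""

    scene: SyntheticScene
    maskset: MethodMaskSet
    description: str = ""


def benchmark_suite(
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    n_nuclei: int = 100,
) -> dict[str, BenchmarkFixture]:
    """The canonical benchmark fixtures used throughout the test suite.

    - ``unanimity``: three identical copies of the ground truth — any
      sane consensus must return it unchanged.
    - ``complementary_halves``: method A is perfect on the left half and
      merge-degraded (rate 0.5) on the right, method B the mirror image,
      and a third method is boundary-jittered everywhere.  The third
      method never has the best mask anywhere but keeps the total-Jaccard
      vote non-degenerate (with two methods that metric is symmetric and
      ties everywhere); jitter is used because its footprint errors are
      uncorrelated with either method's merge bridges and it preserves
      nucleus counts.  A consensus that picks locally should beat every
      single method.
    - ``noisy_trio``: three methods with distinct global failure modes
      (boundary jitter rate 0.4 at 2 px, dropout rate 0.15, split rate
      0.3) — exercises overlap resolution and neighborhood robustness.
    """
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=8)]

    scene_u = generate_scene(SceneConfig(shape=shape, n_nuclei=n_nuclei, seed=sub[0]))
    unanimity = BenchmarkFixture(
        scene=scene_u,
        maskset=MethodMaskSet(
            {
                "method_a": scene_u.gt_mask.copy(),
                "method_b": scene_u.gt_mask.copy(),
                "method_c": scene_u.gt_mask.copy(),
            }
        ),
        description="three identical methods",
    )

    scene_c = generate_scene(SceneConfig(shape=shape, n_nuclei=n_nuclei, seed=sub[1]))
    gt = scene_c.gt_mask
    halves = BenchmarkFixture(
        scene=scene_c,
        maskset=MethodMaskSet(
            {
                "perfect_left": degrade(
                    gt,
                    DegradationConfig(
                        mode="merge", rate=0.5, region="right", seed=sub[2]
                    ),
                ),
                "perfect_right": degrade(
                    gt,
                    DegradationConfig(
                        mode="merge", rate=0.5, region="left", seed=sub[3]
                    ),
                ),
                "jittery_all": degrade(
                    gt,
                    DegradationConfig(
                        mode="jitter", rate=0.5, magnitude=2, region="all", seed=sub[4]
                    ),
                ),
            }
        ),
        description="complementary halves: each method perfect on one half",
    )

    scene_n = generate_scene(SceneConfig(shape=shape, n_nuclei=n_nuclei, seed=sub[5]))
    gtn = scene_n.gt_mask
    noisy = BenchmarkFixture(
        scene=scene_n,
        maskset=MethodMaskSet(
            {
                "jittery": degrade(
                    gtn,
                    DegradationConfig(
                        mode="jitter", rate=0.4, magnitude=2, seed=sub[6]
                    ),
                ),
                "droppy": degrade(
                    gtn, DegradationConfig(mode="dropout", rate=0.15, seed=sub[7])
                ),
                "splitty": degrade(
                    gtn, DegradationConfig(mode="split", rate=0.3, seed=sub[6] ^ 1)
                ),
            }
        ),
        description="three global failure modes",
    )

    return {
        "unanimity": unanimity,
        "complementary_halves": halves,
        "noisy_trio": noisy,
    }
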