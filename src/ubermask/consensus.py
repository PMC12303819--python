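"""Consensus fusion of instance segmentation masks ("uber mask").

Several segmenters produce candidate label masks of the same image.  The
image is partitioned into local neighborhoods; within each, every method is
scored by a user-chosen *metric of merit* and the winner's nuclei (those
whose centroids fall in the neighborhood) are harvested with provenance.
Harvested nuclei from different methods may overlap where neighborhoods
disagree; confirmed overlaps are re-voted among the contributing methods
and losers removed.  The survivors, relabeled contiguously, form the uber
mask: every instance in it is an exact copy of one instance from one input
mask.

Three metrics of merit are available:

- ``jaccard_total``: sum of binary Jaccard agreements with every other
  method in the neighborhood (consensus-seeking);
- ``nucleus_count``: number of nuclei detected in the neighborhood
  (counters under-segmentation);
- ``inv_log_area_sd``: ``1 / ln(sigma(A) / n)`` with ``sigma(A)`` the
  standard deviation of nucleus areas and ``n`` the count (rewards many,
  consistently sized nuclei).

A per-pixel topological voting scheme over whole-window Jaccard scores is
included as a reference implementation for cross-checks on small images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import extract_records
from .types import MethodMaskSet, NucleusRecord, ProvenancedNucleus

METRICS = ("inv_log_area_sd", "nucleus_count", "jaccard_total")

#: (row0, col0, row1, col1), half-open
Neighborhood = tuple[int, int, int, int]


@dataclass
class ConsensusConfig:
    """s: neighborhood size in pixels (square tiles); metric: the metric of
    merit; overlaps are confirmed when the true pixel overlap exceeds
    ``overlap_fraction`` of the ``area_percentile``-th percentile of
    harvested nucleus areas; min_s bounds the smallest allowed
    neighborhood."""

    s: int = 40
    metric: str = "nucleus_count"
    overlap_fraction: float = 0.05
    area_percentile: float = 32.0
    min_s: int = 20

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {self.metric!r}")
        if self.s < self.min_s:
            raise ValueError(f"neighborhood size {self.s} < minimum {self.min_s}")
        if not (0 < self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must lie in (0, 1)")
        if not (0 < self.area_percentile < 100):
            raise ValueError("area_percentile must lie in (0, 100)")


def binary_jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Sum-min over sum-max Jaccard agreement of two binarized regions.

    Any positive label counts as foreground.  Two empty regions agree
    perfectly and score 1.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    fa = a > 0
    fb = b > 0
    union = np.count_nonzero(fa | fb)
    if union == 0:
        return 1.0
    return np.count_nonzero(fa & fb) / union


def tile_neighborhoods(
    shape: tuple[int, int], s: int, min_s: int = 20
) -> list[Neighborhood]:
    """Partition a raster into non-overlapping s-by-s tiles.

    A trailing partial tile thinner than s/2 is merged into its neighbor
    (yielding an edge tile up to 1.5 s wide); otherwise it stands alone.
    """
    if s < min_s:
        raise ValueError(f"neighborhood size {s} < minimum {min_s}")
    if s > shape[0] or s > shape[1]:
        raise ValueError(f"neighborhood size {s} exceeds image shape {shape}")

    def axis_edges(dim: int) -> list[tuple[int, int]]:
        n_full, rem = divmod(dim, s)
        starts = [i * s for i in range(n_full)]
        edges = [(st, st + s) for st in starts]
        if rem:
            if rem < s / 2:
                r0, _ = edges[-1]
                edges[-1] = (r0, dim)
            else:
                edges.append((n_full * s, dim))
        return edges

    rows = axis_edges(shape[0])
    cols = axis_edges(shape[1])
    return [(r0, c0, r1, c1) for r0, r1 in rows for c0, c1 in cols]


def _records_in_region(
    records: Sequence[NucleusRecord], region: Neighborhood
) -> list[NucleusRecord]:
    r0, c0, r1, c1 = region
    return [
        rec
        for rec in records
        if r0 <= rec.centroid[0] < r1 and c0 <= rec.centroid[1] < c1
    ]


def metric_of_merit(
    method: str,
    maskset: MethodMaskSet,
    region: Neighborhood,
    metric: str,
    records: dict[str, list[NucleusRecord]] | None = None,
) -> float:
    """Score one method on one neighborhood under the chosen metric.

    ``inv_log_area_sd`` is undefined (and returns ``-inf``, so the method
    cannot win on it) when fewer than two nuclei are present, when their
    area spread is zero, or when ``sigma(A)/n == 1`` exactly.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if records is None:
        records = {m: extract_records(maskset[m], m) for m in maskset}
    r0, c0, r1, c1 = region
    if metric == "jaccard_total":
        this = maskset[method][r0:r1, c0:c1]
        return float(
            sum(
                binary_jaccard(this, maskset[other][r0:r1, c0:c1])
                for other in maskset
                if other != method
            )
        )
    local = _records_in_region(records[method], region)
    if metric == "nucleus_count":
        return float(len(local))
    # inv_log_area_sd
    n = len(local)
    if n < 2:
        return -math.inf
    sigma = float(np.std([rec.area for rec in local]))
    if sigma == 0:
        return -math.inf
    ratio = sigma / n
    log = math.log(ratio)
    if log == 0:
        return -math.inf
    return 1.0 / log


def vote_neighborhood(
    maskset: MethodMaskSet,
    region: Neighborhood,
    metric: str,
    records: dict[str, list[NucleusRecord]] | None = None,
) -> str:
    """The method with the highest metric of merit on the neighborhood;
    exact ties go to the method listed earlier in the maskset order."""
    best_method = None
    best_score = -math.inf
    for method in maskset:
        score = metric_of_merit(method, maskset, region, metric, records)
        if best_method is None or score > best_score:
            best_method = method
            best_score = score
    assert best_method is not None
    return best_method


def _pixel_sets(mask: np.ndarray) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """label -> (rows, cols) member pixel coordinates, for all labels at once."""
    flat = np.flatnonzero(mask)
    if flat.size == 0:
        return {}
    labels = mask.reshape(-1)[flat]
    order = np.argsort(labels, kind="stable")
    flat = flat[order]
    labels = labels[order]
    bounds = np.flatnonzero(np.diff(labels)) + 1
    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    ncols = mask.shape[1]
    for chunk_labels, chunk in zip(
        np.split(labels, bounds), np.split(flat, bounds)
    ):
        out[int(chunk_labels[0])] = (chunk // ncols, chunk % ncols)
    return out


def harvest(
    winner: str,
    maskset: MethodMaskSet,
    region: Neighborhood,
    records: dict[str, list[NucleusRecord]] | None = None,
    pixel_sets: dict[str, dict[int, tuple[np.ndarray, np.ndarray]]] | None = None,
) -> list[ProvenancedNucleus]:
    """All of the winner's nuclei whose centroids fall inside the half-open
    region, carrying their full pixel sets (which may spill outside it)."""
    if winner not in maskset.masks:
        raise KeyError(f"method {winner!r} not in maskset")
    if records is None:
        records = {winner: extract_records(maskset[winner], winner)}
    if pixel_sets is None:
        pixel_sets = {winner: _pixel_sets(maskset[winner])}
    return [
        ProvenancedNucleus(
            record=rec, method=winner, pixels=pixel_sets[winner][rec.label]
        )
        for rec in _records_in_region(records[winner], region)
    ]


def _overlap_area(
    a: ProvenancedNucleus, b: ProvenancedNucleus, ncols: int
) -> int:
    ia = a.pixels[0].astype(np.int64) * ncols + a.pixels[1]
    ib = b.pixels[0].astype(np.int64) * ncols + b.pixels[1]
    return int(np.intersect1d(ia, ib, assume_unique=True).size)


def detect_overlaps(
    candidates: Sequence[ProvenancedNucleus],
    cfg: ConsensusConfig,
    ncols: int | None = None,
) -> list[list[ProvenancedNucleus]]:
    """Two-stage overlap detection among harvested nuclei.

    Stage one suggests a pair when the center distance is smaller than the
    equivalent radius (circle of equal area) of the larger of the two.
    Stage two confirms the pair when the true pixel overlap strictly
    exceeds ``overlap_fraction`` times the ``area_percentile``-th
    percentile of all candidate areas.  Groups are connected components of
    confirmed pairs; nuclei from the same method can never overlap.
    """
    n = len(candidates)
    if n < 2:
        return []
    if ncols is None:
        ncols = int(max(int(c.pixels[1].max()) for c in candidates)) + 1
    centers = np.array([c.centroid for c in candidates])
    radii = np.array([c.record.equivalent_radius for c in candidates])
    area_thresh = cfg.overlap_fraction * float(
        np.percentile([c.area for c in candidates], cfg.area_percentile)
    )
    tree = cKDTree(centers)
    pairs = tree.query_pairs(r=float(radii.max()), output_type="ndarray")
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    confirmed_any = np.zeros(n, dtype=bool)
    for i, j in pairs:
        dist = float(np.hypot(*(centers[i] - centers[j])))
        if dist >= max(radii[i], radii[j]):
            continue
        if candidates[i].method == candidates[j].method:
            continue
        if _overlap_area(candidates[i], candidates[j], ncols) > area_thresh:
            pi, pj = find(int(i)), find(int(j))
            parent[pi] = pj
            confirmed_any[i] = confirmed_any[j] = True

    groups: dict[int, list[ProvenancedNucleus]] = {}
    for idx in np.flatnonzero(confirmed_any):
        groups.setdefault(find(int(idx)), []).append(candidates[int(idx)])
    return [g for g in groups.values() if len(g) >= 2]


def _group_neighborhood(
    group: Sequence[ProvenancedNucleus], shape: tuple[int, int], s: int
) -> Neighborhood:
    """Joint bounding box of the group, padded symmetrically to at least
    s-by-s and clipped to the image."""
    r0 = min(n.record.bbox[0] for n in group)
    c0 = min(n.record.bbox[1] for n in group)
    r1 = max(n.record.bbox[2] for n in group)
    c1 = max(n.record.bbox[3] for n in group)

    def pad(lo: int, hi: int, dim: int) -> tuple[int, int]:
        extra = max(0, s - (hi - lo))
        lo = lo - extra // 2
        hi = hi + (extra - extra // 2)
        if lo < 0:
            hi -= lo
            lo = 0
        if hi > dim:
            lo -= hi - dim
            hi = dim
        return max(0, lo), hi

    r0, r1 = pad(r0, r1, shape[0])
    c0, c1 = pad(c0, c1, shape[1])
    return (r0, c0, r1, c1)


def resolve_overlap(
    group: Sequence[ProvenancedNucleus],
    maskset: MethodMaskSet,
    metric: str,
    cfg: ConsensusConfig,
    records: dict[str, list[NucleusRecord]] | None = None,
) -> list[ProvenancedNucleus]:
    """Re-vote an overlap group on a neighborhood enclosing it, restricted
    to the methods that contributed a member; only the winner's members
    survive."""
    if len(group) < 2:
        raise ValueError("an overlap group needs at least two members")
    contributing = []
    for nuc in group:
        if nuc.method not in contributing:
            contributing.append(nuc.method)
    # preserve maskset order among contributors for deterministic ties
    contributing = [m for m in maskset if m in contributing]
    sub = MethodMaskSet({m: maskset[m] for m in contributing})
    region = _group_neighborhood(group, maskset.shape, cfg.s)
    if records is not None:
        records = {m: records[m] for m in contributing}
    winner = vote_neighborhood(sub, region, metric, records)
    return [nuc for nuc in group if nuc.method == winner]


def build_uber_mask(
    maskset: MethodMaskSet, cfg: ConsensusConfig | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Fuse a set of candidate masks into the consensus uber mask.

    Returns the relabeled mask (fresh contiguous labels 1..N) and a
    provenance table mapping each new label to the winning method and the
    original label in that method's mask.  Residual sub-threshold pixel
    conflicts between survivors are resolved toward the nucleus with the
    nearer centroid (ties to the lower new label).
    """
    cfg = cfg or ConsensusConfig()
    shape = maskset.shape
    records = {m: extract_records(maskset[m], m) for m in maskset}
    pixel_sets = {m: _pixel_sets(maskset[m]) for m in maskset}

    candidates: list[ProvenancedNucleus] = []
    for region in tile_neighborhoods(shape, cfg.s, cfg.min_s):
        winner = vote_neighborhood(maskset, region, cfg.metric, records)
        candidates.extend(harvest(winner, maskset, region, records, pixel_sets))

    removed: set[int] = set()
    groups = detect_overlaps(candidates, cfg, ncols=shape[1])
    ids = {id(c): i for i, c in enumerate(candidates)}
    for group in groups:
        survivors = resolve_overlap(group, maskset, cfg.metric, cfg, records)
        surviving_ids = {id(s) for s in survivors}
        removed.update(ids[id(n)] for n in group if id(n) not in surviving_ids)

    out = np.zeros(shape, dtype=np.int32)
    rows = []
    centroids: list[tuple[float, float]] = []
    new_label = 0
    for i, nuc in enumerate(candidates):
        if i in removed:
            continue
        new_label += 1
        rr, cc = nuc.pixels
        taken = out[rr, cc]
        conflict = taken > 0
        if conflict.any():
            keep = ~conflict
            cr, cc_c = nuc.centroid
            for k in np.flatnonzero(conflict):
                r, c = int(rr[k]), int(cc[k])
                other = int(taken[k])
                ocr, occ = centroids[other - 1]
                d_new = (r - cr) ** 2 + (c - cc_c) ** 2
                d_old = (r - ocr) ** 2 + (c - occ) ** 2
                if d_new < d_old:
                    keep[k] = True  # strictly nearer; ties stay with lower label
            out[rr[keep], cc[keep]] = new_label
        else:
            out[rr, cc] = new_label
        centroids.append(nuc.centroid)
        rows.append(
            {
                "label": new_label,
                "method": nuc.method,
                "source_label": nuc.record.label,
                "centroid_row": nuc.centroid[0],
                "centroid_col": nuc.centroid[1],
                "area_px": nuc.area,
            }
        )
    provenance = pd.DataFrame(
        rows,
        columns=[
            "label",
            "method",
            "source_label",
            "centroid_row",
            "centroid_col",
            "area_px",
        ],
    )
    return out, provenance


def pixel_topological_vote(maskset: MethodMaskSet, s: int) -> np.ndarray:
    """Reference per-pixel topological voting (for cross-checks only).

    For every pixel, binary Jaccard agreement is computed within the
    ±s window among all methods; the method with the lowest total
    agreement is eliminated, totals are recomputed among the remainder,
    and the pixel takes the value of the highest-scoring method.  Requires
    at least three methods (the elimination round must leave two).
    Quadratic in image size — intended for small rasters.
    """
    if len(maskset) < 3:
        raise ValueError("per-pixel topological voting requires >= 3 methods")
    methods = maskset.methods
    shape = maskset.shape
    out = np.zeros(shape, dtype=np.int32)
    for r in range(shape[0]):
        for c in range(shape[1]):
            r0, r1 = max(0, r - s), min(shape[0], r + s + 1)
            c0, c1 = max(0, c - s), min(shape[1], c + s + 1)
            windows = {m: maskset[m][r0:r1, c0:c1] for m in methods}

            def totals(active: list[str]) -> dict[str, float]:
                return {
                    m: sum(
                        binary_jaccard(windows[m], windows[o])
                        for o in active
                        if o != m
                    )
                    for m in active
                }

            t = totals(methods)
            eliminated = min(methods, key=lambda m: (t[m], -methods.index(m)))
            remaining = [m for m in methods if m != eliminated]
            t2 = totals(remaining)
            winner = max(remaining, key=lambda m: (t2[m], -remaining.index(m)))
            out[r, c] = maskset[winner][r, c]
    return out
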