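"""Instance-level scoring of predicted masks against ground truth.

A sparse IOU matrix is built over ground-truth/prediction pairs whose
centroids lie within a cutoff distance (distant nuclei cannot intersect);
predictions are then classified as true positives, plain false positives,
split errors or merge errors by thresholded best-IOU matching, and the
counts summarized as recall, precision, F1 and Jaccard scores.  A
label-expansion operator turns nuclear masks into approximate whole-cell
masks for comparison against cell-level ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure, segmentation

from .types import MatchResult, ScoreSet, validate_mask


@dataclass
class IouMatrix:
    """Sparse IOU entries keyed by (gt_label, pred_label); absent pairs are
    implicit zeros.  Entries exist only for intersecting pairs whose
    centroids are within the cutoff."""

    entries: dict[tuple[int, int], float]
    n_gt: int
    n_pred: int
    gt_labels: tuple[int, ...] = ()
    pred_labels: tuple[int, ...] = ()

    def by_pred(self) -> dict[int, dict[int, float]]:
        out: dict[int, dict[int, float]] = {}
        for (g, p), v in self.entries.items():
            out.setdefault(p, {})[g] = v
        return out


def iou_matrix(
    gt: np.ndarray, pred: np.ndarray, cutoff_px: float = 80.0
) -> IouMatrix:
    """Pairwise intersection-over-union between ground-truth and predicted
    instances.

    Pairs with centroids more than ``cutoff_px`` apart are assumed not to
    intersect and are assigned an implicit IOU of 0 (a computational
    shortcut retained even for pathologically elongated instances).
    """
    gt = validate_mask(gt)
    pred = validate_mask(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")

    gt_props = {rp.label: rp for rp in measure.regionprops(gt)}
    pred_props = {rp.label: rp for rp in measure.regionprops(pred)}

    both = (gt > 0) & (pred > 0)
    entries: dict[tuple[int, int], float] = {}
    if both.any():
        pair_ids = gt[both].astype(np.int64) * (pred.max() + 1) + pred[both]
        uniq, counts = np.unique(pair_ids, return_counts=True)
        base = int(pred.max() + 1)
        for pid, inter in zip(uniq, counts):
            g, p = int(pid // base), int(pid % base)
            cg = np.asarray(gt_props[g].centroid)
            cp = np.asarray(pred_props[p].centroid)
            if float(np.hypot(*(cg - cp))) > cutoff_px:
                continue
            union = gt_props[g].area + pred_props[p].area - int(inter)
            entries[(g, p)] = float(inter) / float(union)
    return IouMatrix(
        entries=entries,
        n_gt=len(gt_props),
        n_pred=len(pred_props),
        gt_labels=tuple(sorted(gt_props)),
        pred_labels=tuple(sorted(pred_props)),
    )


def match_nuclei(iou: IouMatrix, threshold: float = 0.1) -> MatchResult:
    """Classify predictions as TP / FP / split / merge by best-IOU matching.

    Predictions whose best IOU does not exceed ``threshold`` are plain FPs.
    Otherwise a prediction claims the ground-truth nucleus with its highest
    IOU; if that highest value (rounded half-even to two decimals) is
    shared by several ground-truth nuclei the prediction is a merge error,
    and if the claimed nucleus was already matched it is a split error —
    both count as FPs.  Ground-truth nuclei left unmatched at the end are
    FNs (this is what makes under-segmentation visible to the recall
    score: a nucleus swallowed by a merged prediction still counts as
    missed).  Predictions are processed in descending best-IOU order (ties
    by ascending label) so the strongest claim wins.
    """
    by_pred = iou.by_pred()
    order = sorted(
        iou.pred_labels,
        key=lambda p: (-max(by_pred.get(p, {}).values(), default=0.0), p),
    )
    matched_gt: set[int] = set()
    assignments: dict[int, tuple[str, int | None]] = {}
    tp = fp = splits = merges = 0
    for p in order:
        row = by_pred.get(p, {})
        best = max(row.values(), default=0.0)
        if best <= threshold:
            fp += 1
            assignments[p] = ("FP", None)
            continue
        rounded_best = np.round(best, 2)
        contenders = [g for g, v in row.items() if np.round(v, 2) == rounded_best]
        if len(contenders) > 1:
            fp += 1
            merges += 1
            assignments[p] = ("FP_merge", None)
            continue
        g = max(row, key=lambda k: (row[k], -k))
        if g in matched_gt:
            fp += 1
            splits += 1
            assignments[p] = ("FP_split", g)
        else:
            tp += 1
            matched_gt.add(g)
            assignments[p] = ("TP", g)
    unmatched = {g for g in iou.gt_labels if g not in matched_gt}
    return MatchResult(
        tp=tp,
        fp=fp,
        fn=len(unmatched),
        split_errors=splits,
        merge_errors=merges,
        assignments=assignments,
        unmatched_gt=unmatched,
    )


def scores(match: MatchResult) -> ScoreSet:
    """Recall, precision, F1 and Jaccard from the TP/FP/FN tallies.

    recall = TP/(TP+FN); precision = TP/(TP+FP);
    F1 = 2 P R / (P + R); Jaccard = TP/(TP+FP+FN).
    """
    tp, fp, fn = match.tp, match.fp, match.fn
    if tp + fn == 0 or tp + fp == 0:
        raise ValueError("scores undefined: zero denominator (no instances?)")
    recall = tp / (tp + fn)
    precision = tp / (tp + fp)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    jaccard = tp / (tp + fp + fn)
    return ScoreSet(recall=recall, precision=precision, f1=f1, jaccard=jaccard)


def evaluate_masks(
    gt: np.ndarray,
    pred: np.ndarray,
    threshold: float = 0.1,
    cutoff_px: float = 80.0,
    expand_px: int = 0,
) -> tuple[ScoreSet, MatchResult]:
    """Convenience wrapper: optional label expansion, IOU matrix, matching
    and scoring in one call."""
    if expand_px:
        pred = expand_labels(pred, expand_px)
    match = match_nuclei(iou_matrix(gt, pred, cutoff_px), threshold)
    return scores(match), match


def expand_labels(mask: np.ndarray, d_px: float) -> np.ndarray:
    """Grow every instance outward by up to ``d_px`` (Euclidean) into the
    background; instances never merge — each background pixel joins its
    nearest instance, with equidistant pixels resolved deterministically by
    the distance transform's nearest-feature choice."""
    mask = validate_mask(mask)
    if d_px < 0:
        raise ValueError("expansion distance must be >= 0")
    if d_px == 0:
        return mask.copy()
    return segmentation.expand_labels(mask, distance=d_px)


def compare_methods(
    scoresets: Mapping[str, Sequence[ScoreSet]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize per-image scores across methods and test pairwise
    differences.

    Returns (summary, pairwise): ``summary`` holds per-method medians and
    mean-absolute-deviation error bars for each score; ``pairwise`` one row
    per method pair with the Wilcoxon signed-rank p-value on the
    concatenated Jaccard and F1 scores and the median paired difference.
    Score lists must be paired (same images, same order, same length).
    """
    methods = list(scoresets)
    if len(methods) < 2:
        raise ValueError("compare_methods needs at least two methods")
    lengths = {len(v) for v in scoresets.values()}
    if len(lengths) != 1:
        raise ValueError("score lists must be paired across methods")

    def mad(x: np.ndarray) -> float:
        return float(np.mean(np.abs(x - np.mean(x))))

    rows = []
    for m, sets in scoresets.items():
        for name in ("recall", "precision", "f1", "jaccard"):
            vals = np.array([getattr(s, name) for s in sets])
            rows.append(
                {
                    "method": m,
                    "score": name,
                    "median": float(np.median(vals)),
                    "mad": mad(vals),
                }
            )
    summary = pd.DataFrame(rows)

    pair_rows = []
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            xa = np.concatenate(
                [
                    [s.jaccard for s in scoresets[a]],
                    [s.f1 for s in scoresets[a]],
                ]
            )
            xb = np.concatenate(
                [
                    [s.jaccard for s in scoresets[b]],
                    [s.f1 for s in scoresets[b]],
                ]
            )
            diff = xa - xb
            if np.all(diff == 0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(xa, xb).pvalue)
            pair_rows.append(
                {
                    "method_a": a,
                    "method_b": b,
                    "wilcoxon_p": p,
                    "median_diff": float(np.median(diff)),
                }
            )
    pairwise = pd.DataFrame(pair_rows)
    return summary, pairwise
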