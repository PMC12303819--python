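import numpy as np
import pytest

from ubermask import SceneConfig, generate_scene
from ubermask.consensus import _pixel_sets


@pytest.fixture(scope="session")
def small_scene():
    """A reproducible 128x128 scene with 25 nuclei."""
    return generate_scene(SceneConfig(shape=(128, 128), n_nuclei=25, seed=7))


@pytest.fixture
def toy_mask():
    """Hand-built 8x8 mask with labels 2 (area 3) and 5 (area 7)."""
    m = np.zeros((8, 8), dtype=np.int32)
    m[0, 0:3] = 2
    m[4:5, 0:7] = 5
    return m


def dense_match_oracle(gt, pred, threshold=0.1, cutoff=80.0):
    """Brute-force reimplementation of instance matching on a dense
    all-pairs IOU matrix, independent of the library code path.

    Every (gt, pred) IOU is computed from explicit pixel sets; the matching
    rules (best-IOU claim, 2-dp merge ties, split errors, unmatched-gt FNs)
    are applied from scratch.
    """

    def instances(mask):
        out = {}
        for lab in np.unique(mask):
            if lab == 0:
                continue
            coords = set(map(tuple, np.argwhere(mask == lab)))
            centroid = np.mean(np.array(sorted(coords)), axis=0)
            out[int(lab)] = (coords, centroid)
        return out

    g, p = instances(gt), instances(pred)
    dense = {}
    for gl, (gset, gc) in g.items():
        for pl, (pset, pc) in p.items():
            if np.hypot(*(gc - pc)) > cutoff:
                continue
            inter = len(gset & pset)
            if inter:
                dense[(gl, pl)] = inter / len(gset | pset)
    order = sorted(
        p,
        key=lambda pl: (
            -max((v for (g_, p_), v in dense.items() if p_ == pl), default=0.0),
            pl,
        ),
    )
    matched, tp, fp, splits, merges = set(), 0, 0, 0, 0
    for pl in order:
        row = {g_: v for (g_, p_), v in dense.items() if p_ == pl}
        best = max(row.values(), default=0.0)
        if best <= threshold:
            fp += 1
            continue
        rb = np.round(best, 2)
        if sum(np.round(v, 2) == rb for v in row.values()) > 1:
            fp += 1
            merges += 1
            continue
        gl = max(row, key=lambda k: (row[k], -k))
        if gl in matched:
            fp += 1
            splits += 1
        else:
            tp += 1
            matched.add(gl)
    fn = len(set(g) - matched)
    return tp, fp, fn, splits, merges


def masks_equal_up_to_relabel(a: np.ndarray, b: np.ndarray) -> bool:
    """True when the two masks contain exactly the same instance pixel sets."""
    if a.shape != b.shape or not np.array_equal(a > 0, b > 0):
        return False
    sets_a = {frozenset(zip(rr.tolist(), cc.tolist())) for rr, cc in _pixel_sets(a).values()}
    sets_b = {frozenset(zip(rr.tolist(), cc.tolist())) for rr, cc in _pixel_sets(b).values()}
    return sets_a == sets_b
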