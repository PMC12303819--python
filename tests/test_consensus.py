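import math

import numpy as np
import pandas as pd
import pytest

from ubermask import (
    ConsensusConfig,
    MethodMaskSet,
    benchmark_suite,
    binary_jaccard,
    build_uber_mask,
    detect_overlaps,
    extract_records,
    harvest,
    metric_of_merit,
    pixel_topological_vote,
    resolve_overlap,
    tile_neighborhoods,
    vote_neighborhood,
)
from ubermask.consensus import _pixel_sets
from ubermask.types import NucleusRecord, ProvenancedNucleus

from conftest import masks_equal_up_to_relabel


def square_nucleus(label, r0, c0, size, shape):
    m = np.zeros(shape, dtype=np.int32)
    m[r0 : r0 + size, c0 : c0 + size] = label
    return m


def provenanced(mask, method):
    ps = _pixel_sets(mask)
    return [
        ProvenancedNucleus(record=rec, method=method, pixels=ps[rec.label])
        for rec in extract_records(mask, method)
    ]


class TestBinaryJaccard:
    def test_identical_nonempty(self):
        a = np.array([[1, 0], [2, 0]])
        assert binary_jaccard(a, a) == 1.0

    def test_disjoint(self):
        a = np.array([[1, 0], [0, 0]])
        b = np.array([[0, 0], [0, 3]])
        assert binary_jaccard(a, b) == 0.0

    def test_row_vs_column(self):
        a = np.zeros((2, 2)); a[0, :] = 1
        b = np.zeros((2, 2)); b[:, 0] = 1
        assert binary_jaccard(a, b) == pytest.approx(1 / 3)

    def test_both_empty_is_perfect_agreement(self):
        z = np.zeros((3, 3))
        assert binary_jaccard(z, z) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            binary_jaccard(np.zeros((2, 2)), np.zeros((3, 3)))


class TestMetricOfMerit:
    def test_three_identical_methods_jaccard_total_is_two(self, small_scene):
        gt = small_scene.gt_mask
        ms = MethodMaskSet({"a": gt, "b": gt.copy(), "c": gt.copy()})
        region = (0, 0, *gt.shape)
        assert metric_of_merit("a", ms, region, "jaccard_total") == pytest.approx(2.0)

    def test_nucleus_count_counts_centroids_in_region(self, small_scene):
        gt = small_scene.gt_mask
        ms = MethodMaskSet({"a": gt})
        region = (0, 0, *gt.shape)
        n = metric_of_merit("a", ms, region, "nucleus_count")
        assert n == len(extract_records(gt))

    def test_inv_log_area_sd_value(self):
        # areas 10 and 10 + d; sigma = d/2, n = 2; metric = 1/ln(d/4)
        shape = (40, 80)
        m = np.zeros(shape, dtype=np.int32)
        m[0:2, 0:5] = 1       # area 10
        m[10:12, 0:15] = 2    # area 30 -> d = 20, sigma/n = 5
        ms = MethodMaskSet({"a": m})
        got = metric_of_merit("a", ms, (0, 0, *shape), "inv_log_area_sd")
        assert got == pytest.approx(1.0 / math.log(5.0))

    @pytest.mark.parametrize(
        "areas",
        [
            [9],            # n < 2
            [9, 9],         # sigma = 0
            [10, 14],       # sigma/n = 1 -> ln = 0
        ],
    )
    def test_inv_log_area_sd_guards(self, areas):
        shape = (50, 120)
        m = np.zeros(shape, dtype=np.int32)
        for i, a in enumerate(areas):
            m[i * 5 : i * 5 + 1, 0:a] = i + 1
        ms = MethodMaskSet({"a": m})
        assert metric_of_merit("a", ms, (0, 0, *shape), "inv_log_area_sd") == -math.inf

    def test_negative_metric_allowed_below_unity_ratio(self):
        # areas 10 and 12: sigma = 1, n = 2 -> ratio 0.5, metric 1/ln(0.5) < 0
        shape = (30, 40)
        m = np.zeros(shape, dtype=np.int32)
        m[0:2, 0:5] = 1
        m[10:12, 0:6] = 2
        ms = MethodMaskSet({"a": m})
        got = metric_of_merit("a", ms, (0, 0, *shape), "inv_log_area_sd")
        assert got == pytest.approx(1.0 / math.log(0.5))
        assert got < 0


class TestTileNeighborhoods:
    def test_exact_tiling(self):
        tiles = tile_neighborhoods((80, 80), 40)
        assert len(tiles) == 4
        assert all(r1 - r0 == 40 and c1 - c0 == 40 for r0, c0, r1, c1 in tiles)

    def test_single_tile(self):
        assert tile_neighborhoods((40, 40), 40) == [(0, 0, 40, 40)]

    def test_thin_remainder_merged(self):
        # 90 = 2*40 + 10; 10 < 20 -> merged into the last tile (50 wide)
        tiles = tile_neighborhoods((90, 40), 40)
        rows = sorted({(r0, r1) for r0, c0, r1, c1 in tiles})
        assert rows == [(0, 40), (40, 90)]

    def test_wide_remainder_kept(self):
        # 512 = 12*40 + 32; 32 >= 20 -> the remainder stands alone
        tiles = tile_neighborhoods((512, 512), 40)
        assert len(tiles) == 13 * 13
        rows = sorted({(r0, r1) for r0, c0, r1, c1 in tiles})
        assert rows[-1] == (480, 512)

    def test_tiles_partition_raster(self):
        for shape, s in [((100, 130), 40), ((256, 256), 20), ((90, 91), 30)]:
            cover = np.zeros(shape, dtype=int)
            for r0, c0, r1, c1 in tile_neighborhoods(shape, s, min_s=20):
                cover[r0:r1, c0:c1] += 1
            assert np.all(cover == 1)

    def test_oversized_neighborhood_errors(self):
        with pytest.raises(ValueError):
            tile_neighborhoods((30, 100), 40, min_s=20)


class TestVoteAndHarvest:
    def test_single_method_wins(self, small_scene):
        ms = MethodMaskSet({"only": small_scene.gt_mask})
        assert vote_neighborhood(ms, (0, 0, 64, 64), "nucleus_count") == "only"

    def test_argmax_on_count(self):
        shape = (60, 60)
        a = np.zeros(shape, dtype=np.int32)
        for i in range(5):
            a[i * 10 : i * 10 + 2, 0:2] = i + 1
        b = np.zeros(shape, dtype=np.int32)
        for i in range(3):
            b[i * 10 : i * 10 + 2, 10:12] = i + 1
        ms = MethodMaskSet({"A": a, "B": b})
        assert vote_neighborhood(ms, (0, 0, *shape), "nucleus_count") == "A"

    def test_exact_tie_prefers_earlier_method(self, small_scene):
        gt = small_scene.gt_mask
        ms = MethodMaskSet({"zeta": gt, "alpha": gt.copy()})
        # identical masks tie on every metric; configured order wins
        for metric in ("nucleus_count", "jaccard_total"):
            assert vote_neighborhood(ms, (0, 0, 64, 64), metric) == "zeta"

    def test_harvest_half_open_edges(self):
        shape = (80, 80)
        m = np.zeros(shape, dtype=np.int32)
        m[39:42, 10:13] = 1   # centroid row = 40.0 -> on the high edge of tile rows 0:40
        ms = MethodMaskSet({"A": m})
        low = harvest("A", ms, (40, 0, 80, 80))
        high = harvest("A", ms, (0, 0, 40, 80))
        assert [p.record.label for p in low] == [1]
        assert high == []

    def test_instance_harvested_once_by_owning_tile(self):
        shape = (80, 80)
        m = np.zeros(shape, dtype=np.int32)
        m[35:45, 35:45] = 1  # straddles four tiles, centroid in one
        ms = MethodMaskSet({"A": m})
        total = []
        for region in tile_neighborhoods(shape, 40):
            total += harvest("A", ms, region)
        assert len(total) == 1
        # full pixel set included even though it spills outside the tile
        assert total[0].pixels[0].size == 100

    def test_empty_mask_harvests_nothing(self):
        ms = MethodMaskSet({"A": np.zeros((40, 40), dtype=np.int32)})
        assert harvest("A", ms, (0, 0, 40, 40)) == []


class TestDetectOverlaps:
    @staticmethod
    def candidate(method, centroid, pixel_blocks):
        """Candidate with an explicit centroid and pixel set (rows, cols)."""
        rr = np.concatenate([np.repeat(np.arange(a, b), d - c) for a, b, c, d in pixel_blocks])
        cc = np.concatenate([np.tile(np.arange(c, d), b - a) for a, b, c, d in pixel_blocks])
        bbox = (int(rr.min()), int(cc.min()), int(rr.max()) + 1, int(cc.max()) + 1)
        rec = NucleusRecord(
            label=1, method=method, centroid=centroid, area=rr.size, bbox=bbox
        )
        return ProvenancedNucleus(record=rec, method=method, pixels=(rr, cc))

    def pair_with_overlap(self, n_overlap):
        """Two area-100 candidates with nearby centers sharing n_overlap px.

        Both areas are 100, so the 32nd-percentile area is 100 and the
        confirmation threshold is 5 px; centers are 2 px apart, well within
        the equivalent radius sqrt(100/pi) ~ 5.64 px.
        """
        x = self.candidate("A", (5.0, 5.0), [(0, 10, 0, 10)])
        y = self.candidate(
            "B",
            (7.0, 5.0),
            [(0, 1, 0, n_overlap), (20, 29, 0, 10), (40, 41, 0, 10 - n_overlap)],
        )
        assert x.area == 100 and y.area == 100
        return [x, y]

    def test_confirmed_above_threshold(self):
        groups = detect_overlaps(self.pair_with_overlap(6), ConsensusConfig(), ncols=40)
        assert len(groups) == 1 and len(groups[0]) == 2

    def test_boundary_overlap_not_confirmed(self):
        """Overlap of exactly 5 px = 5% of P32 fails the strictly-greater rule."""
        assert detect_overlaps(self.pair_with_overlap(5), ConsensusConfig(), ncols=40) == []

    def test_same_method_never_grouped(self):
        shape = (40, 60)
        m = square_nucleus(1, 10, 10, 10, shape)
        m[10:20, 21:31] = 2
        cands = provenanced(m, "A")
        assert detect_overlaps(cands, ConsensusConfig(), ncols=60) == []

    def test_distant_nuclei_not_suggested(self):
        shape = (40, 120)
        a = square_nucleus(1, 10, 10, 10, shape)
        b = square_nucleus(1, 10, 90, 10, shape)
        cands = provenanced(a, "A") + provenanced(b, "B")
        assert detect_overlaps(cands, ConsensusConfig(), ncols=120) == []


class TestResolveOverlap:
    def overlapping_maskset(self):
        """A and B share one overlapping nucleus; A carries two extra nuclei
        inside the re-vote neighborhood so it wins on nucleus_count."""
        shape = (60, 60)
        a = np.zeros(shape, dtype=np.int32)
        a[20:30, 20:30] = 1
        a[10:14, 20:24] = 2
        a[36:40, 20:24] = 3
        b = np.zeros(shape, dtype=np.int32)
        b[20:30, 24:34] = 1
        b[40:50, 40:50] = 2
        return MethodMaskSet({"A": a, "B": b})

    def test_winner_members_survive(self):
        ms = self.overlapping_maskset()
        cands = provenanced(ms["A"], "A") + provenanced(ms["B"], "B")
        cfg = ConsensusConfig()
        groups = detect_overlaps(cands, cfg, ncols=60)
        assert len(groups) == 1
        survivors = resolve_overlap(groups[0], ms, "nucleus_count", cfg)
        assert {s.method for s in survivors} == {"A"}

    def test_no_confirmed_overlap_after_resolution(self):
        ms = self.overlapping_maskset()
        cands = provenanced(ms["A"], "A") + provenanced(ms["B"], "B")
        cfg = ConsensusConfig()
        groups = detect_overlaps(cands, cfg, ncols=60)
        survivors = resolve_overlap(groups[0], ms, "nucleus_count", cfg)
        kept = [c for c in cands if c not in groups[0] or c in survivors]
        assert detect_overlaps(kept, cfg, ncols=60) == []

    def test_group_of_one_rejected(self):
        ms = self.overlapping_maskset()
        cands = provenanced(ms["A"], "A")
        with pytest.raises(ValueError):
            resolve_overlap(cands[:1], ms, "nucleus_count", ConsensusConfig())


class TestBuildUberMask:
    @pytest.mark.parametrize("metric", ["inv_log_area_sd", "nucleus_count", "jaccard_total"])
    def test_unanimous_consensus_returns_input(self, small_scene, metric):
        gt = small_scene.gt_mask
        ms = MethodMaskSet({"a": gt, "b": gt.copy(), "c": gt.copy()})
        uber, prov = build_uber_mask(ms, ConsensusConfig(metric=metric, s=32))
        assert masks_equal_up_to_relabel(uber, gt)

    def test_single_method_identity(self, small_scene):
        gt = small_scene.gt_mask
        uber, prov = build_uber_mask(MethodMaskSet({"only": gt}), ConsensusConfig(s=32))
        assert masks_equal_up_to_relabel(uber, gt)
        assert set(prov["method"]) == {"only"}

    def test_provenance_completeness(self):
        """Every uber instance's pixel set equals one instance of one input."""
        fx = benchmark_suite(5, shape=(128, 128), n_nuclei=30)["noisy_trio"]
        uber, prov = build_uber_mask(fx.maskset, ConsensusConfig(s=32))
        source_sets = {
            method: {
                lab: frozenset(zip(*map(lambda a: a.tolist(), px)))
                for lab, px in _pixel_sets(fx.maskset[method]).items()
            }
            for method in fx.maskset
        }
        uber_sets = _pixel_sets(uber)
        assert len(prov) == len(uber_sets)
        for row in prov.itertuples():
            got = frozenset(
                zip(*map(lambda a: a.tolist(), uber_sets[row.label]))
            )
            src = source_sets[row.method][row.source_label]
            # rasterization may shave contested pixels off, never add any
            assert got <= src
            assert len(got) >= 0.5 * len(src)

    def test_fresh_contiguous_labels(self):
        fx = benchmark_suite(6, shape=(128, 128), n_nuclei=30)["noisy_trio"]
        uber, prov = build_uber_mask(fx.maskset, ConsensusConfig(s=32))
        labels = sorted(int(l) for l in np.unique(uber) if l > 0)
        assert labels == list(range(1, len(labels) + 1))
        assert sorted(prov["label"]) == labels

    def test_deterministic(self):
        fx = benchmark_suite(7, shape=(128, 128), n_nuclei=30)["noisy_trio"]
        u1, p1 = build_uber_mask(fx.maskset, ConsensusConfig(s=32))
        u2, p2 = build_uber_mask(fx.maskset, ConsensusConfig(s=32))
        assert np.array_equal(u1, u2)
        pd.testing.assert_frame_equal(p1, p2)

    def test_complementary_halves_beats_both_parents(self):
        fx = benchmark_suite(11)["complementary_halves"]
        from ubermask import evaluate_masks

        gt = fx.scene.gt_mask
        f1 = {
            name: evaluate_masks(gt, fx.maskset[name])[0].f1
            for name in ("perfect_left", "perfect_right")
        }
        uber, _ = build_uber_mask(fx.maskset, ConsensusConfig(metric="nucleus_count"))
        assert evaluate_masks(gt, uber)[0].f1 > max(f1.values())


class TestPixelTopologicalVote:
    def test_three_identical_methods_identity(self, small_scene):
        crop = small_scene.gt_mask[:24, :24]
        ms = MethodMaskSet({"a": crop, "b": crop.copy(), "c": crop.copy()})
        assert np.array_equal(pixel_topological_vote(ms, s=4), crop)

    def test_requires_three_methods(self):
        z = np.zeros((4, 4), dtype=np.int32)
        with pytest.raises(ValueError, match=">= 3"):
            pixel_topological_vote(MethodMaskSet({"a": z, "b": z.copy()}), s=1)

    def test_matches_exhaustive_hand_computation(self):
        """5x5 masks: per-pixel winners equal a brute-force reimplementation."""
        rng = np.random.default_rng(2)
        masks = {
            name: (rng.random((5, 5)) < 0.5).astype(np.int32)
            for name in ("m0", "m1", "m2")
        }
        ms = MethodMaskSet(masks)
        s = 1
        got = pixel_topological_vote(ms, s=s)
        names = list(masks)
        expect = np.zeros((5, 5), dtype=np.int32)
        for r in range(5):
            for c in range(5):
                win = {}
                r0, r1 = max(0, r - s), min(5, r + s + 1)
                c0, c1 = max(0, c - s), min(5, c + s + 1)
                w = {n: masks[n][r0:r1, c0:c1] > 0 for n in names}

                def tot(active):
                    out = {}
                    for n in active:
                        t = 0.0
                        for o in active:
                            if o == n:
                                continue
                            union = (w[n] | w[o]).sum()
                            t += 1.0 if union == 0 else (w[n] & w[o]).sum() / union
                        out[n] = t
                    return out

                t1 = tot(names)
                worst = min(t1.values())
                elim = [n for n in names if t1[n] == worst][-1]
                rest = [n for n in names if n != elim]
                t2 = tot(rest)
                best = max(t2.values())
                winner = [n for n in rest if t2[n] == best][0]
                expect[r, c] = masks[winner][r, c]
        assert np.array_equal(got, expect)

    def test_everywhere_disagreeing_method_eliminated(self):
        base = np.zeros((6, 6), dtype=np.int32)
        base[2:4, 2:4] = 1
        contrarian = 1 - (base > 0).astype(np.int32)
        ms = MethodMaskSet({"a": base, "b": base.copy(), "c": contrarian})
        out = pixel_topological_vote(ms, s=2)
        assert np.array_equal(out, base)
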