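"""Quantification tests: threshold semantics, labelling, partition, summary."""

import math

import numpy as np
import pytest

from myoagg.roiquant import (
    QuantConfig,
    ROIStats,
    aggregate_mouse,
    classify_inclusions,
    filter_debris,
    grid_rois,
    label_objects,
    partition_signal,
    quantify_roi,
    summarize_roi,
    threshold_channel,
)


def flood_fill_count(mask: np.ndarray, connectivity: int) -> int:
    """Independent connected-component count by iterative flood fill."""
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(mask, dtype=bool)
    count = 0
    nrows, ncols = mask.shape
    for r in range(nrows):
        for c in range(ncols):
            if mask[r, c] and not seen[r, c]:
                count += 1
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    for dr, dc in steps:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < nrows and 0 <= nc < ncols:
                            if mask[nr, nc] and not seen[nr, nc]:
                                seen[nr, nc] = True
                                stack.append((nr, nc))
    return count


class TestThreshold:
    @pytest.mark.parametrize(
        "intensity,threshold,expect_any,expect_all",
        [
            (89, 90, False, False),  # just below: excluded
            (90, 90, True, True),  # at threshold: retained
            (0, 0, True, True),  # zero threshold keeps everything
        ],
    )
    def test_boundary_semantics(self, intensity, threshold, expect_any, expect_all):
        img = np.full((8, 8), intensity, dtype=np.uint8)
        mask = threshold_channel(img, threshold)
        assert mask.any() == expect_any
        assert mask.all() == expect_all

    def test_out_of_range_threshold(self):
        with pytest.raises(ValueError):
            threshold_channel(np.zeros((4, 4), np.uint8), 300)

    def test_raising_threshold_never_grows_foreground(self, rng):
        img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        counts = [threshold_channel(img, t).sum() for t in range(0, 256, 15)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestLabelObjects:
    def test_diagonal_pixels_connectivity(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = True
        assert label_objects(mask, 8).n_objects == 1
        assert label_objects(mask, 4).n_objects == 2

    def test_empty_mask(self):
        objs = label_objects(np.zeros((5, 5), bool), 8)
        assert objs.n_objects == 0 and not objs.mask.any()

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        for _ in range(20):
            mask = rng.random((64, 64)) < 0.35
            assert label_objects(mask, connectivity).n_objects == flood_fill_count(
                mask, connectivity
            )

    def test_labels_partition_foreground(self, rng):
        mask = rng.random((64, 64)) < 0.4
        objs = label_objects(mask, 8)
        assert objs.sizes().sum() == mask.sum()
        covered = np.zeros_like(mask)
        for o in objs.objects:
            assert not covered[o.rows, o.cols].any()
            covered[o.rows, o.cols] = True
        assert np.array_equal(covered, mask)


class TestFilterDebris:
    def _square(self, side, at, shape=(32, 32)):
        mask = np.zeros(shape, bool)
        mask[at[0] : at[0] + side, at[1] : at[1] + side] = True
        return mask

    def test_below_min_removed_at_min_retained(self):
        mask = np.zeros((32, 32), bool)
        mask[1:5, 1:7] = True  # 24 px
        mask[10:15, 10:15] = True  # 25 px
        objs = label_objects(mask, 8)
        kept = filter_debris(objs, 25)
        assert kept.n_objects == 1
        assert kept.objects[0].n_pixels == 25

    def test_min_one_is_identity(self, rng):
        mask = rng.random((32, 32)) < 0.3
        objs = label_objects(mask, 8)
        assert filter_debris(objs, 1).n_objects == objs.n_objects

    def test_raising_min_never_increases_count(self, rng):
        mask = rng.random((64, 64)) < 0.4
        objs = label_objects(mask, 8)
        counts = [filter_debris(objs, m).n_objects for m in (1, 5, 10, 25, 50)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_invalid_min(self):
        with pytest.raises(ValueError):
            filter_debris(label_objects(np.zeros((4, 4), bool), 8), 0)


class TestPartitionSignal:
    def test_disjoint_masks(self):
        s830 = np.zeros((10, 10), bool)
        s830[:2] = True
        nuc = np.zeros((10, 10), bool)
        nuc[5:] = True
        assert partition_signal(s830, nuc) == (0, 20)

    def test_signal_inside_nuclei(self):
        nuc = np.ones((10, 10), bool)
        s830 = np.zeros((10, 10), bool)
        s830[3:5, 3:5] = True
        assert partition_signal(s830, nuc) == (4, 0)

    def test_pixel_conservation_random(self, rng):
        for _ in range(25):
            s830 = rng.random((48, 48)) < 0.3
            nuc = rng.random((48, 48)) < 0.4
            intra, extra = partition_signal(s830, nuc)
            assert intra + extra == s830.sum()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            partition_signal(np.zeros((4, 4), bool), np.zeros((5, 5), bool))

    def test_matches_simulator_truth_exactly(self, simulated_rois, sim_config):
        for dapi, s830, truth in simulated_rois[:10]:
            s_mask = threshold_channel(s830, 50)
            n_mask = threshold_channel(dapi, 90)
            intra, extra = partition_signal(s_mask, n_mask)
            assert 100 * intra / (intra + extra) == pytest.approx(
                truth.true_pct_signal_nuclear, abs=1e-12
            )


class TestClassifyInclusions:
    def _straddling_fixture(self):
        # nucleus occupies columns 0-4; a 2x5 inclusion spans columns 2-6:
        # 6 px inside (60%), 4 px outside (40%)
        nuc = np.zeros((10, 10), bool)
        nuc[:, :5] = True
        s830 = np.zeros((10, 10), bool)
        s830[4:6, 2:7] = True
        return label_objects(s830, 8), nuc

    def test_straddling_object_pixel_partition(self):
        objs, nuc = self._straddling_fixture()
        out = classify_inclusions(objs, nuc, "pixel-partition")
        sizes = sorted((i.compartment, i.n_pixels) for i in out)
        assert sizes == [("cytoplasmic", 4), ("nuclear", 6)]

    def test_straddling_object_majority(self):
        objs, nuc = self._straddling_fixture()
        out = classify_inclusions(objs, nuc, "majority")
        assert len(out) == 1
        assert out[0].compartment == "nuclear" and out[0].n_pixels == 10
        assert out[0].n_pixels_in_nucleus == 6

    def test_fully_inside_object_both_rules(self):
        nuc = np.ones((8, 8), bool)
        s830 = np.zeros((8, 8), bool)
        s830[2:4, 2:4] = True
        objs = label_objects(s830, 8)
        for rule in ("pixel-partition", "majority"):
            out = classify_inclusions(objs, nuc, rule)
            assert [(i.compartment, i.n_pixels) for i in out] == [("nuclear", 4)]

    def test_rules_agree_with_simulator_truth(self, simulated_rois, sim_config):
        """With no straddling objects both rules recover the exact
        ground-truth compartment counts."""
        for dapi, s830, truth in simulated_rois[:5]:
            n_mask = threshold_channel(dapi, 90)
            objs = label_objects(threshold_channel(s830, 50), 8)
            want = sorted(
                (o.compartment, o.n_pixels) for o in truth.inclusions
            )
            for rule in ("pixel-partition", "majority"):
                got = sorted((i.compartment, i.n_pixels) for i in
                             classify_inclusions(objs, n_mask, rule))
                assert got == want

    def test_unknown_rule(self):
        objs, nuc = self._straddling_fixture()
        with pytest.raises(ValueError):
            classify_inclusions(objs, nuc, "plurality")


class TestSummarizeRoi:
    def test_no_inclusions_fields_undefined(self):
        mask = np.zeros((32, 32), bool)
        mask[2:8, 2:8] = True
        nuclei = label_objects(mask, 8)
        stats = summarize_roi(nuclei, [])
        assert stats.n_nuclei == 1 and stats.n_inclusions == 0
        assert math.isnan(stats.mean_inclusion_px)
        assert math.isnan(stats.pct_signal_colocalized)
        assert math.isnan(stats.pct_nuclei_with_inclusions)

    def test_mean_nucleus_size(self):
        mask = np.zeros((40, 40), bool)
        # four squares: 30, 30, 50(5x10), 50 px
        mask[0:5, 0:6] = True
        mask[0:5, 10:16] = True
        mask[10:15, 0:10] = True
        mask[20:25, 0:10] = True
        nuclei = label_objects(mask, 8)
        assert summarize_roi(nuclei, []).mean_nucleus_px == pytest.approx(40.0)

    def test_matches_ground_truth_on_simulated_roi(self, simulated_rois, sim_config):
        for dapi, s830, truth in simulated_rois[:5]:
            stats, nuclei, _ = quantify_roi(dapi, s830, QuantConfig())
            nuclear = [o for o in truth.inclusions if o.compartment == "nuclear"]
            assert stats.n_nuclei == len(truth.nuclei)
            assert stats.n_inclusions == len(truth.inclusions)
            assert stats.n_nuclear_inclusions == len(nuclear)
            assert stats.mean_nucleus_px == pytest.approx(
                np.mean([o.n_pixels for o in truth.nuclei])
            )
            assert stats.pct_signal_colocalized == pytest.approx(
                truth.true_pct_signal_nuclear
            )
            assert stats.pct_inclusions_nuclear == pytest.approx(
                100 * len(nuclear) / len(truth.inclusions)
            )
            assert stats.mean_nuclear_inclusion_px == pytest.approx(
                np.mean([o.n_pixels for o in nuclear])
            )
            # occupied nuclei, recomputed from truth pixel sets
            nuc_sets = [o.pixel_set() for o in truth.nuclei]
            occupied = sum(
                any(bool(s & i.pixel_set()) for i in nuclear) for s in nuc_sets
            )
            assert stats.pct_nuclei_with_inclusions == pytest.approx(
                100 * occupied / len(truth.nuclei)
            )


class TestGridRois:
    def test_tiles_square_image(self):
        img = np.full((900, 900), 100, np.uint8)
        boxes = grid_rois(img, 9)
        assert len(boxes) == 9
        assert all((r1 - r0, c1 - c0) == (300, 300) for r0, c0, r1, c1 in boxes)
        cover = np.zeros((900, 900), int)
        for r0, c0, r1, c1 in boxes:
            cover[r0:r1, c0:c1] += 1
        assert cover.max() == 1 and cover.sum() == 900 * 900

    def test_two_sections_give_18_rois(self):
        img = np.full((300, 300), 50, np.uint8)
        assert sum(len(grid_rois(img, 9)) for _ in range(2)) == 18

    def test_grid_centred_in_tissue_bbox(self):
        img = np.zeros((200, 200), np.uint8)
        img[40:160, 50:170] = 80
        boxes = grid_rois(img, 9)
        rows = [b[0] for b in boxes] + [b[2] for b in boxes]
        cols = [b[1] for b in boxes] + [b[3] for b in boxes]
        assert min(rows) >= 40 and max(rows) <= 160
        assert min(cols) >= 50 and max(cols) <= 170

    def test_too_small_image_errors(self):
        with pytest.raises(ValueError):
            grid_rois(np.full((2, 2), 10, np.uint8), 9)


class TestAggregateMouse:
    def _stats(self, n_nuclei, mean_inc):
        return ROIStats(
            n_nuclei=n_nuclei,
            mean_nucleus_px=50.0,
            n_inclusions=0 if math.isnan(mean_inc) else 3,
            mean_inclusion_px=mean_inc,
            pct_signal_colocalized=mean_inc,
            pct_inclusions_nuclear=50.0,
            n_nuclear_inclusions=1,
            pct_nuclei_with_inclusions=10.0,
            mean_nuclear_inclusion_px=mean_inc,
        )

    def test_identical_rois_mean_is_identity(self):
        stats = [self._stats(10, 20.0)] * 18
        agg = aggregate_mouse(stats)
        assert agg.loc["n_nuclei", "mean"] == 10
        assert agg.loc["mean_inclusion_px", "mean"] == 20.0
        assert (agg["n"] == 18).all()

    def test_undefined_roi_changes_only_those_fields_n(self):
        stats = [self._stats(10, 20.0), self._stats(14, math.nan)]
        agg = aggregate_mouse(stats)
        assert agg.loc["n_nuclei", "n"] == 2
        assert agg.loc["mean_inclusion_px", "n"] == 1
        assert agg.loc["n_nuclei", "mean"] == 12
        assert agg.loc["mean_inclusion_px", "mean"] == 20.0

    def test_hand_computed_means(self):
        stats = [self._stats(8, 10.0), self._stats(12, 30.0), self._stats(16, math.nan)]
        agg = aggregate_mouse(stats)
        assert agg.loc["n_nuclei", "mean"] == pytest.approx(12.0)
        assert agg.loc["mean_inclusion_px", "mean"] == pytest.approx(20.0)

    def test_empty_input(self):
        with pytest.raises(ValueError):
            aggregate_mouse([])
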