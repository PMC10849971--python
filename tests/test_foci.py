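"""Cell objects, WT masking, haemoglobin ratios, foci rules, z-profiles, ΔΔCt."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from embryoquant import (CellObject, MultiChannelScene, average_z_profiles,
                         cd34_area_fraction, classify_focus, detect_cells,
                         exclude_wt_regions, fold_change_ddct,
                         fold_changes_from_table, group_foci,
                         haemoglobin_ratios, make_zstack, z_distribution)


def _blob_scene(n_blobs, blob_value=2.0, size=3):
    """Grid of non-touching square cell blobs on a CD43 channel."""
    side = int(np.ceil(np.sqrt(n_blobs)))
    dim = side * (size + 4) + 4
    img = np.zeros((dim, dim))
    placed = 0
    for i, j in itertools.product(range(side), repeat=2):
        if placed >= n_blobs:
            break
        r, c = 4 + i * (size + 4), 4 + j * (size + 4)
        img[r:r + size, c:c + size] = blob_value
        placed += 1
    return MultiChannelScene({"CD43": img})


class TestDetectCells:
    def test_blank_channel_gives_no_objects(self):
        scene = MultiChannelScene({"CD43": np.zeros((20, 20))})
        assert detect_cells(scene, "CD43", threshold=0.5) == []

    def test_fifty_blobs_detected_as_fifty_objects(self):
        scene = _blob_scene(50)
        cells = detect_cells(scene, "CD43", threshold=0.5)
        assert len(cells) == 50

    def test_flat_blob_mean_intensity_is_its_value(self):
        scene = _blob_scene(1, blob_value=3.25)
        cells = detect_cells(scene, "CD43", threshold=0.5)
        assert cells[0].intensities["CD43"] == pytest.approx(3.25)

    def test_missing_channel_is_an_error(self):
        scene = MultiChannelScene({"CD43": np.zeros((10, 10))})
        with pytest.raises(KeyError):
            detect_cells(scene, "CD33")

    def test_size_gate_removes_small_objects(self):
        img = np.zeros((20, 20))
        img[2, 2] = 1.0
        img[10:13, 10:13] = 1.0
        scene = MultiChannelScene({"CD43": img})
        cells = detect_cells(scene, "CD43", threshold=0.5, min_area_px=4)
        assert len(cells) == 1


class TestExcludeWtRegions:
    def test_empty_mask_leaves_scene_unchanged(self):
        scene = _blob_scene(5)
        out = exclude_wt_regions(scene, np.zeros(scene.shape, dtype=bool))
        np.testing.assert_array_equal(out.channels["CD43"],
                                      scene.channels["CD43"])

    def test_full_mask_removes_every_cell(self):
        scene = _blob_scene(5)
        out = exclude_wt_regions(scene, np.ones(scene.shape, dtype=bool))
        assert detect_cells(out, "CD43", threshold=0.5) == []

    def test_half_mask_keeps_only_outside_cells(self):
        scene = _blob_scene(16)
        mask = np.zeros(scene.shape, dtype=bool)
        mask[: scene.shape[0] // 2, :] = True
        out = exclude_wt_regions(scene, mask)
        all_cells = detect_cells(scene, "CD43", threshold=0.5)
        kept = detect_cells(out, "CD43", threshold=0.5)
        # containment oracle: cells whose centroid row is below the mask
        expected = [c for c in all_cells
                    if c.centroid[1] > scene.shape[0] // 2]
        assert len(kept) == len(expected)

    def test_shape_mismatch_is_an_error(self):
        scene = _blob_scene(2)
        with pytest.raises(ValueError):
            exclude_wt_regions(scene, np.zeros((3, 3), dtype=bool))


class TestHaemoglobinRatios:
    def _cells(self, rows):
        return [CellObject(i, (0.0, 0.0),
                           {"HbE": e, "HbG": g, "HbPan": p})
                for i, (e, g, p) in enumerate(rows)]

    def test_equal_chains_give_unit_ratio(self):
        out = haemoglobin_ratios(self._cells([(2, 2, 1), (5, 5, 3)]))
        np.testing.assert_allclose(out["ratio"], 1.0)

    def test_worked_normalization_case(self):
        out = haemoglobin_ratios(self._cells([(4, 2, 2)]))
        assert out.loc[0, "eps_norm"] == pytest.approx(2.0)
        assert out.loc[0, "gamma_norm"] == pytest.approx(1.0)
        assert out.loc[0, "ratio"] == pytest.approx(2.0)

    def test_scale_invariance(self):
        base = self._cells([(4, 2, 2), (1, 3, 2)])
        scaled = self._cells([(4 * 7, 2 * 7, 2 * 7), (7, 21, 14)])
        a = haemoglobin_ratios(base)
        b = haemoglobin_ratios(scaled)
        for col in ("eps_norm", "gamma_norm", "ratio"):
            np.testing.assert_allclose(a[col], b[col])

    def test_zero_gamma_reports_missing_ratio(self):
        out = haemoglobin_ratios(self._cells([(4, 0, 2), (4, 2, 2)]))
        assert math.isnan(out.loc[0, "ratio"])
        assert out.loc[1, "ratio"] == pytest.approx(2.0)

    def test_log_ratio_median_recovery(self):
        # parameter recovery: true log2 ratio mu -> population median ~ 2^mu
        rng = np.random.default_rng(42)
        n, mu = 1000, -1.0  # emulates the late-culture epsilon/gamma decline
        log_eps = rng.normal(2.0 + mu, 0.3, n)
        log_gamma = rng.normal(2.0, 0.3, n)
        cells = self._cells(list(zip(2.0 ** log_eps, 2.0 ** log_gamma,
                                     np.full(n, 4.0))))
        out = haemoglobin_ratios(cells)
        assert float(out["ratio"].median()) == pytest.approx(2.0 ** mu,
                                                             rel=0.05)


class TestCd34AreaFraction:
    def test_blank_image_zero_percent(self):
        scene = MultiChannelScene({"CD34": np.zeros((40, 40))})
        assert cd34_area_fraction(scene, threshold=0.5) == 0.0

    def test_everything_positive_hundred_percent(self):
        scene = MultiChannelScene({"CD34": np.ones((40, 40))})
        assert cd34_area_fraction(scene, threshold=0.5) == 100.0

    def test_one_positive_quadrant_is_quarter(self):
        img = np.zeros((40, 40))
        img[:20, :20] = 1.0
        scene = MultiChannelScene({"CD34": img})
        assert cd34_area_fraction(scene, threshold=0.5) == pytest.approx(25.0)

    def test_wt_mask_removes_positive_area_not_denominator(self):
        img = np.ones((40, 40))
        mask = np.zeros((40, 40), dtype=bool)
        mask[:20, :] = True
        scene = MultiChannelScene({"CD34": img})
        assert cd34_area_fraction(scene, threshold=0.5, wt_mask=mask) == 50.0


def _focus_cells(n, markers_per_cell):
    """markers_per_cell: list of sets of positive markers, padded/cycled to n."""
    cells = []
    for i in range(n):
        pos = markers_per_cell[i] if i < len(markers_per_cell) else set()
        cells.append(CellObject(i, (float(i), 0.0),
                                {m: (2.0 if m in pos else 0.0)
                                 for m in ("A", "B", "CD43")}))
    return cells


THRESH = {"A": 1.0, "B": 1.0, "CD43": 1.0}


class TestClassifyFocus:
    def test_single_negative_cell_still_uni_lineage(self):
        cells = _focus_cells(25, [{"A"}] * 24 + [set()])
        rec = classify_focus(cells, THRESH, ["A", "B"])
        assert rec.classification == "uni_lineage"
        assert rec.lineage_markers == ("A",)

    def test_two_negative_cells_still_uni_lineage(self):
        cells = _focus_cells(25, [{"A"}] * 23 + [set(), set()])
        assert classify_focus(cells, THRESH, ["A", "B"]).classification == \
            "uni_lineage"

    def test_three_negative_cells_break_uni_lineage(self):
        cells = _focus_cells(25, [{"A"}] * 22 + [set()] * 3)
        assert classify_focus(cells, THRESH, ["A", "B"]).classification == \
            "unclassified"

    def test_three_of_each_of_two_markers_is_multilineage(self):
        cells = _focus_cells(25, [{"A"}] * 10 + [{"B"}] * 10 + [{"A", "B"}] * 5)
        rec = classify_focus(cells, THRESH, ["A", "B"])
        assert rec.classification == "multi_lineage"
        assert rec.lineage_markers == ("A", "B")

    def test_twenty_cells_is_too_few_to_classify(self):
        cells = _focus_cells(20, [{"A"}] * 20)
        assert classify_focus(cells, THRESH, ["A", "B"]).classification == \
            "unclassified"

    def test_cd43_coexpression_does_not_break_uni_lineage(self):
        cells = _focus_cells(25, [{"A", "CD43"}] * 24 + [{"A"}])
        assert classify_focus(cells, THRESH, ["A", "B"]).classification == \
            "uni_lineage"

    def test_cd43_only_cell_blocks_uni_lineage(self):
        cells = _focus_cells(25, [{"A", "CD43"}] * 24 + [{"CD43"}])
        assert classify_focus(cells, THRESH, ["A", "B"]).classification == \
            "unclassified"

    def test_empty_cell_list_is_an_error(self):
        with pytest.raises(ValueError):
            classify_focus([], THRESH, ["A"])

    def test_agrees_with_rule_table_oracle_on_small_cases(self):
        """Exhaustive check against an independently coded rule table.

        Cells carry marker A and/or B (plus optional CD43-only cells);
        sweep focus sizes 15..30 with 0..5 negatives and 0..5 positives
        per marker.
        """
        def oracle(n, n_a_only, n_b_only, n_ab, n_cd43_only):
            n_neg = n - n_a_only - n_b_only - n_ab - n_cd43_only
            if n <= 20:
                return "unclassified"
            pos_a = n_a_only + n_ab
            pos_b = n_b_only + n_ab
            if pos_a >= 3 and pos_b >= 3:
                return "multi_lineage"
            if n - pos_a < 3 and n_cd43_only == 0:
                return "uni_lineage"
            if n - pos_b < 3 and n_cd43_only == 0:
                return "uni_lineage"
            return "unclassified"

        for n in range(15, 31):
            for n_ab in (0, 2, 5, n - 2):
                for n_a_only in (0, 1, 3, 5):
                    for n_b_only in (0, 2, 4):
                        for n_cd43_only in (0, 1):
                            total = n_ab + n_a_only + n_b_only + n_cd43_only
                            if total > n or n_ab < 0:
                                continue
                            comp = ([{"A", "B"}] * n_ab
                                    + [{"A"}] * n_a_only
                                    + [{"B"}] * n_b_only
                                    + [{"CD43"}] * n_cd43_only)
                            cells = _focus_cells(n, comp)
                            got = classify_focus(cells, THRESH,
                                                 ["A", "B"]).classification
                            want = oracle(n, n_a_only, n_b_only, n_ab,
                                          n_cd43_only)
                            assert got == want, (n, n_a_only, n_b_only,
                                                 n_ab, n_cd43_only)


class TestGroupFoci:
    def test_two_spatial_clusters_form_two_groups(self):
        cells = [CellObject(i, (float(i % 5), 0.0), {}) for i in range(5)]
        cells += [CellObject(5 + i, (100.0 + i, 0.0), {}) for i in range(5)]
        groups = group_foci(cells, link_radius=2.0)
        assert sorted(map(len, groups)) == [5, 5]

    def test_no_cells_no_groups(self):
        assert group_foci([], 10.0) == []


class TestZDistribution:
    def test_single_nonzero_slice_normalizes_to_hundred(self):
        stack, _ = make_zstack([("CD34", 0, 0.0, 5.0)], n_slices=1)
        zp = z_distribution(stack)
        np.testing.assert_allclose(zp.normalized_pct["CD34"], [100.0])

    def test_two_slices_percent_of_max(self):
        stack = MultiChannelScene(
            {"CD34": np.stack([np.full((4, 4), 2.0), np.full((4, 4), 4.0)])})
        zp = z_distribution(stack)
        np.testing.assert_allclose(zp.normalized_pct["CD34"], [50.0, 100.0])

    def test_scale_invariance_of_normalized_profile(self):
        base = np.stack([np.full((4, 4), v) for v in (1.0, 3.0, 2.0)])
        zp1 = z_distribution(MultiChannelScene({"CD34": base}))
        zp2 = z_distribution(MultiChannelScene({"CD34": 7.3 * base}))
        np.testing.assert_allclose(zp1.normalized_pct["CD34"],
                                   zp2.normalized_pct["CD34"])

    def test_bottom_index_skips_out_of_focus_slices(self):
        stack = MultiChannelScene({"CD34": np.stack(
            [np.zeros((4, 4)), np.full((4, 4), 2.0), np.full((4, 4), 4.0)])})
        zp = z_distribution(stack, focus_metric_threshold=0.5)
        assert zp.bottom_index == 1
        np.testing.assert_allclose(zp.normalized_pct["CD34"], [50.0, 100.0])

    def test_no_in_focus_slice_is_an_error(self):
        stack = MultiChannelScene({"CD34": np.zeros((3, 4, 4))})
        with pytest.raises(ValueError):
            z_distribution(stack, focus_metric_threshold=0.5)

    def test_identical_replicates_average_to_themselves(self):
        stack = MultiChannelScene(
            {"CD34": np.stack([np.full((4, 4), 2.0), np.full((4, 4), 4.0)])})
        zp = z_distribution(stack)
        avg = average_z_profiles([zp, zp, zp])
        np.testing.assert_allclose(avg.normalized_pct["CD34"],
                                   zp.normalized_pct["CD34"])

    def test_opposed_replicates_average_then_renormalize(self):
        # [2,4] and [4,2] -> normalized [50,100] and [100,50] -> mean
        # [75,75] -> percent of max [100,100]
        a = MultiChannelScene(
            {"CD34": np.stack([np.full((4, 4), 2.0), np.full((4, 4), 4.0)])})
        b = MultiChannelScene(
            {"CD34": np.stack([np.full((4, 4), 4.0), np.full((4, 4), 2.0)])})
        avg = average_z_profiles([z_distribution(a), z_distribution(b)])
        np.testing.assert_allclose(avg.normalized_pct["CD34"], [100.0, 100.0])


class TestFoldChange:
    @pytest.mark.parametrize("ddct,expected", [(0.0, 1.0), (1.0, 0.5),
                                               (-2.0, 4.0)])
    def test_ddct_fold_changes(self, ddct, expected):
        # calibrator delta-Ct fixed at 0: sample delta-Ct equals ddct
        assert fold_change_ddct(20.0 + ddct, 20.0, 18.0, 18.0) == \
            pytest.approx(expected)

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValueError):
            fold_change_ddct(math.nan, 20.0, 18.0, 18.0)

    def test_table_helper_matches_scalar_path(self):
        table = pd.DataFrame({
            "sample": ["d12", "d12", "d21", "d21"],
            "gene": ["HBE", "R18S", "HBE", "R18S"],
            "ct": [22.0, 15.0, 25.0, 15.0],
        })
        out = fold_changes_from_table(table, "HBE", "R18S", "d12")
        by_sample = dict(zip(out["sample"], out["fold_change"]))
        assert by_sample["d12"] == pytest.approx(1.0)
        assert by_sample["d21"] == pytest.approx(0.125)  # ddct = 3
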