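"""Data-model operations: scores, lesion loads, correlations, RoB merges."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lesionmsa import (
    LesionDataset,
    Region,
    RegionSet,
    binarize_performance,
    compute_lesion_correlations,
    derive_motor_score,
    extract_lesion_loads,
    filter_patients,
    merge_into_rob,
)
from conftest import make_dataset, make_region_set


class TestScores:
    @pytest.mark.parametrize(
        "upper,lower,expected",
        [(0, 0, 10), (4, 4, 2), (2, 1, 7), (0, 4, 6), (3, 0, 7)],
    )
    def test_motor_score_is_ten_minus_item_sum(self, upper, lower, expected):
        assert derive_motor_score(upper, lower) == expected

    @pytest.mark.parametrize("upper,lower", [(-1, 0), (5, 0), (0, 5), (2, -2)])
    def test_items_outside_range_rejected(self, upper, lower):
        with pytest.raises(ValueError):
            derive_motor_score(upper, lower)

    @pytest.mark.parametrize("score,expected", [(10, 1), (9, 0), (2, 0), (7, 0)])
    def test_binarization_is_intact_iff_ceiling(self, score, expected):
        assert binarize_performance(score) == expected

    @pytest.mark.parametrize("score", [1, 11, 0])
    def test_score_outside_range_rejected(self, score):
        with pytest.raises(ValueError):
            binarize_performance(score)

    @given(st.integers(0, 4), st.integers(0, 4))
    def test_composition_intact_iff_both_items_zero(self, upper, lower):
        intact = binarize_performance(derive_motor_score(upper, lower))
        assert intact == (1 if upper == 0 and lower == 0 else 0)

    def test_vectorized_paths_match_scalars(self):
        upper = np.array([0, 2, 4])
        lower = np.array([0, 1, 4])
        np.testing.assert_array_equal(derive_motor_score(upper, lower), [10, 7, 2])
        np.testing.assert_array_equal(
            binarize_performance(np.array([10, 7, 2])), [1, 0, 0]
        )


class TestRegionSet:
    def test_duplicate_ids_rejected(self):
        regions = (
            Region("A", 1, 10),
            Region("A", 2, 10),
            Region("RoB", None, 100),
        )
        with pytest.raises(ValueError, match="unique"):
            RegionSet(regions=regions, rob_id="RoB")

    def test_rob_must_be_listed(self):
        with pytest.raises(ValueError, match="rob_id"):
            RegionSet(regions=(Region("A", 1, 10),), rob_id="RoB")

    def test_nonpositive_voxel_count_rejected(self):
        with pytest.raises(ValueError, match="voxel_count"):
            Region("A", 1, 0)


class TestExtractLesionLoads:
    def _region_set(self):
        regions = (
            Region("left", 1, 5),
            Region("right", 2, 3),
            Region("RoB", None, 3),
        )
        return RegionSet(regions=regions, rob_id="RoB")

    def _atlas(self):
        # 3x4x1 grid: label 1 on 5 voxels, label 2 on 3, label 7 on 3
        atlas = np.zeros((3, 4, 1), dtype=int)
        atlas[0, :, 0] = 1
        atlas[1, 0, 0] = 1
        atlas[1, 1:, 0] = 2
        atlas[2, 1:, 0] = 7  # unclaimed -> RoB territory
        return atlas

    def test_toy_volume_hand_counts(self):
        atlas = self._atlas()
        mask = np.zeros_like(atlas)
        mask[0, 0, 0] = 1
        mask[0, 1, 0] = 1  # two voxels of label 1
        absolute, relative = extract_lesion_loads(mask, atlas, self._region_set())
        np.testing.assert_array_equal(absolute, [2, 0, 0])
        np.testing.assert_allclose(relative, [40.0, 0.0, 0.0])

    def test_empty_mask_gives_zero_loads(self):
        atlas = self._atlas()
        absolute, relative = extract_lesion_loads(
            np.zeros_like(atlas), atlas, self._region_set()
        )
        assert absolute.sum() == 0 and relative.sum() == 0

    def test_complete_ablation_of_one_region(self):
        atlas = self._atlas()
        mask = (atlas == 2).astype(int)
        absolute, relative = extract_lesion_loads(mask, atlas, self._region_set())
        np.testing.assert_allclose(relative, [0.0, 100.0, 0.0])

    def test_voxel_conservation_over_random_masks(self):
        atlas = self._atlas()
        rng = np.random.default_rng(0)
        for _ in range(20):
            mask = rng.integers(0, 2, size=atlas.shape)
            absolute, _ = extract_lesion_loads(mask, atlas, self._region_set())
            inside = int(np.count_nonzero((mask == 1) & (atlas > 0)))
            assert absolute.sum() == inside

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            extract_lesion_loads(np.zeros((2, 2, 1)), self._atlas(), self._region_set())

    def test_absent_label_warns_and_counts_zero(self):
        regions = (
            Region("present", 1, 5),
            Region("ghost", 99, 10),
            Region("RoB", None, 3),
        )
        rs = RegionSet(regions=regions, rob_id="RoB")
        atlas = self._atlas()
        with pytest.warns(UserWarning, match="absent"):
            absolute, _ = extract_lesion_loads(np.ones_like(atlas), atlas, rs)
        assert absolute[1] == 0


class TestCorrelations:
    def test_hand_computed_pearson_on_five_patients(self):
        # independent oracle: scipy.stats.pearsonr per pair
        rng = np.random.default_rng(4)
        loads = rng.uniform(0, 100, size=(5, 4))
        ds = make_dataset(loads, np.array([1, 0, 1, 0, 1]))
        corr = compute_lesion_correlations(ds)
        for i in range(4):
            for j in range(4):
                r_ref, p_ref = stats.pearsonr(loads[:, i], loads[:, j])
                assert corr.r[i, j] == pytest.approx(r_ref, abs=1e-12)
                if i != j:
                    assert corr.p[i, j] == pytest.approx(p_ref, abs=1e-12)

    def test_linear_dependence_gives_unit_correlation(self):
        base = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        loads = np.column_stack([base, 2 * base, np.zeros(5)])
        ds = make_dataset(
            loads, np.array([1, 1, 0, 0, 1]), region_set=make_region_set(2)
        )
        corr = compute_lesion_correlations(ds, region_subset=["R00", "R01"])
        assert corr.r[0, 1] == pytest.approx(1.0)
        assert corr.p[0, 1] == pytest.approx(0.0)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(7)
        ds = make_dataset(rng.uniform(0, 100, (8, 5)), rng.integers(0, 2, 8))
        corr = compute_lesion_correlations(ds)
        np.testing.assert_allclose(corr.r, corr.r.T)
        np.testing.assert_allclose(np.diag(corr.r), 1.0)
        assert np.nanmax(corr.p) <= 1.0 and np.nanmin(corr.p) >= 0.0

    def test_constant_column_reported_missing_not_zero(self):
        loads = np.column_stack(
            [np.full(5, 20.0), np.array([1.0, 5, 9, 3, 7]), np.zeros(5)]
        )
        ds = make_dataset(loads, np.array([1, 0, 1, 0, 1]), region_set=make_region_set(2))
        corr = compute_lesion_correlations(ds)
        assert set(corr.undefined_ids) == {"R00", "RoB"}
        assert np.isnan(corr.r[0, 1])

    def test_too_few_patients_rejected(self):
        ds = make_dataset(np.zeros((2, 3)), np.array([1, 0]), region_set=make_region_set(2))
        with pytest.raises(ValueError, match="3 patients"):
            compute_lesion_correlations(ds)


class TestMergeIntoRob:
    def test_zero_lesion_merge_is_pure_dilution(self):
        rs = make_region_set(2, voxel_counts=[500, 300], rob_voxels=1000)
        loads = np.array([[0.0, 40.0, 20.0], [0.0, 0.0, 10.0]])
        ds = make_dataset(loads, np.array([1, 0]), region_set=rs)
        merged = merge_into_rob(ds, ["R00"])
        # new_rob = old_rob * V_rob / (V_rob + V_r)
        expected = loads[:, 2] * 1000 / 1500
        np.testing.assert_allclose(
            merged.loads[:, merged.region_set.rob_index], expected
        )

    def test_equal_voxel_counts_average_loads(self):
        # two regions of equal size, loads 20% and 40%, into an empty RoB of
        # negligible size -> pooled load tends to the 30% equal-weight mean
        rs = make_region_set(2, voxel_counts=[1000, 1000], rob_voxels=1)
        loads = np.array([[20.0, 40.0, 0.0]])
        ds = make_dataset(loads, np.array([1]), region_set=rs)
        merged = merge_into_rob(ds, ["R00", "R01"])
        rob = merged.loads[0, merged.region_set.rob_index]
        assert rob == pytest.approx(100 * (200 + 400) / 2001)
        assert rob == pytest.approx(30.0, rel=1e-3)

    def test_pooled_voxel_hand_computation(self):
        rs = make_region_set(2, voxel_counts=[100, 300], rob_voxels=600)
        loads = np.array([[50.0, 10.0, 0.0]])
        ds = make_dataset(loads, np.array([0]), region_set=rs)
        merged = merge_into_rob(ds, ["R00", "R01"])
        # 100*(50 + 30 + 0)/1000 = 8.0%
        assert merged.loads[0, merged.region_set.rob_index] == pytest.approx(8.0)
        assert merged.region_set["RoB"].voxel_count == 1000

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_merge_conserves_pooled_lesioned_voxels(self, seed):
        rng = np.random.default_rng(seed)
        vox = rng.integers(50, 2000, size=5)
        rs = make_region_set(5, voxel_counts=vox, rob_voxels=int(rng.integers(1000, 9000)))
        loads = rng.uniform(0, 100, size=(4, 6))
        ds = make_dataset(loads, rng.integers(0, 2, 4), region_set=rs)
        merged = merge_into_rob(ds, ["R01", "R03"])
        before = ds.loads @ rs.voxel_counts / 100.0
        after = merged.loads @ merged.region_set.voxel_counts / 100.0
        np.testing.assert_allclose(before, after, rtol=1e-12)

    def test_merging_is_associative(self):
        rng = np.random.default_rng(3)
        rs = make_region_set(4, voxel_counts=[100, 200, 300, 400], rob_voxels=500)
        ds = make_dataset(rng.uniform(0, 100, (3, 5)), rng.integers(0, 2, 3), region_set=rs)
        one_shot = merge_into_rob(ds, ["R00", "R02"])
        stepwise = merge_into_rob(merge_into_rob(ds, ["R00"]), ["R02"])
        np.testing.assert_allclose(one_shot.loads, stepwise.loads, rtol=1e-12)

    def test_discarding_rob_rejected(self):
        ds = make_dataset(np.zeros((2, 3)), np.array([1, 0]), region_set=make_region_set(2))
        with pytest.raises(ValueError, match="rest-of-brain"):
            merge_into_rob(ds, ["RoB"])


class TestDatasetValidation:
    def test_performance_must_match_raw_score(self):
        with pytest.raises(ValueError, match="performance"):
            LesionDataset(
                patient_ids=["a"],
                loads=np.zeros((1, 3)),
                raw_motor_score=np.array([9]),
                performance=np.array([1]),
                region_set=make_region_set(2),
            )

    def test_loads_outside_percent_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            make_dataset(np.full((1, 3), 101.0), np.array([1]), region_set=make_region_set(2))

    def test_metadata_filtering_drops_flagged_patients(self):
        import pandas as pd

        ds = make_dataset(np.zeros((4, 3)), np.array([1, 0, 1, 0]), region_set=make_region_set(2))
        ds.metadata = pd.DataFrame(
            {"bilateral": [True, False, False, False], "recurrent": [False, False, True, False]}
        )
        kept = filter_patients(ds, exclude_bilateral=True, exclude_recurrent=True)
        assert kept.patient_ids == ["P001", "P003"]
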