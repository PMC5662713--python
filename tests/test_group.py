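import numpy as np
import pytest
from scipy import stats

from reinstate.data_model import StatMap, VolumeGrid
from reinstate.group import (ClusterConfig, cluster_fwe, interaction_anova_2x3,
                             one_sample_t_map, paired_t_map)
from reinstate.synth import box_mask


def maps_from(data, grid):
    return [StatMap(grid, d, "searchlight_sum") for d in data]


class TestTMaps:
    def test_voxelwise_t_follows_student_t(self, small_grid, rng):
        """Null data: one-sample t over n=21 subjects is t(20) distributed."""
        data = rng.standard_normal((21,) + small_grid.shape)
        t = one_sample_t_map(maps_from(data, small_grid))
        assert t.df == 20
        stat, p = stats.kstest(t.values.ravel(), stats.t(df=20).cdf)
        assert p > 0.01

    def test_identical_constant_maps_flagged_inf(self, small_grid):
        data = np.full((5,) + small_grid.shape, 3.0)
        t = one_sample_t_map(maps_from(data, small_grid))
        assert np.all(np.isposinf(t.values))

    def test_antisymmetric_pair_gives_zero(self, small_grid, rng):
        m = rng.standard_normal(small_grid.shape)
        data = np.stack([m, -m, m, -m])
        t = one_sample_t_map(maps_from(data, small_grid))
        np.testing.assert_allclose(t.values, 0.0, atol=1e-10)

    def test_nan_propagates(self, small_grid, rng):
        data = rng.standard_normal((5,) + small_grid.shape)
        data[2, 0, 0, 0] = np.nan
        t = one_sample_t_map(maps_from(data, small_grid))
        assert np.isnan(t.values[0, 0, 0])
        assert np.isfinite(t.values[1:]).all()

    def test_paired_identical_is_zero(self, small_grid, rng):
        data = rng.standard_normal((6,) + small_grid.shape)
        maps = maps_from(data, small_grid)
        t = paired_t_map(maps, maps)
        np.testing.assert_allclose(t.values, 0.0)

    def test_paired_invariant_to_common_addend(self, small_grid, rng):
        a = rng.standard_normal((8,) + small_grid.shape)
        b = rng.standard_normal((8,) + small_grid.shape)
        common = rng.standard_normal((8,) + small_grid.shape)
        t1 = paired_t_map(maps_from(a, small_grid), maps_from(b, small_grid))
        t2 = paired_t_map(maps_from(a + common, small_grid),
                          maps_from(b + common, small_grid))
        np.testing.assert_allclose(t1.values, t2.values, atol=1e-9)

    def test_subject_mismatch_errors(self, small_grid, rng):
        a = maps_from(rng.standard_normal((5,) + small_grid.shape), small_grid)
        with pytest.raises(ValueError, match="same subjects"):
            paired_t_map(a, a[:-1])


class TestClusterFwe:
    def test_deterministic_given_seed(self, small_grid, rng):
        data = rng.standard_normal((8,) + small_grid.shape) + 0.8
        maps = maps_from(data, small_grid)
        cfg = ClusterConfig(n_permutations=200, seed=9)
        r1 = cluster_fwe(maps, cfg)
        r2 = cluster_fwe(maps, cfg)
        assert [c.p_fwe for c in r1.clusters] == [c.p_fwe for c in r2.clusters]
        np.testing.assert_array_equal(r1.null_max_sizes, r2.null_max_sizes)

    def test_corrected_p_monotone_in_size(self, small_grid, rng):
        data = rng.standard_normal((10,) + small_grid.shape)
        data[:, 2:5, 2:5, 2:5] += 2.5
        data[:, 7:9, 7:9, 7:9] += 2.5
        res = cluster_fwe(maps_from(data, small_grid),
                          ClusterConfig(n_permutations=300, seed=1))
        sizes = [c.size for c in res.clusters]
        ps = [c.p_fwe for c in res.clusters]
        for (s1, p1), (s2, p2) in zip(zip(sizes, ps), zip(sizes[1:], ps[1:])):
            assert s1 >= s2 and p1 <= p2

    def test_no_suprathreshold_voxels_is_empty_result(self, small_grid, rng):
        # alternating signs: every voxelwise mean is 0, so no voxel can
        # exceed the cluster-defining threshold
        base = np.abs(rng.standard_normal(small_grid.shape)) + 0.1
        data = np.stack([base, -base] * 4)
        res = cluster_fwe(maps_from(data, small_grid),
                          ClusterConfig(n_permutations=100, seed=0))
        assert res.clusters == []
        assert res.significant == []

    def test_whole_brain_roi_equals_no_roi(self, small_grid, rng):
        data = rng.standard_normal((8,) + small_grid.shape)
        data[:, 3:6, 3:6, 3:6] += 2.0
        maps = maps_from(data, small_grid)
        cfg = ClusterConfig(n_permutations=128, seed=4)
        full = box_mask(small_grid, (0, 0, 0), small_grid.shape)
        r1 = cluster_fwe(maps, cfg)
        r2 = cluster_fwe(maps, cfg, roi=full)
        assert [(c.size, c.p_fwe) for c in r1.clusters] == \
               [(c.size, c.p_fwe) for c in r2.clusters]

    def test_roi_restricts_detection(self, small_grid, rng):
        data = rng.standard_normal((10,) + small_grid.shape)
        data[:, 1:4, 1:4, 1:4] += 3.0   # effect outside the ROI
        roi = box_mask(small_grid, (6, 6, 6), (10, 10, 10))
        res = cluster_fwe(maps_from(data, small_grid),
                          ClusterConfig(n_permutations=100, seed=2), roi=roi)
        assert all(roi.voxels[c.peak_voxel] for c in res.clusters)

    def test_strong_effect_detected(self, small_grid, rng):
        data = rng.standard_normal((12,) + small_grid.shape)
        data[:, 2:7, 2:7, 2:7] += 1.5
        res = cluster_fwe(maps_from(data, small_grid),
                          ClusterConfig(n_permutations=500, seed=3))
        assert len(res.significant) >= 1
        peak = res.significant[0].peak_voxel
        assert all(2 <= peak[k] < 7 for k in range(3))


class TestInteractionAnova:
    def test_no_interaction_when_gap_constant(self, rng):
        """Same-vs-diff gap identical in all three phase pairs at the group
        level: interaction F collapses to ~0 even with subject variability."""
        n = 12
        subj = rng.standard_normal((n, 1, 1))
        phase_eff = np.array([0.1, 0.2, 0.3])[None, None, :]
        type_eff = np.array([0.5, 0.0])[None, :, None]
        data = subj + phase_eff + type_eff
        # subject-level interaction wiggle that cancels exactly across the
        # group, so the group-level cell means stay perfectly additive
        wiggle = rng.standard_normal((1, 2, 3))
        wiggle = wiggle - wiggle.mean(1, keepdims=True) \
            - wiggle.mean(2, keepdims=True) + wiggle.mean()
        signs = np.array([1, -1] * (n // 2))[:, None, None]
        data = data + signs * wiggle
        F, df1, df2, p = interaction_anova_2x3(data)
        assert F == pytest.approx(0.0, abs=1e-12)

    def test_df_shape_matches_design(self, rng):
        data = rng.standard_normal((20, 2, 3))
        F, df1, df2, p = interaction_anova_2x3(data)
        assert (df1, df2) == (2, 38)
        data21 = rng.standard_normal((21, 2, 3))
        _, d1, d2, _ = interaction_anova_2x3(data21)
        assert (d1, d2) == (2, 40)

    def test_interaction_detected_when_gap_varies(self, rng):
        n = 21
        data = 0.05 * rng.standard_normal((n, 2, 3))
        data[:, 0, 2] += 1.0  # same-vs-diff gap doubled in one phase pair
        F, _, _, p = interaction_anova_2x3(data)
        assert p < 0.05
        small = 0.05 * rng.standard_normal((n, 2, 3))
        small[:, 0, 2] += 0.02
        F2, _, _, _ = interaction_anova_2x3(small)
        assert F > F2

    def test_missing_cells_error(self):
        data = np.full((5, 2, 3), np.nan)
        with pytest.raises(ValueError, match="missing"):
            interaction_anova_2x3(data)

    def test_matches_manual_two_way_rm_computation(self, rng):
        """Cross-check against a direct sum-of-squares computation."""
        n = 8
        data = rng.standard_normal((n, 2, 3))
        F, df1, df2, _ = interaction_anova_2x3(data)
        # manual: interaction SS of cell means vs subject x cell residual
        grand = data.mean()
        cell = data.mean(axis=0)              # 2 x 3
        a_m = data.mean(axis=(0, 2))          # type means
        b_m = data.mean(axis=(0, 1))          # phase means
        ss_inter = n * ((cell - a_m[:, None] - b_m[None, :] + grand) ** 2).sum()
        subj_cell = data                       # n x 2 x 3
        s_ab = subj_cell
        s_a = data.mean(axis=2)                # n x 2
        s_b = data.mean(axis=1)                # n x 3
        s_m = data.mean(axis=(1, 2))           # n
        resid = (s_ab - s_a[:, :, None] - s_b[:, None, :] - cell[None]
                 + a_m[None, :, None] + b_m[None, None, :]
                 + s_m[:, None, None] - grand)
        ss_err = (resid ** 2).sum()
        df_i = (2 - 1) * (3 - 1)
        df_e = df_i * (n - 1)
        F_manual = (ss_inter / df_i) / (ss_err / df_e)
        assert F == pytest.approx(F_manual, rel=1e-6)
        assert (df1, df2) == (df_i, df_e)
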