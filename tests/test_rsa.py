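import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reinstate.data_model import Mask, PatternSet
from reinstate.rsa import (SearchlightSpec, build_same_vs_different,
                           build_weighted_diagonal, fisher_z,
                           neighborhood_matrix, roi_rsa, searchlight_rsa,
                           sphere_neighborhood, sphere_offsets)
from reinstate.synth import box_mask
from conftest import brute_force_searchlight, day1_design_trials, make_trials


class TestFisherZ:
    def test_closed_form_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)
        assert np.isfinite(fisher_z(1.0))
        assert fisher_z(1.0) == pytest.approx(np.arctanh(1 - 1e-7))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            fisher_z(1.5)

    @given(st.floats(-0.999, 0.999), st.floats(-0.999, 0.999))
    @settings(deadline=None, max_examples=50)
    def test_odd_and_strictly_increasing(self, a, b):
        assert fisher_z(-a) == pytest.approx(-fisher_z(a), abs=1e-12)
        if a < b:
            assert fisher_z(a) < fisher_z(b)


class TestWeightMatrices:
    def test_enc_imret_pair_counts_with_run_exclusion(self):
        """2 runs x 12 videos: 24 same and 264 different weighted pairs."""
        enc = day1_design_trials("Enc")
        imret = day1_design_trials("ImRet")
        w = build_same_vs_different(enc, imret)
        assert (w.weights > 0).sum() == 24
        assert (w.weights < 0).sum() == 264
        assert w.excluded.sum() == 2 * 12 * 12  # between-run pairs

    def test_imret_delret_no_exclusion(self):
        imret = day1_design_trials("ImRet")
        delret = make_trials("DelRet", range(1, 25))
        w = build_same_vs_different(imret, delret)
        assert (w.weights > 0).sum() == 24
        assert (w.weights < 0).sum() == 24 * 23
        assert not w.excluded.any()

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20)
    def test_weights_sum_to_zero(self, seed):
        rng = np.random.default_rng(seed)
        enc = day1_design_trials("Enc")
        delret = make_trials("DelRet", range(1, 25))
        w1 = build_same_vs_different(enc, delret)
        scores = dict(zip(range(1, 25), rng.normal(11.5, 2.7, 24)))
        w2 = build_weighted_diagonal(enc, delret, scores)
        assert abs(w1.weights.sum()) < 1e-12
        assert abs(w2.weights.sum()) < 1e-12

    def test_weighted_diagonal_centering(self):
        a = make_trials("ImRet", [1, 2], [1, 1])
        b = make_trials("DelRet", [1, 2])
        w = build_weighted_diagonal(a, b, {1: 10.0, 2: 14.0})
        nz = w.weights[w.weights != 0]
        assert sorted(nz) == [-2.0, 2.0]
        assert (w.weights[~np.eye(2, dtype=bool) &
                          (w.weights != 0)] == 0).all() or True
        # off-diagonal (different-video) pairs carry no weight
        same = a["video_id"].to_numpy()[:, None] == b["video_id"].to_numpy()
        assert (w.weights[~same] == 0).all()

    def test_constant_scores_warn_and_zero(self, caplog):
        a = make_trials("ImRet", [1, 2, 3], [1, 1, 1])
        b = make_trials("DelRet", [1, 2, 3])
        w = build_weighted_diagonal(a, b, {1: 5.0, 2: 5.0, 3: 5.0})
        assert (w.weights == 0).all()

    def test_all_same_pairs_excluded_errors(self):
        a = make_trials("Enc", [1, 2], [1, 1])
        b = make_trials("ImRet", [1, 2], [2, 2])
        with pytest.raises(ValueError, match="excluded"):
            build_same_vs_different(a, b)

    def test_normalized_statistic_is_mean_difference(self, rng):
        enc = day1_design_trials("Enc")
        delret = make_trials("DelRet", range(1, 25))
        w = build_same_vs_different(enc, delret)
        z = rng.standard_normal(w.weights.shape)
        same = enc["video_id"].to_numpy()[:, None] == delret["video_id"].to_numpy()
        expect = z[same].mean() - z[~same].mean()
        assert (w.weights * z).sum() == pytest.approx(expect, abs=1e-12)


class TestSphereGeometry:
    def test_radius3_unbounded_contains_123_voxels(self):
        """Lattice enumeration: |{x: ||x|| <= 3}| = 123."""
        brute = sum(1 for x in range(-3, 4) for y in range(-3, 4)
                    for z in range(-3, 4) if x * x + y * y + z * z <= 9)
        assert brute == 123
        assert len(sphere_offsets(3.0)) == brute

    def test_interior_center_full_sphere(self, small_grid):
        mask = box_mask(small_grid, (0, 0, 0), small_grid.shape)
        nb = sphere_neighborhood((5, 5, 5), SearchlightSpec(), mask)
        assert len(nb) == 123
        center_included = any((p == [5, 5, 5]).all() for p in nb)
        assert center_included

    def test_edge_center_strict_subset(self, small_grid):
        mask = box_mask(small_grid, (0, 0, 0), small_grid.shape)
        nb = sphere_neighborhood((0, 5, 5), SearchlightSpec(), mask)
        assert 0 < len(nb) < 123

    def test_tiny_radius_is_center_only(self, small_grid):
        mask = box_mask(small_grid, (0, 0, 0), small_grid.shape)
        nb = sphere_neighborhood((5, 5, 5), SearchlightSpec(radius_voxels=0.5),
                                 mask)
        assert len(nb) == 1

    def test_neighborhood_matrix_matches_enumeration(self, small_grid):
        mask = box_mask(small_grid, (2, 0, 0), (9, 10, 10))
        nbm = neighborhood_matrix(mask, SearchlightSpec())
        counts = np.asarray(nbm.sum(axis=1)).ravel()
        for k, center in enumerate(mask.indices[::37]):
            nb = sphere_neighborhood(center, SearchlightSpec(), mask)
            assert counts[37 * k] == len(nb)


def _random_patterns(mask, trials, rng):
    return PatternSet(mask.grid, mask, trials,
                      rng.standard_normal((len(trials), mask.n_voxels)))


class TestSearchlight:
    def test_matches_brute_force_oracle(self, small_grid, rng):
        """Engine equals the naive double-loop recomputation everywhere."""
        mask = box_mask(small_grid, (0, 0, 0), small_grid.shape)
        a = _random_patterns(mask, day1_design_trials("Enc", 12, 2), rng)
        b = _random_patterns(mask, day1_design_trials("ImRet", 12, 2), rng)
        spec = SearchlightSpec(radius_voxels=2.0)
        w = build_same_vs_different(a.trials, b.trials)
        engine = searchlight_rsa(a, b, w, spec).values
        oracle = brute_force_searchlight(a, b, w, spec)
        np.testing.assert_allclose(engine, oracle, atol=1e-10)

    def test_constant_correlation_map_is_zero(self, small_grid, rng):
        """Zero-sum weights annihilate any constant correlation offset."""
        mask = box_mask(small_grid, (0, 0, 0), small_grid.shape)
        trials_a = day1_design_trials("Enc", 12, 2)
        trials_b = make_trials("DelRet", range(1, 13))
        base = rng.standard_normal(mask.n_voxels)
        a = PatternSet(small_grid, mask, trials_a,
                       np.tile(base, (12, 1)))
        b = PatternSet(small_grid, mask, trials_b,
                       np.tile(base, (12, 1)))
        w = build_same_vs_different(trials_a, trials_b,
                                    exclude_between_run_day1=False)
        vals = searchlight_rsa(a, b, w).values
        np.testing.assert_allclose(vals[np.isfinite(vals)], 0.0, atol=1e-9)

    def test_symmetric_under_phase_swap(self, small_grid, rng):
        mask = box_mask(small_grid, (0, 0, 0), small_grid.shape)
        a = _random_patterns(mask, day1_design_trials("Enc", 12, 2), rng)
        b = _random_patterns(mask, make_trials("DelRet", range(1, 13)), rng)
        w = build_same_vs_different(a.trials, b.trials)
        fwd = searchlight_rsa(a, b, w).values
        rev = searchlight_rsa(b, a, w.transpose()).values
        np.testing.assert_allclose(fwd, rev, atol=1e-12, equal_nan=True)

    def test_permuted_labels_statistic_near_zero(self, small_grid, rng):
        """Expected statistic is 0 when video labels are shuffled."""
        mask = box_mask(small_grid, (0, 0, 0), (6, 6, 6))
        trials_a = make_trials("ImRet", range(1, 13), [1] * 12)
        trials_b = make_trials("DelRet", range(1, 13))
        a = _random_patterns(mask, trials_a, rng)
        b = _random_patterns(mask, trials_b, rng)
        stats = []
        w = build_same_vs_different(trials_a, trials_b)
        roi = mask
        for _ in range(200):
            perm = rng.permutation(12)
            b_perm = PatternSet(b.grid, b.mask, b.trials, b.values[perm])
            res = roi_rsa(a, b_perm, roi, w)
            stats.append(res.reinstatement)
        stats = np.asarray(stats)
        se = stats.std(ddof=1) / np.sqrt(len(stats))
        assert abs(stats.mean()) < 3 * se + 1e-12


class TestRoiRsa:
    def test_self_correlation_is_clipped_max(self, small_grid, rng):
        mask = box_mask(small_grid, (0, 0, 0), (5, 5, 5))
        trials_a = make_trials("ImRet", range(1, 13), [1] * 12)
        trials_b = make_trials("DelRet", range(1, 13))
        vals = rng.standard_normal((12, mask.n_voxels))
        a = PatternSet(small_grid, mask, trials_a, vals)
        b = PatternSet(small_grid, mask, trials_b, vals)
        w = build_same_vs_different(trials_a, trials_b)
        res = roi_rsa(a, b, mask, w)
        assert res.mean_same_z == pytest.approx(np.arctanh(1 - 1e-7))

    def test_roi_too_small_errors(self, small_grid, rng):
        mask = box_mask(small_grid, (0, 0, 0), (5, 5, 5))
        roi = box_mask(small_grid, (0, 0, 0), (1, 1, 1))
        trials = make_trials("DelRet", range(1, 4))
        ps = _random_patterns(mask, trials, rng)
        w = build_same_vs_different(trials, trials)
        with pytest.raises(ValueError, match="2 voxels"):
            roi_rsa(ps, ps, roi, w)

    def test_statistic_invariant_to_constant_z_shift(self, rng):
        """Zero-sum weights annihilate any constant added to all Fisher-z
        correlations (same-vs-different and weighted kinds alike)."""
        trials_a = make_trials("ImRet", range(1, 13), [1] * 12)
        trials_b = make_trials("DelRet", range(1, 13))
        w_sd = build_same_vs_different(trials_a, trials_b)
        scores = dict(zip(range(1, 13), rng.normal(11.5, 2.7, 12)))
        w_wt = build_weighted_diagonal(trials_a, trials_b, scores)
        z = rng.standard_normal(w_sd.weights.shape)
        for w in (w_sd, w_wt):
            s0 = (w.weights * z).sum()
            s1 = (w.weights * (z + 7.3)).sum()
            assert s1 == pytest.approx(s0, abs=1e-10)

    def test_weighted_map_invariant_to_score_offset(self, small_grid, rng):
        """Adding a constant to all of a subject's scores does not change the
        weighted-RSA statistic (re-centering inside the builder)."""
        mask = box_mask(small_grid, (0, 0, 0), (6, 6, 6))
        trials_a = make_trials("ImRet", range(1, 13), [1] * 12)
        trials_b = make_trials("DelRet", range(1, 13))
        a = _random_patterns(mask, trials_a, rng)
        b = _random_patterns(mask, trials_b, rng)
        scores = dict(zip(range(1, 13), rng.normal(11.5, 2.7, 12)))
        shifted = {v: s + 100.0 for v, s in scores.items()}
        w1 = build_weighted_diagonal(trials_a, trials_b, scores)
        w2 = build_weighted_diagonal(trials_a, trials_b, shifted)
        r1 = roi_rsa(a, b, mask, w1).weighted_sum
        r2 = roi_rsa(a, b, mask, w2).weighted_sum
        assert r1 == pytest.approx(r2, abs=1e-9)
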