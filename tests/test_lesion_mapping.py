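"""Lesion smoothing, coverage, voxelwise GLM and cluster permutation."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import ndimage
from sklearn.base import clone

from rhythmap.lesion_mapping import (
    VLSM,
    LesionCohort,
    cluster_correct,
    coverage_mask,
    fwhm_to_sigma,
    lesion_overlay,
    roi_damage,
    smooth_mask,
    vlsm_tmap,
)
from tests.conftest import identical_mask_cohort


class TestSmoothing:
    def test_zero_mask_stays_zero(self):
        assert smooth_mask(np.zeros((9, 9, 9)), 2.0).max() == 0.0

    def test_single_voxel_matches_direct_convolution_oracle(self):
        mask = np.zeros((21, 21, 21))
        mask[10, 10, 10] = 1.0
        out = smooth_mask(mask, voxel_size_mm=1.0, fwhm_mm=8.0)
        assert np.unravel_index(out.argmax(), out.shape) == (10, 10, 10)
        # oracle: separable discrete Gaussian, radius 4 sigma (the smoother's
        # support), normalized over its full support then indexed on the grid
        sigma = fwhm_to_sigma(8.0)
        radius = int(4 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-0.5 * (x / sigma) ** 2)
        k1 /= k1.sum()
        idx = np.arange(21) - 10 + radius
        g = k1[idx]
        oracle = g[:, None, None] * g[None, :, None] * g[None, None, :]
        np.testing.assert_allclose(out, oracle, atol=1e-12)

    def test_interior_lesion_mass_conserved(self):
        mask = np.zeros((31, 31, 31))
        mask[13:18, 13:18, 13:18] = 1.0
        out = smooth_mask(mask, 1.0, fwhm_mm=4.0)
        assert out.sum() == pytest.approx(mask.sum(), rel=1e-3)

    def test_anisotropic_voxels_warn(self):
        with pytest.warns(UserWarning, match="anisotropic"):
            smooth_mask(np.zeros((5, 5, 5)), [1.0, 1.0, 2.0])

    def test_fwhm_sigma_conversion(self):
        assert fwhm_to_sigma(8.0) == pytest.approx(8.0 / 2.3548, abs=1e-3)


class TestCoverageOverlay:
    def test_four_lesions_below_min_five_gives_empty_mask(self):
        mask = np.zeros((6, 6, 6))
        mask[2:4, 2:4, 2:4] = 1
        cohort = identical_mask_cohort(mask, 4)
        assert not coverage_mask(cohort, min_patients=5).any()

    def test_five_identical_lesions_cover_the_lesion(self):
        mask = np.zeros((6, 6, 6))
        mask[2:4, 2:4, 2:4] = 1
        cohort = identical_mask_cohort(mask, 5)
        np.testing.assert_array_equal(coverage_mask(cohort, 5), mask.astype(bool))

    def test_coverage_matches_per_voxel_loop_oracle(self, small_cohort):
        cohort, _ = small_cohort
        cov = coverage_mask(cohort, min_patients=5)
        for idx in np.ndindex(*cohort.masks.shape[1:]):
            count = sum(int(m[idx]) for m in cohort.masks)
            assert cov[idx] == (count >= 5)

    def test_overlay_identities(self, small_cohort):
        cohort, _ = small_cohort
        ov = lesion_overlay(cohort)
        assert ov.max() <= cohort.n_patients
        one = LesionCohort(masks=cohort.masks[:1], affine=cohort.affine)
        np.testing.assert_array_equal(lesion_overlay(one), cohort.masks[0])


class TestROIDamage:
    def test_superset_is_full_damage(self):
        roi = np.zeros((5, 5, 5), bool)
        roi[1:3, 1:3, 1:3] = True
        assert roi_damage(np.ones((5, 5, 5), bool), roi) == 1.0

    def test_disjoint_is_zero(self):
        roi = np.zeros((5, 5, 5), bool)
        roi[0, 0, 0] = True
        lesion = np.zeros((5, 5, 5), bool)
        lesion[4, 4, 4] = True
        assert roi_damage(lesion, roi) == 0.0

    def test_half_covered_roi(self):
        roi = np.zeros((10, 10, 1), bool)
        roi[:, :, 0] = True  # 100 voxels
        lesion = np.zeros_like(roi)
        lesion[:5, :, 0] = True
        assert roi_damage(lesion, roi) == 0.5

    def test_empty_roi_raises(self):
        with pytest.raises(ValueError, match="empty"):
            roi_damage(np.ones((3, 3, 3)), np.zeros((3, 3, 3)))


class TestVoxelwiseGLM:
    def test_t_values_match_statsmodels_ols_oracle(self, small_cohort):
        cohort, scores = small_cohort
        cov = coverage_mask(cohort, min_patients=5)
        t_map, thr = vlsm_tmap(cohort, scores, min_patients=5,
                               behavior_direction="score")
        vols = cohort.total_volumes_mm3()
        checked = 0
        for idx in zip(*np.nonzero(cov)):
            lesion_vals = cohort.masks[(slice(None), *idx)].astype(float)
            X = sm.add_constant(np.column_stack([lesion_vals, vols]))
            if np.linalg.matrix_rank(X) < 3:
                continue
            res = sm.OLS(scores, X).fit()
            np.testing.assert_allclose(-res.tvalues[1], t_map[idx], atol=1e-10)
            checked += 1
        assert checked > 20

    def test_impairment_and_score_directions_are_opposite(self, small_cohort):
        cohort, scores = small_cohort
        t_score, _ = vlsm_tmap(cohort, scores, behavior_direction="score")
        t_imp, _ = vlsm_tmap(cohort, scores, behavior_direction="impairment")
        cov = coverage_mask(cohort, 5)
        np.testing.assert_allclose(t_score[cov], -t_imp[cov], atol=1e-12)

    def test_voxel_threshold_is_t_quantile_at_df_n_minus_3(self, small_cohort):
        from scipy import stats

        cohort, scores = small_cohort
        _, thr = vlsm_tmap(cohort, scores, voxel_p=0.01)
        assert thr == pytest.approx(stats.t.ppf(0.99, cohort.n_patients - 3))

    def test_constant_behavior_raises(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ValueError, match="constant"):
            vlsm_tmap(cohort, np.ones(cohort.n_patients))

    def test_strong_planted_effect_peaks_inside_roi(self, planted_cohort):
        cohort, scores, damage, roi = planted_cohort
        t_map, _ = vlsm_tmap(cohort, scores, behavior_direction="score")
        peak = np.unravel_index(np.nanargmax(t_map), t_map.shape)
        assert roi[peak]


def flood_fill_labels(volume, connectivity):
    """Brute-force connected-component labeling oracle."""
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
        and (abs(dx) + abs(dy) + abs(dz) <= {6: 1, 18: 2, 26: 3}[connectivity])
    ]
    labels = np.zeros(volume.shape, int)
    current = 0
    for start in zip(*np.nonzero(volume)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            x, y, z = stack.pop()
            for dx, dy, dz in offsets:
                n = (x + dx, y + dy, z + dz)
                if all(0 <= n[i] < volume.shape[i] for i in range(3)):
                    if volume[n] and not labels[n]:
                        labels[n] = current
                        stack.append(n)
    return labels, current


class TestClusterCorrection:
    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_labeling_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(0)
        for _ in range(5):
            vol = rng.random((10, 10, 10)) < 0.25
            _, n_oracle = flood_fill_labels(vol, connectivity)
            structure = ndimage.generate_binary_structure(
                3, {6: 1, 18: 2, 26: 3}[connectivity]
            )
            _, n_scipy = ndimage.label(vol, structure=structure)
            assert n_scipy == n_oracle

    def test_identity_permutation_reproduces_observed_max_cluster(self, planted_cohort):
        cohort, scores, _, _ = planted_cohort
        t_map, thr = vlsm_tmap(cohort, scores, behavior_direction="score")
        res = cluster_correct(
            t_map, cohort, scores, n_perm=100, behavior_direction="score", seed=0
        )
        # recompute the observed max cluster size by thresholding the t map
        supra = np.zeros(t_map.shape, bool)
        supra[res.coverage_mask] = t_map[res.coverage_mask] >= res.voxel_threshold_t
        structure = ndimage.generate_binary_structure(3, 3)
        labels, n = ndimage.label(supra, structure=structure)
        observed_max = max(
            (int((labels == i).sum()) for i in range(1, n + 1)), default=0
        )
        assert res.clusters[0].size_voxels == observed_max

    def test_smallest_possible_corrected_p(self, planted_cohort):
        cohort, scores, _, roi = planted_cohort
        t_map, _ = vlsm_tmap(cohort, scores, behavior_direction="score")
        res = cluster_correct(
            t_map, cohort, scores, n_perm=199, behavior_direction="score", seed=1
        )
        assert res.clusters
        assert min(c.corrected_p for c in res.clusters) >= 1 / 200
        # corrected p non-increasing in cluster size
        sizes = [c.size_voxels for c in res.clusters]
        ps = [c.corrected_p for c in res.clusters]
        for (s1, p1), (s2, p2) in zip(zip(sizes, ps), zip(sizes[1:], ps[1:])):
            assert (s1 >= s2) == (p1 <= p2) or p1 == p2

    def test_permutation_engine_reproducible_bitwise(self, planted_cohort):
        cohort, scores, _, _ = planted_cohort
        t_map, _ = vlsm_tmap(cohort, scores, behavior_direction="score")
        kw = dict(n_perm=150, behavior_direction="score", seed=42)
        a = cluster_correct(t_map, cohort, scores, **kw)
        b = cluster_correct(t_map, cohort, scores, **kw)
        np.testing.assert_array_equal(a.null_max_cluster_sizes, b.null_max_cluster_sizes)
        assert [c.corrected_p for c in a.clusters] == [c.corrected_p for c in b.clusters]

    def test_low_n_perm_warns(self, planted_cohort):
        cohort, scores, _, _ = planted_cohort
        t_map, _ = vlsm_tmap(cohort, scores, behavior_direction="score")
        with pytest.warns(UserWarning, match="low"):
            cluster_correct(t_map, cohort, scores, n_perm=50,
                            behavior_direction="score", seed=0)


class TestVLSMEstimator:
    def test_planted_roi_recovered_as_top_cluster(self, planted_cohort):
        cohort, scores, _, roi = planted_cohort
        est = VLSM(n_permutations=500, behavior_direction="score", random_state=0)
        est.fit(cohort, scores)
        assert len(est.significant_clusters_) >= 1
        top = est.clusters_.iloc[0]
        com_world = np.array([top.com_x_mm, top.com_y_mm, top.com_z_mm, 1.0])
        com_vox = np.linalg.inv(cohort.affine) @ com_world
        assert roi[tuple(np.round(com_vox[:3]).astype(int))]
        assert top.corrected_p <= 0.05

    def test_clusters_only_inside_coverage(self, planted_cohort):
        cohort, scores, _, _ = planted_cohort
        est = VLSM(n_permutations=200, behavior_direction="score", random_state=0)
        est.fit(cohort, scores)
        assert np.isnan(est.t_map_[~est.coverage_mask_]).all()

    def test_sklearn_params_and_clone(self):
        est = VLSM(n_permutations=123, fwhm_mm=4.0)
        c = clone(est)
        assert c.get_params()["n_permutations"] == 123
        assert c.get_params()["fwhm_mm"] == 4.0

    def test_unsmoothed_binary_fit_also_works(self, planted_cohort):
        cohort, scores, _, _ = planted_cohort
        est = VLSM(fwhm_mm=0.0, n_permutations=100,
                   behavior_direction="score", random_state=0)
        est.fit(cohort, scores)
        assert est.clusters_ is not None

    def test_invalid_connectivity_raises(self, planted_cohort):
        cohort, scores, _, _ = planted_cohort
        with pytest.raises(ValueError, match="connectivity"):
            VLSM(connectivity=10, n_permutations=100).fit(cohort, scores)
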