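"""GLM, TFCE, permutation inference, PCA shape models, region overlap."""

import numpy as np
import pytest
from scipy import ndimage, stats

from fetalatlas.tbm import (DesignMatrix, cluster_region_overlap,
                            components_for_variance_fraction, glm_tstat,
                            pca_shape_model, permutation_fwer,
                            residualize_covariate, shape_variation_at_sd,
                            tfce_enhance)
from fetalatlas.volume import LabelMap
from oracles import tfce_bruteforce


class TestResidualize:
    def test_orthogonal_centred_covariate_unchanged(self):
        group = np.array([1.0, 1, -1, -1])
        cov = np.array([1.0, -1, 1, -1])  # centred, orthogonal to group
        np.testing.assert_allclose(residualize_covariate(cov, group), cov,
                                   atol=1e-12)

    def test_covariate_equal_to_group_zeroed(self):
        group = np.array([1.0, 1, -1, -1])
        np.testing.assert_allclose(residualize_covariate(group, group), 0,
                                   atol=1e-12)

    def test_residual_orthogonal_to_design(self, rng):
        group = np.array([1.0] * 6 + [-1.0] * 6)
        cov = rng.normal(20, 3, 12)
        r = residualize_covariate(cov, group)
        assert abs(r.sum()) < 1e-10
        assert abs(r @ group) < 1e-10


class TestGLM:
    def test_matches_two_sample_t(self, rng):
        maps = rng.normal(0, 1, (10, 6, 6, 6))
        maps[:5] += 1.0
        design = DesignMatrix(np.array([1.0] * 5 + [-1.0] * 5))
        t = glm_tstat(maps, design)
        expected = stats.ttest_ind(maps[:5], maps[5:], axis=0).statistic
        np.testing.assert_allclose(t, expected, rtol=1e-10)

    def test_identical_groups_zero_and_antisymmetry(self, rng):
        maps = rng.normal(0, 1, (8, 5, 5, 5))
        g = np.array([1.0] * 4 + [-1.0] * 4)
        t1 = glm_tstat(maps, DesignMatrix(g))
        t2 = glm_tstat(maps, DesignMatrix(-g))
        np.testing.assert_allclose(t1, -t2, atol=1e-12)
        same = np.concatenate([maps[:4], maps[:4]])
        t0 = glm_tstat(same, DesignMatrix(g))
        np.testing.assert_allclose(t0, 0, atol=1e-8)


class TestTFCE:
    def test_zero_map(self):
        assert np.all(tfce_enhance(np.zeros((8, 8, 8))) == 0)

    def test_single_voxel_closed_form(self):
        stat = np.zeros((9, 9, 9))
        stat[4, 4, 4] = 2.0
        out = tfce_enhance(stat, E=0.5, H=2.0)
        # single voxel: sum 1^E · h^H · dh ≈ h0^{H+1}/(H+1)
        assert out[4, 4, 4] == pytest.approx(2.0 ** 3 / 3.0, rel=0.02)
        assert np.count_nonzero(out) == 1

    @pytest.mark.parametrize("conn", [6, 26])
    def test_matches_bruteforce_on_random_maps(self, rng, conn):
        for _ in range(20):
            m = ndimage.gaussian_filter(rng.standard_normal((16, 16, 16)), 1.2)
            ours = tfce_enhance(m, connectivity=conn)
            oracle = tfce_bruteforce(m, conn=conn)
            assert np.abs(ours - oracle).max() <= 0.01 * np.abs(oracle).max()

    def test_nonpositive_dh_rejected(self):
        with pytest.raises(ValueError):
            tfce_enhance(np.ones((4, 4, 4)), dh=0.0)


class TestPermutationFWER:
    def _exact_oracle(self, maps, group):
        """Exhaustive max-TFCE enumeration, fully independent code path."""
        from itertools import combinations
        n = len(group)
        plus = np.flatnonzero(group > 0)
        minus = np.flatnonzero(group < 0)
        flat = maps.reshape(n, -1)
        mean = flat.mean(0)
        resid = flat - mean

        obs_shape = maps.shape[1:]
        maxes, tfces = [], {}
        for subset in combinations(range(n), len(plus)):
            perm = np.empty(n, dtype=int)
            perm[plus] = subset
            perm[minus] = [i for i in range(n) if i not in subset]
            y = (mean + resid[perm]).reshape(maps.shape)
            t = stats.ttest_ind(y[group > 0], y[group < 0], axis=0).statistic
            enh = np.abs(tfce_bruteforce(np.abs(t)))
            tfces[subset] = enh
            maxes.append(enh.max())
        obs = tfces[tuple(plus)]
        maxes = np.array(maxes)
        p = np.array([(maxes >= v).sum() for v in obs.ravel()]) / len(maxes)
        return p.reshape(obs_shape)

    def test_exact_enumeration_4v4(self, rng):
        maps = rng.normal(0, 1, (8, 6, 6, 6))
        maps[:4, 2:4, 2:4, 2:4] += 2.5
        group = np.array([1.0] * 4 + [-1.0] * 4)
        res = permutation_fwer(maps, DesignMatrix(group), n_perm=100, seed=0)
        assert res.exhaustive and res.n_permutations == 70
        oracle_p = self._exact_oracle(maps, group)
        np.testing.assert_allclose(res.p_corrected, oracle_p, atol=1e-12)

    def test_strong_effect_detected(self, rng):
        maps = np.stack([ndimage.gaussian_filter(
            rng.standard_normal((12, 12, 12)), 1.0) for _ in range(20)])
        region = np.zeros((12, 12, 12), bool)
        region[4:8, 4:8, 4:8] = True
        maps[:10][:, region] += 3.0  # Cohen's d = 3 in the region
        design = DesignMatrix(np.array([1.0] * 10 + [-1.0] * 10))
        res = permutation_fwer(maps, design, n_perm=500, seed=1)
        assert res.significant[region].mean() > 0.5
        assert res.significant[~region].mean() < 0.05

    def test_determinism_given_seed(self, rng):
        maps = rng.normal(0, 1, (12, 8, 8, 8))
        design = DesignMatrix(np.tile([1.0, -1.0], 6),
                              covariate=rng.normal(20, 2, 12))
        r1 = permutation_fwer(maps, design, n_perm=150, seed=7)
        r2 = permutation_fwer(maps, design, n_perm=150, seed=7)
        np.testing.assert_array_equal(r1.p_corrected, r2.p_corrected)


class TestShapeModel:
    def test_identical_fields_give_empty_model(self):
        f = np.ones((4, 4, 4, 3))
        model = pca_shape_model([f, f.copy(), f.copy()])
        assert len(model.variances) == 0

    def test_single_mode_cohort(self, rng):
        mode = rng.normal(0, 1, (5, 5, 5, 3))
        mode /= np.linalg.norm(mode)
        coeffs = rng.normal(0, 2.0, 30)
        fields = [c * mode for c in coeffs]
        model = pca_shape_model(fields)
        assert model.explained_fractions[0] >= 0.99
        cos = abs(model.components[0] @ mode.ravel())
        assert cos >= 0.99
        assert components_for_variance_fraction(model, 0.95) == 1

    def test_completeness_and_reconstruction(self, rng):
        data = [rng.normal(0, 1, (4, 4, 4, 3)) for _ in range(6)]
        model = pca_shape_model(data)
        assert model.cumulative_fractions[-1] == pytest.approx(1.0, abs=1e-8)
        assert len(model.variances) == 5  # n − 1 non-trivial components
        # projecting a sample onto all components reproduces it
        x = data[2].ravel() - model.mean
        recon = model.components.T @ (model.components @ x)
        np.testing.assert_allclose(recon, x, atol=1e-8)

    def test_components_orthonormal_and_order_invariant(self, rng):
        data = [rng.normal(0, 1, (3, 3, 3, 3)) for _ in range(8)]
        model = pca_shape_model(data)
        G = model.components @ model.components.T
        np.testing.assert_allclose(G, np.eye(len(G)), atol=1e-10)
        perm_model = pca_shape_model([data[i] for i in (3, 1, 7, 0, 2, 6, 4, 5)])
        np.testing.assert_allclose(np.sort(model.variances),
                                   np.sort(perm_model.variances), rtol=1e-9)

    def test_shape_variation_linearity(self, rng):
        data = [rng.normal(0, 1, (3, 3, 3, 3)) for _ in range(5)]
        model = pca_shape_model(data)
        mid = 0.5 * (shape_variation_at_sd(model, 0, 2.0)
                     + shape_variation_at_sd(model, 0, -2.0))
        np.testing.assert_allclose(mid.ravel(), model.mean, atol=1e-10)
        np.testing.assert_allclose(shape_variation_at_sd(model, 0, 0.0).ravel(),
                                   model.mean, atol=1e-12)

    def test_variance_fraction_hand_case(self):
        # hand case: variances (0.5, 0.3, 0.2) → cumulative (0.5, 0.8, 1.0)
        from fetalatlas.tbm import ShapeModel
        m = ShapeModel(mean=np.zeros(3), components=np.eye(3),
                       variances=np.array([0.5, 0.3, 0.2]), field_shape=None,
                       size_corrected=False, n_samples=4)
        assert components_for_variance_fraction(m, 0.68) == 2
        assert components_for_variance_fraction(m, 0.79) == 2
        assert components_for_variance_fraction(m, 0.81) == 3


class TestRegionOverlap:
    def _parcellation(self):
        lab = np.zeros((10, 10, 10), dtype=np.int16)
        lab[:5] = 1
        lab[5:] = 2
        return LabelMap(lab, labels={1: "anterior", 2: "posterior"})

    def test_mask_inside_one_region(self):
        parc = self._parcellation()
        sig = np.zeros((10, 10, 10), bool)
        sig[1:3, 1:3, 1:3] = True
        table = cluster_region_overlap(sig, parc)
        r1 = table.set_index("region_id")
        assert r1.loc[1, "pct_cluster_in_region"] == 100.0
        assert r1.loc[2, "pct_cluster_in_region"] == 0.0

    def test_split_mask_and_display_threshold(self):
        parc = self._parcellation()
        sig = np.zeros((10, 10, 10), bool)
        sig[4:6] = True  # 100 voxels in each region; regions are 500 each
        table = cluster_region_overlap(sig, parc).set_index("region_id")
        assert table.loc[1, "pct_cluster_in_region"] == 50.0
        assert table.loc[2, "pct_cluster_in_region"] == 50.0
        assert table.loc[1, "pct_region_significant"] == 20.0
        assert bool(table.loc[1, "display"]) is True
        # a region with 9% significant voxels is not displayed
        sig2 = np.zeros((10, 10, 10), bool)
        sig2.reshape(-1)[:45] = True  # 45/500 = 9% of region 1
        t2 = cluster_region_overlap(sig2, parc).set_index("region_id")
        assert bool(t2.loc[1, "display"]) is False

    def test_empty_parcellation_rejected(self):
        with pytest.raises(ValueError):
            cluster_region_overlap(np.zeros((4, 4, 4), bool),
                                   np.zeros((4, 4, 4), dtype=np.int16))
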