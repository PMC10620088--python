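"""Preprocessing: resampling, cropping, Procrustes, matching, edge maps."""

import numpy as np
import pytest
from scipy import ndimage

from fetalatlas.preprocess import (LandmarkSet, crop_to_cube, histogram_match,
                                   mask_brain, mirror_midsagittal,
                                   monogenic_feature_asymmetry,
                                   resample_isotropic, rigid_align,
                                   select_hemisphere)
from fetalatlas.volume import Volume3D


class TestResample:
    def test_isotropic_input_unchanged(self, rng):
        vol = Volume3D(rng.random((16, 16, 16)), (0.6, 0.6, 0.6))
        out = resample_isotropic(vol)
        np.testing.assert_array_equal(out.values, vol.values)

    def test_constant_volume_stays_constant(self):
        vol = Volume3D(np.full((12, 20, 9), 3.25), (0.32, 0.51, 0.85))
        out = resample_isotropic(vol)
        assert out.spacing_mm == (0.6, 0.6, 0.6)
        np.testing.assert_allclose(out.values, 3.25, atol=1e-12)

    def test_linear_ramp_reproduced_exactly(self):
        # trilinear interpolation is exact on linear functions
        x, y, z = np.meshgrid(np.arange(20), np.arange(24), np.arange(16),
                              indexing="ij")
        ramp = 0.5 * x + 0.25 * y - 0.125 * z
        vol = Volume3D(ramp.astype(float), (0.4, 0.9, 0.7))
        out = resample_isotropic(vol)
        xo, yo, zo = np.meshgrid(*[np.arange(n) for n in out.shape],
                                 indexing="ij")
        expected = (0.5 * xo * 0.6 / 0.4 + 0.25 * yo * 0.6 / 0.9
                    - 0.125 * zo * 0.6 / 0.7)
        interior = (slice(1, -1),) * 3
        np.testing.assert_allclose(out.values[interior], expected[interior],
                                   atol=1e-9)

    def test_missing_spacing_rejected(self, rng):
        with pytest.raises(ValueError):
            Volume3D(rng.random((8, 8, 8)), (0.0, 0.6, 0.6))


class TestCrop:
    def test_identity_crop(self, rng):
        vol = Volume3D(rng.random((16, 16, 16)))
        out = crop_to_cube(vol, size=16, centre=(8, 8, 8))
        np.testing.assert_array_equal(out.values, vol.values)

    def test_corner_centre_mostly_padding(self, rng):
        vol = Volume3D(np.ones((32, 32, 32)))
        out = crop_to_cube(vol, size=32, centre=(0, 0, 0))
        # only the (+,+,+) octant overlaps data: ≥ 7/8 of output is zeros
        assert (out.values == 0).mean() >= 7 / 8

    def test_mask_conserved_when_interior(self, clean_phantom):
        _, _, lab = clean_phantom
        vol = Volume3D((lab.values > 0).astype(float))
        out = crop_to_cube(vol, size=44, centre=(24, 24, 24))
        assert out.values.sum() == pytest.approx(vol.values.sum())


class TestRigidAlign:
    PTS = np.array([[0.0, 10.0, 3.0], [0.0, -8.0, 4.0], [0.0, 2.0, -5.0]])

    def _lm(self, pts):
        return LandmarkSet(("a", "b", "c"), pts)

    def test_identity(self):
        tf = rigid_align(self._lm(self.PTS), self._lm(self.PTS))
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(tf.translation_mm, 0, atol=1e-12)
        assert tf.scale == pytest.approx(1.0)

    def test_pure_translation_recovered(self):
        tf = rigid_align(self._lm(self.PTS), self._lm(self.PTS + (5, 0, 0)))
        np.testing.assert_allclose(tf.translation_mm, (5, 0, 0), atol=1e-10)
        assert tf.scale == pytest.approx(1.0)

    def test_scale_about_centroid_recovered(self):
        centroid = self.PTS.mean(0)
        doubled = centroid + 2.0 * (self.PTS - centroid)
        tf = rigid_align(self._lm(self.PTS), self._lm(doubled))
        assert tf.scale == pytest.approx(2.0)

    def test_invariant_to_common_rigid_motion(self, rng):
        # applying one rigid motion to both sets leaves the fit exact
        theta = 0.3
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        src = self.PTS + rng.normal(0, 2, self.PTS.shape)
        dst = self.PTS
        tf0 = rigid_align(self._lm(src), self._lm(dst))
        moved_src = src @ R.T + (1.0, -2.0, 3.0)
        moved_dst = dst @ R.T + (1.0, -2.0, 3.0)
        tf1 = rigid_align(self._lm(moved_src), self._lm(moved_dst))
        assert tf1.scale == pytest.approx(tf0.scale, rel=1e-9)
        # residuals are preserved under the common motion
        r0 = np.linalg.norm(tf0.apply(src) - dst)
        r1 = np.linalg.norm(tf1.apply(moved_src) - moved_dst)
        assert r1 == pytest.approx(r0, abs=1e-9)

    def test_collinear_landmarks_rejected(self):
        pts = np.array([[0, 0, 0.0], [1, 1, 1.0], [2, 2, 2.0]])
        with pytest.raises(ValueError, match="degenerate"):
            rigid_align(self._lm(pts), self._lm(self.PTS))


class TestMaskAndHistogram:
    def test_mask_identity_and_zero(self, noisy_phantom):
        _, vol, lab = noisy_phantom
        ones = np.ones(vol.shape)
        np.testing.assert_array_equal(mask_brain(vol, ones).values, vol.values)
        assert mask_brain(vol, np.zeros(vol.shape)).values.sum() == 0

    def test_mask_conserves_interior_sum(self, noisy_phantom):
        _, vol, lab = noisy_phantom
        m = lab.mask()
        out = mask_brain(vol, m)
        assert out.values.sum() == pytest.approx(vol.values[m].sum())

    def test_histmatch_self_is_identity(self, noisy_phantom):
        _, vol, _ = noisy_phantom
        out = histogram_match(vol, vol, n_levels=256)
        assert np.abs(out.values - vol.values).max() < np.ptp(vol.values) / 64

    def test_histmatch_monotone_transform_matches_cdf(self, rng):
        ref = Volume3D(rng.gamma(2.0, 1.0, (24, 24, 24)))
        src = Volume3D(np.sqrt(ref.values) * 3.0 + 1.0)  # monotone transform
        out = histogram_match(src, ref, n_levels=256)
        qs = np.linspace(0.01, 0.99, 99)
        gap = np.abs(np.quantile(out.values, qs) - np.quantile(ref.values, qs))
        assert gap.max() < np.ptp(ref.values) * 2 / 256
        assert out.values.min() >= ref.values.min() - 1e-9
        assert out.values.max() <= ref.values.max() + 1e-9

    def test_histmatch_constant_reference_degenerate(self, noisy_phantom):
        _, vol, _ = noisy_phantom
        ref = Volume3D(np.full(vol.shape, 2.0))
        out = histogram_match(vol, ref)
        np.testing.assert_array_equal(out.values, vol.values)


class TestFeatureAsymmetry:
    def test_constant_volume_gives_zero(self):
        out = monogenic_feature_asymmetry(Volume3D(np.full((32, 32, 32), 5.0)))
        assert np.all(out.values == 0)

    def test_step_edge_peaks_at_step_plane(self):
        # 1D step embedded in 3D; the 1D analytic-signal oracle puts the
        # odd-dominant response at the discontinuity plane
        vals = np.zeros((64, 32, 32))
        vals[32:] = 1.0
        vals = ndimage.gaussian_filter(vals, (1.0, 0, 0))
        fa = monogenic_feature_asymmetry(Volume3D(vals)).values
        profile = fa[:, 16, 16]
        peak = np.argmax(profile)
        assert abs(peak - 31.5) <= 1.5
        # 1D oracle: Hilbert-based odd response along the step axis (interior
        # only — the circular Hilbert transform has wrap artefacts at 0/N)
        from scipy.signal import hilbert
        sig = vals[:, 16, 16] - vals[:, 16, 16].mean()
        odd = np.abs(np.imag(hilbert(sig)))
        interior = slice(8, 56)
        oracle_peak = 8 + np.argmax(odd[interior])
        assert abs(oracle_peak - peak) <= 2

    def test_contrast_invariance(self, noisy_phantom):
        _, vol, _ = noisy_phantom
        fa1 = monogenic_feature_asymmetry(vol).values
        fa2 = monogenic_feature_asymmetry(
            vol.with_values(3.7 * vol.values + 11.0)).values
        assert np.abs(fa1 - fa2).max() < 0.05

    def test_range_bounded(self, noisy_phantom):
        _, vol, _ = noisy_phantom
        fa = monogenic_feature_asymmetry(vol).values
        assert fa.min() >= 0.0 and fa.max() <= 1.0


class TestHemisphere:
    def test_full_margin_is_identity(self, noisy_phantom):
        _, vol, _ = noisy_phantom
        with pytest.raises(ValueError):
            select_hemisphere(vol, "left", margin=vol.shape[0] // 2)
        out = select_hemisphere(vol, "left", margin=vol.shape[0] // 2 - 1)
        kept = (out.values != 0).sum()
        assert kept >= (vol.values != 0).sum() * 0.9

    def test_margin_zero_partitions_brain(self, noisy_phantom):
        _, vol, _ = noisy_phantom
        left = select_hemisphere(vol, "left", margin=0)
        right = select_hemisphere(vol, "right", margin=0)
        np.testing.assert_allclose(left.values + right.values, vol.values,
                                   atol=1e-12)

    def test_retained_voxel_count_with_margin(self):
        vol = Volume3D(np.ones((160, 4, 4)))
        out = select_hemisphere(vol, "left", margin=10)
        assert out.values.sum() == (80 + 10) * 16

    def test_mirror_involution_and_conservation(self, noisy_phantom):
        _, vol, _ = noisy_phantom
        m = mirror_midsagittal(vol)
        np.testing.assert_array_equal(mirror_midsagittal(m).values, vol.values)
        assert m.values.sum() == pytest.approx(vol.values.sum())

    def test_mirror_point_mass_index_arithmetic(self):
        vals = np.zeros((160, 8, 8))
        vals[10, 3, 4] = 1.0
        out = mirror_midsagittal(Volume3D(vals))
        assert out.values[149, 3, 4] == 1.0
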