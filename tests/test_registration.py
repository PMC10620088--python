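"""Demons registration, groupwise atlas construction, affine normalisation."""

import numpy as np
import pytest

from fetalatlas.fields import exp_velocity
from fetalatlas.morphometry import jacobian_determinant
from fetalatlas.registration import (AffineTransform, DemonsParams,
                                     affine_size_normalize, apply_affine,
                                     build_groupwise_atlas,
                                     demons_multichannel, warp_volume)
from fetalatlas.synthetic import (PhantomSpec, apply_known_warp,
                                  generate_phantom, random_smooth_velocity)
from fetalatlas.volume import Volume3D

LIGHT = DemonsParams(n_levels=2, iterations=(10, 20))


def _blob(grid=32, centre=None, widths=(6.0, 7.0, 6.5)):
    centre = centre or [grid / 2.0] * 3
    x, y, z = np.meshgrid(*[np.arange(grid)] * 3, indexing="ij")
    return np.exp(-(((x - centre[0]) / widths[0]) ** 2
                    + ((y - centre[1]) / widths[1]) ** 2
                    + ((z - centre[2]) / widths[2]) ** 2))


class TestDemons:
    def test_identical_images_give_no_motion(self):
        blob = _blob()
        _, d = demons_multichannel([blob], [blob], LIGHT)
        assert d.max_magnitude() < 0.05

    def test_translation_recovered(self):
        blob = _blob(48, widths=(8.0, 10.0, 9.0))
        moving = np.roll(blob, 2, axis=1)
        params = DemonsParams(n_levels=3, iterations=(25, 50, 100))
        _, d = demons_multichannel([blob], [moving], params)
        support = blob > 0.1
        mean_u = d.vectors[support].mean(0)
        # moving(x + u) ≈ fixed(x) with moving shifted +2 along axis 1
        assert np.abs(mean_u - (0.0, 2.0, 0.0)).max() < 0.3
        assert jacobian_determinant(d).values.min() > 0

    def test_zero_weight_channel_is_ignored(self):
        blob = _blob()
        other = np.roll(blob, 3, axis=0)
        p1 = DemonsParams(n_levels=2, iterations=(10, 20),
                          channel_weights=(1.0, 0.0))
        v1, _ = demons_multichannel([blob, blob], [np.roll(blob, 1, 2), other],
                                    p1)
        v2, _ = demons_multichannel([blob], [np.roll(blob, 1, 2)],
                                    DemonsParams(n_levels=2,
                                                 iterations=(10, 20)))
        np.testing.assert_allclose(v1.vectors, v2.vectors, atol=1e-12)

    def test_channel_count_mismatch_rejected(self):
        blob = _blob()
        with pytest.raises(ValueError):
            demons_multichannel([blob, blob], [blob], LIGHT)

    def test_nonfinite_rejected(self):
        blob = _blob()
        bad = blob.copy()
        bad[0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            demons_multichannel([blob], [bad], LIGHT)


class TestWarpVolume:
    def test_identity_and_integer_shift(self, rng):
        vol = Volume3D(rng.random((16, 16, 16)))
        from fetalatlas.fields import DeformationField
        assert np.array_equal(
            warp_volume(vol, DeformationField.zero(vol.shape)).values,
            vol.values)
        d = np.zeros((16, 16, 16, 3))
        d[..., 0] = 1.0
        out = warp_volume(vol, DeformationField(d), interpolation="nearest")
        np.testing.assert_array_equal(out.values[:-1], vol.values[1:])

    def test_scaling_field_changes_mask_volume_by_det(self):
        # backward scaling field u(x) = (1/s − 1)(x − c): samples at x/s,
        # so a radius-r sphere maps to radius s·r (volume × s³)
        grid, s = 48, 1.12
        c = (grid - 1) / 2.0
        x, y, z = np.meshgrid(*[np.arange(grid, dtype=float)] * 3,
                              indexing="ij")
        r = np.sqrt((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2)
        sphere = (r <= 10).astype(float)
        u = np.stack([(1 / s - 1) * (x - c), (1 / s - 1) * (y - c),
                      (1 / s - 1) * (z - c)], -1)
        from fetalatlas.fields import DeformationField
        out = warp_volume(Volume3D(sphere), DeformationField(u),
                          interpolation="nearest")
        ratio = out.values.sum() / sphere.sum()
        assert ratio == pytest.approx(s ** 3, rel=0.03)


class TestGroupwiseAtlas:
    def test_identical_copies_reproduce_image(self, noisy_phantom):
        _, vol, _ = noisy_phantom
        atlas = build_groupwise_atlas([(vol,)] * 3, LIGHT, max_outer=2)
        np.testing.assert_allclose(atlas.mean_image.values, vol.values,
                                   atol=np.ptp(vol.values) * 0.01)
        assert max(f.max_magnitude() for f in atlas.fields) < 0.05

    def test_order_invariance(self):
        spec = PhantomSpec(ga_weeks=24.0, grid_size=32, noise_level=0.1,
                           seed=3)
        base, _ = generate_phantom(spec)
        rng = np.random.default_rng(0)
        scans = []
        for _ in range(4):
            v = random_smooth_velocity(base.shape, 1.0, rng, smooth_sigma=4.0)
            scans.append((apply_known_warp(base, exp_velocity(v)),))
        a1 = build_groupwise_atlas(scans, LIGHT, max_outer=2)
        a2 = build_groupwise_atlas([scans[i] for i in (2, 0, 3, 1)], LIGHT,
                                   max_outer=2)
        np.testing.assert_allclose(a1.mean_image.values, a2.mean_image.values,
                                   atol=1e-7)

    def test_debiasing_keeps_mean_displacement_small(self):
        spec = PhantomSpec(ga_weeks=24.0, grid_size=32, noise_level=0.1,
                           seed=4)
        base, _ = generate_phantom(spec)
        rng = np.random.default_rng(1)
        scans = []
        for _ in range(5):
            v = random_smooth_velocity(base.shape, 1.5, rng, smooth_sigma=4.0)
            scans.append((apply_known_warp(base, exp_velocity(v)),))
        atlas = build_groupwise_atlas(scans, LIGHT, max_outer=2)
        assert atlas.mean_displacement_magnitude() <= 0.5
        for lj in atlas.log_jacobians:
            assert np.exp(lj).min() > 0

    def test_fewer_than_two_scans_rejected(self, noisy_phantom):
        _, vol, _ = noisy_phantom
        with pytest.raises(ValueError):
            build_groupwise_atlas([(vol,)], LIGHT)


class TestAtlasBundle:
    def test_roundtrip(self, noisy_phantom, tmp_path):
        from fetalatlas.registration import (load_atlas_bundle,
                                             save_atlas_bundle)
        _, vol, _ = noisy_phantom
        atlas = build_groupwise_atlas([(vol,)] * 2, LIGHT, max_outer=1,
                                      week=24.0, hemisphere="left")
        save_atlas_bundle(atlas, tmp_path / "bundle")
        back = load_atlas_bundle(tmp_path / "bundle")
        assert back.week == 24.0 and back.hemisphere == "left"
        assert back.n_scans == 2 and len(back.fields) == 2
        np.testing.assert_allclose(back.mean_image.values,
                                   atlas.mean_image.values, atol=1e-5)
        np.testing.assert_allclose(back.fields[0].vectors,
                                   atlas.fields[0].vectors, atol=1e-5)
        assert back.fields[0].direction == "template_to_scan"


class TestAffineNormalize:
    def test_identity_for_equal_input(self, clean_phantom):
        _, vol, lab = clean_phantom
        mask = lab.mask()
        outs, tfs = affine_size_normalize([vol], [mask])
        np.testing.assert_allclose(tfs[0].matrix, np.eye(3), atol=1e-6)
        assert tfs[0].isotropic_scale == pytest.approx(1.0, abs=1e-6)

    def test_known_scaling_recovered(self):
        s = 1.2
        spec_a = PhantomSpec(ga_weeks=24.0, grid_size=64, noise_level=0.0)
        spec_b = PhantomSpec(ga_weeks=24.0, grid_size=64, noise_level=0.0,
                             size_jitter=s - 1.0)
        vol_a, lab_a = generate_phantom(spec_a)
        vol_b, lab_b = generate_phantom(spec_b)
        # normalise the scaled brain onto the unscaled target
        _, tfs = affine_size_normalize([vol_a, vol_b],
                                       [lab_a.mask(), lab_b.mask()],
                                       target_mask=lab_a.mask())
        assert tfs[1].isotropic_scale == pytest.approx(1.0 / s, rel=0.02)
        vol_ratio = lab_a.mask().sum() / lab_b.mask().sum()
        assert np.linalg.det(tfs[1].matrix) == pytest.approx(vol_ratio,
                                                             rel=0.05)

    def test_apply_affine_translation(self, rng):
        vol = Volume3D(rng.random((16, 16, 16)))
        tf = AffineTransform(np.eye(3), np.array([2.0, 0.0, 0.0]))
        out = apply_affine(vol, tf)
        np.testing.assert_allclose(out.values[2:], vol.values[:-2], atol=1e-9)

    def test_empty_mask_rejected(self, clean_phantom):
        _, vol, _ = clean_phantom
        with pytest.raises(ValueError, match="empty"):
            affine_size_normalize([vol], [np.zeros(vol.shape, bool)])
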