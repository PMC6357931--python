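"""NMI similarity and affine/FFD transform recovery."""

import numpy as np
import pytest
import SimpleITK as sitk
from scipy import ndimage as ndi

from coroflow import (MotionModel, RegistrationSettings, apply_transform,
                      generate_tree, normalized_mutual_information,
                      register_affine, register_ffd, register_masks,
                      render_sequence)
from coroflow.registration import TransformModel, transform_points

from conftest import dice


class TestNMI:
    def test_self_similarity_is_two(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(size=(64, 64))
        assert normalized_mutual_information(a, a) == pytest.approx(2.0)

    def test_constant_image_gives_one_with_warning(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(size=(32, 32))
        with pytest.warns(UserWarning, match="constant"):
            val = normalized_mutual_information(a, np.zeros((32, 32)))
        assert val == 1.0

    def test_independent_noise_near_one(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(size=(256, 256))
        b = rng.uniform(size=(256, 256))
        assert normalized_mutual_information(a, b, bins=32) == \
            pytest.approx(1.0, abs=0.02)

    def test_symmetry_and_bounds(self, soft_vessel):
        rng = np.random.default_rng(4)
        pairs = [(soft_vessel, np.roll(soft_vessel, 3, axis=0)),
                 (soft_vessel, rng.uniform(size=soft_vessel.shape))]
        for a, b in pairs:
            ab = normalized_mutual_information(a, b)
            ba = normalized_mutual_information(b, a)
            assert ab == pytest.approx(ba, abs=1e-12)
            assert 1.0 - 1e-9 <= ab <= 2.0 + 1e-9

    def test_rejects_shape_mismatch_and_bad_bins(self):
        with pytest.raises(ValueError):
            normalized_mutual_information(np.zeros((4, 4)), np.zeros((5, 4)))
        with pytest.raises(ValueError):
            normalized_mutual_information(np.zeros((4, 4)), np.zeros((4, 4)),
                                          bins=1)


class TestAffine:
    def test_identity_recovery(self, soft_vessel):
        model, report = register_affine(soft_vessel, soft_vessel)
        assert abs(model.translation_px[0]) < 0.5
        assert abs(model.translation_px[1]) < 0.5
        assert np.abs(model.linear - np.eye(2)).max() < 1e-2
        assert report.nmi_after >= report.nmi_before - 1e-3

    def test_translation_recovery(self, soft_vessel):
        moved = np.roll(soft_vessel, (5, -3), axis=(0, 1))
        model, _ = register_affine(soft_vessel, moved)
        assert model.translation_px[0] == pytest.approx(5.0, abs=0.5)
        assert model.translation_px[1] == pytest.approx(-3.0, abs=0.5)

    def test_scale_recovery(self, soft_vessel):
        # moving = fixed magnified by 1.03 about the image centre
        tx = sitk.AffineTransform(2)
        c = soft_vessel.shape[0] / 2.0
        tx.SetCenter((c, c))
        tx.SetMatrix((1 / 1.03, 0.0, 0.0, 1 / 1.03))
        img = sitk.GetImageFromArray(soft_vessel.astype(np.float32))
        moving = sitk.GetArrayFromImage(
            sitk.Resample(img, img, tx, sitk.sitkLinear, 0.0))
        model, _ = register_affine(soft_vessel, moving)
        scale = np.sqrt(abs(np.linalg.det(model.linear)))
        assert scale == pytest.approx(1.03, abs=0.01)


class TestFFD:
    def test_identity_adds_no_displacement(self, soft_vessel, vessel_mask):
        model, _ = register_ffd(soft_vessel, soft_vessel,
                                TransformModel.identity())
        pts = np.argwhere(vessel_mask)[::9].astype(float)
        mapped = transform_points(model, pts)
        assert np.linalg.norm(mapped - pts, axis=1).max() < 0.5

    def test_known_warp_recovery(self, soft_vessel, vessel_mask):
        """A 4-px single-bump warp is recovered to sub-pixel residual on
        vessel pixels."""
        cy, cx = np.argwhere(vessel_mask).mean(axis=0)
        yy, xx = np.mgrid[:256, :256].astype(float)

        def bump(y, x):
            return 4.0 * np.exp(-((y - cy) ** 2 + (x - cx) ** 2)
                                / (2 * 30.0 ** 2))

        warped = ndi.map_coordinates(soft_vessel, [yy + bump(yy, xx), xx],
                                     order=1)
        model, report = register_ffd(soft_vessel, warped,
                                     TransformModel.identity())
        pts = np.argwhere(vessel_mask)[::5].astype(float)
        truth = pts.copy()
        truth[:, 0] -= bump(pts[:, 0], pts[:, 1])
        mapped = transform_points(model, pts)
        residual = np.linalg.norm(mapped - truth, axis=1)
        initial = np.abs(bump(pts[:, 0], pts[:, 1]))
        assert residual.mean() < 1.0
        assert residual.mean() < initial.mean()
        assert report.nmi_after > report.nmi_before

    def test_pure_affine_disturbance_leaves_ffd_idle(self, soft_vessel,
                                                     vessel_mask):
        moved = np.roll(soft_vessel, (5, -3), axis=(0, 1))
        affine, _ = register_affine(soft_vessel, moved)
        composed, _ = register_ffd(soft_vessel, moved, affine)
        pts = np.argwhere(vessel_mask)[::9].astype(float)
        added = np.linalg.norm(transform_points(composed, pts)
                               - transform_points(affine, pts), axis=1)
        assert added.mean() < 1.0


class TestApplyTransform:
    def test_identity_unchanged(self, vessel_mask):
        out = apply_transform(vessel_mask, TransformModel.identity())
        np.testing.assert_array_equal(out, vessel_mask)

    def test_integer_translation_of_mask_is_exact_shift(self, vessel_mask):
        t = TransformModel(np.array([1.0, 0.0, 0.0, 1.0, 2.0, -4.0]))
        out = apply_transform(vessel_mask, t)
        # sampling at (x+2, y-4) shifts content by +4 rows, -2 cols
        c0 = np.argwhere(vessel_mask).mean(axis=0)
        c1 = np.argwhere(out).mean(axis=0)
        np.testing.assert_allclose(c1 - c0, [4.0, -2.0], atol=0.2)
        assert out.sum() == vessel_mask.sum()  # interior mask moved rigidly

    def test_affine_round_trip_keeps_mask(self, vessel_mask):
        ang = 0.05
        lin = np.array([[np.cos(ang), -np.sin(ang)],
                        [np.sin(ang), np.cos(ang)]])
        t = TransformModel(np.concatenate([lin.ravel(), [3.0, -2.0]]))
        inv_lin = np.linalg.inv(lin)
        inv_t = TransformModel(np.concatenate(
            [inv_lin.ravel(), -inv_lin @ np.array([3.0, -2.0])]))
        once = apply_transform(vessel_mask, t)
        back = apply_transform(once, inv_t)
        assert dice(back, vessel_mask) >= 0.99

    def test_rejects_singular_affine(self):
        with pytest.raises(ValueError):
            TransformModel(np.array([1.0, 0.0, 1.0, 0.0, 0.0, 0.0]))


class TestRegisterMasks:
    def test_registration_improves_alignment_across_pairs(self):
        """Median NMI gain over >= 20 seeded consecutive moving-phantom
        frame pairs is positive."""
        gains = []
        for seed in (21, 22):
            tree = generate_tree(seed=seed, generations=5, image_size=192)
            seq, truth = render_sequence(tree, 0.22, MotionModel(
                affine_amplitude=0.04, warp_amplitude_px=4.0), 26,
                noise_sd=0.0, seed=seed)
            k0 = truth.injection_start_frame + 1
            masks = truth.truth_masks
            for k in range(k0 + 1, min(k0 + 12, 26)):
                _, report, _ = register_masks(masks[k - 1], masks[k],
                                              RegistrationSettings.coarse())
                gains.append(report.nmi_after - report.nmi_before)
        assert len(gains) >= 20
        assert np.median(gains) > 0
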