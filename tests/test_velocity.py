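"""Skeleton-length measurement and the Mlength / Mslope estimators."""

import numpy as np
import pytest

from coroflow import (BranchModel, MaskSequence, MotionModel, branch_velocity,
                      estimate_mlength, estimate_mslope, generate_tree,
                      prebranch_velocity, render_sequence, skeleton_length_mm)
from coroflow.core import AreaSeries
from coroflow.timing import fit_area_polynomial, fit_timing


class TestSkeletonLength:
    def test_horizontal_bar(self):
        mask = np.zeros((20, 60), dtype=bool)
        mask[8:11, 5:55] = True            # 50 x 3 bar
        length = skeleton_length_mm(mask, 0.2)
        assert length == pytest.approx(49 * 0.2, abs=0.4)

    def test_diagonal_bar(self):
        mask = np.zeros((64, 64), dtype=bool)
        for i in range(50):
            mask[6 + i, 6 + i] = True
            mask[7 + i, 6 + i] = True
            mask[6 + i, 7 + i] = True
        length = skeleton_length_mm(mask, 0.2)
        assert length == pytest.approx(49 * np.sqrt(2) * 0.2, abs=0.4)

    def test_empty_mask(self):
        assert skeleton_length_mm(np.zeros((10, 10), dtype=bool), 0.2) == 0.0

    def test_spur_pruning_removes_boundary_twigs(self):
        mask = np.zeros((20, 60), dtype=bool)
        mask[8:11, 5:55] = True
        bumpy = mask.copy()
        bumpy[11, 20] = bumpy[7, 30] = bumpy[11, 40] = True  # boundary bumps
        assert skeleton_length_mm(bumpy, 0.2, prune_px=3) == pytest.approx(
            skeleton_length_mm(mask, 0.2, prune_px=3), abs=0.2)


class TestBranchModel:
    @pytest.mark.parametrize("v1,n1,n2,expected",
                             [(0.3, 1, 2, 0.15), (0.2, 2, 2, 0.2),
                              (0.1, 2, 4, 0.05)])
    def test_conservation_arithmetic(self, v1, n1, n2, expected):
        assert branch_velocity(v1, n1, n2) == pytest.approx(expected)

    def test_cascade_gives_quarter_speed(self):
        v = branch_velocity(branch_velocity(0.4, 1, 2), 2, 4)
        assert v == pytest.approx(0.1)

    @pytest.mark.parametrize("L1,L2,L3,t,expected",
                             [(10.0, 5.0, 5.0, 0.1, 0.2),
                              (12.0, 0.0, 0.0, 0.06, 0.2)])
    def test_prebranch_velocity(self, L1, L2, L3, t, expected):
        assert prebranch_velocity(L1, L2, L3, t) == pytest.approx(expected)

    def test_prebranch_two_printed_forms_agree(self):
        L1, L2, t = 9.0, 4.0, 0.08
        assert prebranch_velocity(L1, L2, L2, t) == pytest.approx(
            (L1 + 2 * L2) / 1000.0 / t)

    def test_model_consistency(self):
        m = BranchModel(n1=1, n2=2, v1=0.25, L1=30.0, L2=21.0, L3=21.0)
        assert m.v2 == pytest.approx(0.125)
        # traversing root + child at the slowed speed equals traversing
        # L1+L2+L3 at the pre-branch speed
        assert prebranch_velocity(m.L1, m.L2, m.L3, m.t_tot) == \
            pytest.approx(m.v1)


def _linear_growth_masks(n=24, px_per_frame=15, spacing=0.2):
    """A bar whose skeleton grows by px_per_frame pixels each frame."""
    masks = np.zeros((n, 64, 400), dtype=bool)
    for k in range(n):
        masks[k, 30:33, 5:5 + 10 + px_per_frame * k] = True
    return MaskSequence(masks)


def _window_fit(series_values, t_s, t_max):
    fit = fit_area_polynomial(
        AreaSeries(np.arange(len(series_values)), series_values), degree=3)
    fit.t_s, fit.t_max = t_s, t_max
    return fit


class TestMlength:
    def test_equation_arithmetic(self):
        """3 mm growth over a 10-frame window at 15 fps -> 0.0045 m/s."""
        masks = _linear_growth_masks(n=14, px_per_frame=1, spacing=0.2)
        # 1 px/frame * 0.2 mm/px = 0.2 mm/frame; choose window of 10 frames
        areas = masks.masks.reshape(14, -1).sum(1).astype(float)
        fit = _window_fit(areas, 2.0, 12.0)
        res = estimate_mlength(masks, fit, fps=15.0, pixel_spacing_mm=0.2)
        assert res.delta_L_T_mm == pytest.approx(2.0, abs=0.3)
        assert res.delta_T_s == pytest.approx(10 / 15)
        assert res.v_mlength_m_per_s == pytest.approx(
            res.delta_L_T_mm / 1000.0 / res.delta_T_s)

    def test_static_masks_give_zero_with_warning(self):
        masks = MaskSequence(np.repeat(
            _linear_growth_masks(n=2).masks[:1], 12, axis=0))
        areas = masks.masks.reshape(12, -1).sum(1).astype(float)
        fit = _window_fit(areas, 2.0, 9.0)
        with pytest.warns(UserWarning, match="no skeleton growth"):
            res = estimate_mlength(masks, fit, 15.0, 0.2)
        assert res.v_mlength_m_per_s == 0.0

    def test_rejects_short_window(self):
        masks = _linear_growth_masks(n=10)
        areas = masks.masks.reshape(10, -1).sum(1).astype(float)
        fit = _window_fit(areas, 3.0, 4.0)
        with pytest.raises(ValueError, match="window"):
            estimate_mlength(masks, fit, 15.0, 0.2)

    def test_increment_mode_matches_endpoint_on_monotone_growth(self):
        masks = _linear_growth_masks(n=20, px_per_frame=8)
        areas = masks.masks.reshape(20, -1).sum(1).astype(float)
        fit = _window_fit(areas, 2.0, 18.0)
        a = estimate_mlength(masks, fit, 15.0, 0.2, mode="endpoint")
        b = estimate_mlength(masks, fit, 15.0, 0.2, mode="increments")
        assert a.v_mlength_m_per_s == pytest.approx(b.v_mlength_m_per_s,
                                                    rel=0.05)


class TestMslope:
    def test_linear_polynomial(self):
        t = np.arange(30, dtype=float)
        fit = _window_fit(2.5 * t + 7.0, 5.0, 20.0)
        assert estimate_mslope(fit) == pytest.approx(2.5, abs=1e-6)

    def test_mean_value_of_quadratic(self):
        t = np.arange(20, dtype=float)
        fit = _window_fit(t ** 2, 0.0, 10.0)
        assert estimate_mslope(fit) == pytest.approx(10.0, abs=1e-6)


class TestPhantomOracles:
    def test_doubling_front_speed_doubles_mslope(self, still_phantom):
        """Paired renders of one tree at v and 2v: the area slope doubles."""
        tree, _, _ = still_phantom
        slopes = {}
        for v in (0.15, 0.30):
            seq, truth = render_sequence(tree, v, MotionModel.still(), 44,
                                         noise_sd=0.0, seed=31)
            counts = truth.truth_masks.reshape(44, -1).sum(1).astype(float)
            counts += truth.catheter_mask.sum()
            fit = fit_timing(AreaSeries(np.arange(44), counts))
            slopes[v] = estimate_mslope(fit)
        ratio = slopes[0.30] / slopes[0.15]
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_foreshortening_never_increases_velocity(self):
        """Projected skeleton growth shrinks monotonically as vessels tilt
        away from the projection plane."""
        tree = generate_tree(seed=17, generations=5, image_size=256)
        rates = []
        for f in (1.0, 0.8, 0.6):
            seq, truth = render_sequence(tree, 0.25, MotionModel.still(), 36,
                                         noise_sd=0.0, seed=17,
                                         foreshorten=f)
            k0 = truth.injection_start_frame + 2
            k1 = truth.full_propagation_frame - 1
            growth = (skeleton_length_mm(truth.truth_masks[k1], 0.2)
                      - skeleton_length_mm(truth.truth_masks[k0], 0.2))
            rates.append(growth / (k1 - k0))
        assert rates[0] >= rates[1] >= rates[2]

    def test_velocity_scale_consistent_across_resolution(self):
        """The same physical phantom sampled at 0.2 and 0.1 mm/px yields
        the same measured skeleton growth in mm."""
        lengths = {}
        for size, spacing in ((256, 0.2), (512, 0.1)):
            tree = generate_tree(seed=23, generations=3, image_size=size,
                                 pixel_spacing_mm=spacing)
            seq, truth = render_sequence(tree, 0.12, MotionModel.still(), 30,
                                         noise_sd=0.0, seed=23)
            k = truth.full_propagation_frame
            lengths[spacing] = skeleton_length_mm(truth.truth_masks[k],
                                                  spacing)
        assert lengths[0.1] == pytest.approx(lengths[0.2], rel=0.05)
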