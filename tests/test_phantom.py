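"""Phantom generator: geometry, kinematics, ground-truth invariants."""

import numpy as np
import pytest

from coroflow import MotionModel, generate_tree, read_truth, render_sequence, \
    write_truth
from coroflow.phantom import _fill_schedule


class TestGenerateTree:
    def test_single_generation_is_one_unbranched_segment(self):
        tree = generate_tree(seed=1, generations=1, image_size=256)
        assert len(tree.segments) == 1
        assert tree.segments[0].parent == -1
        expected = tree.segments[0].length_px * tree.pixel_spacing_mm
        assert tree.total_length_mm == pytest.approx(expected)

    def test_branch_count_doubles_each_generation(self):
        tree = generate_tree(seed=7, generations=3, image_size=512)
        assert tree.branch_counts() == [1, 2, 4]
        assert len(tree.segments) == 7

    def test_deterministic_for_fixed_seed(self):
        a = generate_tree(seed=9, generations=4, image_size=256)
        b = generate_tree(seed=9, generations=4, image_size=256)
        for sa, sb in zip(a.segments, b.segments):
            np.testing.assert_array_equal(sa.points, sb.points)

    def test_geometry_stays_inside_bounds(self):
        for seed in range(6):
            tree = generate_tree(seed=seed, generations=6, image_size=256)
            pts = np.vstack([s.points for s in tree.segments])
            assert pts.min() >= 0 and pts.max() <= 255

    def test_tree_connectivity(self):
        tree = generate_tree(seed=3, generations=4, image_size=256)
        for seg in tree.segments:
            if seg.parent >= 0:
                parent_end = tree.segments[seg.parent].points[-1]
                np.testing.assert_allclose(seg.points[0], parent_end)

    def test_rejects_tiny_image(self):
        with pytest.raises(ValueError):
            generate_tree(seed=1, generations=2, image_size=64)

    def test_rejects_zero_generations(self):
        with pytest.raises(ValueError):
            generate_tree(seed=1, generations=0, image_size=256)


class TestFillKinematics:
    def test_branch_speed_halves_per_generation(self):
        tree = generate_tree(seed=2, generations=4, image_size=256)
        _, speeds, _ = _fill_schedule(tree, speed_px_s=1000.0)
        for seg, sp in zip(tree.segments, speeds):
            assert sp == pytest.approx(1000.0 / 2 ** seg.generation)

    def test_children_start_when_parent_finishes(self):
        tree = generate_tree(seed=2, generations=3, image_size=256)
        start, speeds, _ = _fill_schedule(tree, speed_px_s=1000.0)
        for i, seg in enumerate(tree.segments):
            if seg.parent >= 0:
                p = seg.parent
                finish = start[p] + tree.segments[p].length_px / speeds[p]
                assert start[i] == pytest.approx(finish)


class TestRenderSequence:
    def test_truth_length_follows_constant_rate(self, still_phantom):
        """Conservation through doubling: summed covered length grows at
        exactly the injected speed until the tree is full."""
        tree, seq, truth = still_phantom
        v_px_per_frame = 0.25 * 1000 / seq.pixel_spacing_mm / seq.fps
        for k in range(seq.n_frames):
            tau = k - truth.injection_start_frame
            expected = np.clip(tau * v_px_per_frame, 0, None) \
                * seq.pixel_spacing_mm
            expected = min(expected, tree.total_length_mm)
            assert truth.truth_skeleton_length_mm[k] == pytest.approx(
                expected, abs=1e-6)

    def test_truth_monotone_across_seeds(self):
        for seed in range(20):
            tree = generate_tree(seed=seed, generations=4, image_size=192)
            _, truth = render_sequence(tree, 0.12, MotionModel.still(), 24,
                                       noise_sd=3.0, seed=seed)
            assert np.all(np.diff(truth.truth_skeleton_length_mm) >= -1e-9)
            assert truth.injection_start_frame < truth.full_propagation_frame

    def test_truth_saturates_at_total_length(self, still_phantom):
        tree, seq, truth = still_phantom
        at_full = truth.truth_skeleton_length_mm[truth.full_propagation_frame]
        assert abs(at_full - tree.total_length_mm) <= seq.pixel_spacing_mm

    def test_catheter_only_before_injection(self, still_phantom):
        _, seq, truth = still_phantom
        for k in range(truth.injection_start_frame + 1):
            assert not truth.truth_masks[k].any()

    def test_vessels_darker_than_background(self, still_phantom):
        _, seq, truth = still_phantom
        k = truth.full_propagation_frame
        dye = truth.truth_masks[k]
        assert seq.frames[k][dye].mean() < seq.frames[k][~dye].mean() - 40

    def test_eight_bit_range(self, moving_phantom):
        _, seq, _ = moving_phantom
        assert seq.frames.min() >= 0 and seq.frames.max() <= 255
        np.testing.assert_array_equal(seq.frames, np.round(seq.frames))

    def test_deterministic_render(self):
        tree = generate_tree(seed=4, generations=3, image_size=192)
        a, _ = render_sequence(tree, 0.1, MotionModel(), 22, noise_sd=4.0,
                               seed=5)
        b, _ = render_sequence(tree, 0.1, MotionModel(), 22, noise_sd=4.0,
                               seed=5)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_rejects_velocity_filling_in_under_three_frames(self):
        tree = generate_tree(seed=1, generations=2, image_size=192)
        with pytest.raises(ValueError, match="velocity too large"):
            render_sequence(tree, 5.0, MotionModel.still(), 20, seed=0)

    def test_rejects_sequence_shorter_than_propagation(self):
        tree = generate_tree(seed=1, generations=5, image_size=256)
        with pytest.raises(ValueError, match="too short"):
            render_sequence(tree, 0.05, MotionModel.still(), 12, seed=0)


class TestMotionModel:
    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            MotionModel(cardiac_frequency_hz=0.0)
        with pytest.raises(ValueError):
            MotionModel(warp_amplitude_px=-1.0)
        with pytest.raises(ValueError):
            MotionModel(warp_grid_spacing_px=2.0)

    def test_still_model_has_no_amplitude(self):
        m = MotionModel.still()
        assert m.affine_amplitude == m.warp_amplitude_px == 0.0

    def test_motion_moves_the_rendered_tree(self):
        tree = generate_tree(seed=6, generations=3, image_size=192)
        a, ta = render_sequence(tree, 0.1, MotionModel.still(), 20, seed=6)
        b, tb = render_sequence(tree, 0.1, MotionModel(), 20, seed=6)
        k = ta.full_propagation_frame
        assert (ta.truth_masks[k] != tb.truth_masks[k]).sum() > 50


class TestTruthIO:
    def test_round_trip(self, tmp_path, moving_phantom):
        _, _, truth = moving_phantom
        write_truth(truth, tmp_path)
        back = read_truth(tmp_path)
        np.testing.assert_array_equal(back.truth_masks, truth.truth_masks)
        np.testing.assert_array_equal(back.catheter_mask, truth.catheter_mask)
        np.testing.assert_allclose(back.truth_skeleton_length_mm,
                                   truth.truth_skeleton_length_mm)
        assert back.true_velocity_m_per_s == truth.true_velocity_m_per_s
        assert back.injection_start_frame == truth.injection_start_frame
        assert back.full_propagation_frame == truth.full_propagation_frame

    def test_empty_mask_frames_preserved(self, tmp_path, still_phantom):
        _, _, truth = still_phantom
        write_truth(truth, tmp_path)
        back = read_truth(tmp_path)
        assert not back.truth_masks[0].any()
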