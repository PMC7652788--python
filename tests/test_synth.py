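"""Synthetic generator: kinematics, rendering determinism, dataset/video."""

import json
import math

import numpy as np
import pytest

import ratpose as rp
from ratpose.errors import ConfigurationError, GenerationError
from ratpose.landmarks import LANDMARK_NAMES
from ratpose.synth import swing_bump, stride_x, TWO_PI


class TestGaitPose:
    def test_periodic_in_phase(self):
        a = rp.gait_pose(0.0)
        b = rp.gait_pose(TWO_PI)
        np.testing.assert_allclose(a.xy, b.xy, atol=1e-9)

    def test_deterministic(self):
        a = rp.gait_pose(1.234)
        b = rp.gait_pose(1.234)
        np.testing.assert_array_equal(a.xy, b.xy)

    def test_all_nine_landmarks_finite(self):
        lm = rp.gait_pose(0.7)
        assert lm.xy.shape == (9, 2)
        assert np.all(np.isfinite(lm.xy))

    def test_claw_tip_on_ground_for_stance_fraction(self):
        """The hind claw tip sits at ground level (y=0 in the body frame)
        for a contiguous stance fraction equal to the duty factor."""
        gait = rp.GaitConfig(duty_factor=0.6)
        phases = np.linspace(0, TWO_PI, 1000, endpoint=False)
        y = np.array(
            [rp.gait_pose(p, gait=gait)["back_claw_tip"][1] for p in phases]
        )
        on_ground = np.abs(y) < 1e-9
        assert on_ground.mean() == pytest.approx(0.6, abs=0.01)
        # contiguity: exactly one run boundary pair over the cycle
        transitions = np.sum(on_ground != np.roll(on_ground, 1))
        assert transitions == 2

    def test_ankle_height_matches_closed_form(self):
        """Back-claw-ankle height follows the half-sine swing bump of the
        generator's closed form (independently re-evaluated here)."""
        skel = rp.SkeletonConfig()
        gait = rp.GaitConfig()
        s = skel.body_scale
        off_y = skel.landmark_offsets["back_claw_ankle"][1]
        for phase in np.linspace(0.1, TWO_PI, 17):
            lm = rp.gait_pose(phase, skel, gait)
            frac = ((phase + gait.phase_offsets["hind"]) / TWO_PI + 0.04) % 1.0
            expected_y = off_y * s - 0.6 * gait.amplitude_px * s * swing_bump(
                frac, gait.duty_factor
            )
            assert lm["back_claw_ankle"][1] == pytest.approx(expected_y, abs=1e-9)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            rp.GaitConfig(period_frames=2)
        with pytest.raises(ConfigurationError):
            rp.GaitConfig(duty_factor=1.2)
        with pytest.raises(ConfigurationError):
            rp.SkeletonConfig(segment_lengths={"head": -1.0})
        with pytest.raises(ConfigurationError):
            rp.gait_pose(float("nan"))


class TestStrideProfiles:
    def test_stride_x_continuous_and_periodic(self):
        duty, S = 0.6, 30.0
        for f0, f1 in [(duty - 1e-9, duty + 1e-9), (1 - 1e-9, 1e-9)]:
            assert stride_x(f0, duty, S) == pytest.approx(
                stride_x(f1 % 1.0, duty, S), abs=1e-6
            )

    def test_bump_zero_in_stance_positive_in_swing(self):
        assert swing_bump(0.3, 0.6) == 0.0
        assert swing_bump(0.8, 0.6) > 0.0


class TestRenderFrame:
    def test_noiseless_render_bit_identical(self):
        scene = rp.SceneConfig(noise_sigma=0.0)
        lm = rp.gait_pose(0.5, origin=(96, 112))
        img1, _ = rp.render_frame(lm, scene)
        img2, _ = rp.render_frame(lm, scene)
        np.testing.assert_array_equal(img1, img2)

    def test_landmarks_inside_body_mask(self):
        """Each landmark pixel is covered by drawn body (differs from the
        noiseless background)."""
        scene = rp.SceneConfig(noise_sigma=0.0)
        lm = rp.gait_pose(2.0, origin=(96, 112))
        img, _ = rp.render_frame(lm, scene)
        base = rp.synth._background(scene, 112.0)
        for i, name in enumerate(LANDMARK_NAMES):
            x, y = int(round(lm.xy[i, 0])), int(round(lm.xy[i, 1]))
            x = np.clip(x, 0, scene.image_width - 1)
            y = np.clip(y, 0, scene.image_height - 1)
            assert not np.array_equal(img[y, x], base[y, x].astype(np.uint8)), name

    def test_noise_magnitude(self):
        """Monte-Carlo: mean |difference| between noisy and clean renders
        matches the folded-normal expectation E|N(0, s)| = s*sqrt(2/pi)."""
        lm = rp.gait_pose(1.0, origin=(96, 112))
        clean, _ = rp.render_frame(lm, rp.SceneConfig(noise_sigma=0.0))
        sigma = 10.0
        scene = rp.SceneConfig(noise_sigma=sigma)
        diffs = []
        for seed in range(100):
            noisy, _ = rp.render_frame(
                lm, scene, rng=np.random.default_rng(seed)
            )
            diffs.append(
                np.mean(np.abs(noisy.astype(float) - clean.astype(float)))
            )
        expected = sigma * math.sqrt(2 / math.pi)
        se = np.std(diffs) / math.sqrt(len(diffs))
        # clipping at 0/255 and rounding shrink the mean slightly; 3 sigma band
        assert abs(np.mean(diffs) - expected) < max(3 * se, 0.25)

    def test_scene_too_small_for_skeleton(self):
        scene = rp.SceneConfig(image_width=64, image_height=64)
        lm = rp.gait_pose(0.0, origin=(32, 60))
        with pytest.raises(GenerationError):
            rp.render_frame(lm, scene)


class TestGenerateDataset:
    def test_counts_and_files(self, tmp_path):
        ds = rp.generate_dataset(10, str(tmp_path / "d"), seed=4)
        assert len(ds) == 10
        pngs = sorted((tmp_path / "d").glob("*.png"))
        assert len(pngs) == 10
        assert (tmp_path / "d" / "annotations.json").exists()

    def test_seed_determinism_byte_identical(self, tmp_path):
        rp.generate_dataset(6, str(tmp_path / "a"), seed=9)
        rp.generate_dataset(6, str(tmp_path / "b"), seed=9)
        a = (tmp_path / "a" / "annotations.json").read_text()
        b = (tmp_path / "b" / "annotations.json").read_text()
        assert a == b
        ia = (tmp_path / "a" / "img_00003.png").read_bytes()
        ib = (tmp_path / "b" / "img_00003.png").read_bytes()
        assert ia == ib

    def test_nose_eye_distance_positive_everywhere(self, tiny_dataset):
        for rec in tiny_dataset.records:
            assert rec.landmarks.nose_eye_distance() > 0

    def test_ground_truth_written(self, tmp_path):
        rp.generate_dataset(3, str(tmp_path / "d"), seed=1)
        gt = json.loads((tmp_path / "d" / "ground_truth.json").read_text())
        assert len(gt["frames"]) == 3
        assert gt["gait"]["period_frames"] == 24


class TestGenerateVideo:
    def test_phase_advance_and_maxima_count(self, tmp_path):
        gait = rp.GaitConfig(period_frames=20)
        frames, traj = rp.generate_video(60, None, gait=gait, seed=0)
        assert len(frames) == 60 and len(traj) == 60
        h = rp.height_series(traj, "back_claw_ankle")
        # 3 full cycles -> exactly 3 swing maxima
        peaks = [
            t
            for t in range(1, 59)
            if h[t] > h[t - 1] and h[t] >= h[t + 1] and h[t] > h.min() + 2
        ]
        assert len(peaks) == 3

    def test_nose_horizontal_speed(self):
        gait = rp.GaitConfig(forward_speed_px_per_frame=0.0)
        _, traj = rp.generate_video(24, None, gait=gait, seed=0)
        x = traj.coords("nose_tip")[:, 0]
        np.testing.assert_allclose(np.diff(x), 0.0, atol=1e-9)

    def test_trajectory_equals_recomputed_poses(self):
        """Exported per-frame landmarks equal an independent re-evaluation
        of the pose model at each frame's phase."""
        skel = rp.SkeletonConfig()
        gait = rp.GaitConfig()
        scene = rp.SceneConfig(noise_sigma=0.0)
        _, traj = rp.generate_video(
            gait.period_frames, None, skel, gait, scene, seed=0
        )
        from ratpose.synth import _scene_anchor

        ax, gy = _scene_anchor(scene)
        for t in range(len(traj)):
            expected = rp.gait_pose(
                TWO_PI * t / gait.period_frames, skel, gait, origin=(ax, gy)
            )
            np.testing.assert_allclose(
                traj.landmark_sets[t].xy, expected.xy, atol=1e-9
            )

    def test_hind_limb_height_periodicity_by_autocorrelation(self):
        gait = rp.GaitConfig(period_frames=24)
        _, traj = rp.generate_video(24 * 4, None, gait=gait, seed=0)
        for joint in ("back_claw_ankle", "back_claw_palm", "back_claw_tip"):
            h = rp.height_series(traj, joint)
            x = h - h.mean()
            ac = np.correlate(x, x, "full")[len(x) - 1 :]
            lag = 1
            while lag < len(ac) - 1 and not (
                ac[lag] >= ac[lag - 1] and ac[lag] >= ac[lag + 1] and ac[lag] > 0
            ):
                lag += 1
            assert lag == 24, joint

    def test_too_few_frames_rejected(self):
        with pytest.raises(ConfigurationError):
            rp.generate_video(10, None, gait=rp.GaitConfig(period_frames=24))
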