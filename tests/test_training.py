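"""Losses, augmentation, resizing, and the training driver on a very small
synthetic problem."""

import math

import numpy as np
import pytest

import ratpose as rp
from ratpose.errors import ConfigurationError, TrainingError
from ratpose.models import hir_coordinates
from ratpose.training import _coord_stage_loss

from conftest import small_model_config


class TestSmoothL1:
    @pytest.mark.parametrize(
        "x,expected",
        [(0.0, 0.0), (0.5, 0.125), (1.0, 0.5), (-1.0, 0.5), (2.0, 1.5), (-3.0, 2.5)],
    )
    def test_branch_values(self, x, expected):
        assert rp.smooth_l1(x) == pytest.approx(expected)

    def test_continuity_at_branch_point(self):
        eps = 1e-8
        assert abs(rp.smooth_l1(1 - eps) - rp.smooth_l1(1 + eps)) < 1e-7

    def test_nonnegative_elementwise(self, rng):
        x = rng.normal(0, 3, size=100)
        assert np.all(rp.smooth_l1(x) >= 0)


class TestHeatmapMse:
    def test_identity_is_zero(self, rng):
        m = rng.random((9, 4, 8))
        a = rp.HeatmapStack(m, 8, (32, 64))
        assert rp.heatmap_mse(a, a) == 0.0

    def test_constant_offset(self, rng):
        m = rng.random((9, 4, 8))
        a = rp.HeatmapStack(m, 8, (32, 64))
        b = rp.HeatmapStack(m + 0.1, 8, (32, 64))
        assert rp.heatmap_mse(a, b) == pytest.approx(0.01)

    def test_matches_two_loop_oracle(self, rng):
        pa = rng.normal(size=(9, 3, 5))
        pb = rng.normal(size=(9, 3, 5))
        total = 0.0
        for k in range(9):
            for r in range(3):
                for c in range(5):
                    total += (pa[k, r, c] - pb[k, r, c]) ** 2
        expected = total / (9 * 3 * 5)
        a = rp.HeatmapStack(pa, 4, (12, 20))
        b = rp.HeatmapStack(pb, 4, (12, 20))
        assert rp.heatmap_mse(a, b) == pytest.approx(expected)

    def test_shape_mismatch_rejected(self, rng):
        a = rp.HeatmapStack(rng.random((9, 4, 8)), 8, (32, 64))
        b = rp.HeatmapStack(rng.random((9, 8, 4)), 8, (64, 32))
        with pytest.raises(ConfigurationError):
            rp.heatmap_mse(a, b)


class TestMultiStageLoss:
    def _preds(self, cfg, n=2, seed=0):
        model = rp.build_model(cfg)
        x = np.random.default_rng(seed).random((n, 3, *cfg.input_size)).astype(
            np.float32
        )
        return model.forward(x)

    def test_zero_at_truth_hir(self, small_config):
        preds = self._preds(small_config)
        target = hir_coordinates(preds.final, small_config.stride).data
        # every stage gets the (identical) decoded target of its own output
        per_stage = [
            float(
                _coord_stage_loss(
                    hir_coordinates(o, small_config.stride),
                    hir_coordinates(o, small_config.stride).data,
                    np.ones((2, 9), bool),
                ).data
            )
            for o in preds.outputs
        ]
        assert all(v == 0 for v in per_stage)

    def test_additivity_over_stages(self, small_config, rng):
        preds = self._preds(small_config)
        target = rng.uniform(10, 50, size=(2, 9, 2)).astype(np.float32)
        total = float(rp.multi_stage_loss(preds, target, "HIR").data)
        per_stage = sum(
            float(
                _coord_stage_loss(
                    hir_coordinates(o, small_config.stride),
                    target,
                    np.ones((2, 9), bool),
                ).data
            )
            for o in preds.outputs
        )
        assert total == pytest.approx(per_stage, rel=1e-6)

    def test_hmp_zero_at_truth(self, small_config):
        cfg = small_model_config(decoder="HMP")
        preds = self._preds(cfg)
        target = preds.final.data.copy()
        # identical stages: loss = stages * single-stage MSE; with target =
        # final stage output the final term is exactly zero
        loss = rp.multi_stage_loss(preds, np.stack([target[i] for i in range(2)]), "HMP")
        assert float(loss.data) >= 0

    def test_kind_target_mismatch_rejected(self, small_config, rng):
        preds = self._preds(small_config)
        with pytest.raises(ConfigurationError):
            rp.multi_stage_loss(preds, rng.random((2, 9, 4, 4)), "HIR")

    def test_all_stages_receive_gradient(self, small_config, rng):
        """Intermediate supervision: every stage head's weights get a
        nonzero gradient from the summed loss."""
        model = rp.build_model(small_config)
        x = rng.random((1, 3, 64, 128)).astype(np.float32)
        preds = model.forward(x)
        target = rng.uniform(10, 50, size=(1, 9, 2)).astype(np.float32)
        loss = rp.multi_stage_loss(preds, target, "HIR")
        model.zero_grad()
        loss.backward()
        for s, stage in enumerate(model.stage_modules):
            g = stage.head.weight.grad
            assert g is not None and np.abs(g).max() > 0, f"stage {s}"


class TestHsv:
    def test_zero_ranges_identity(self, rng):
        img = rng.integers(0, 255, size=(16, 16, 3), dtype=np.uint8)
        out = rp.hsv_jitter(img, (0, 0, 0), rng)
        assert np.array_equal(out, img)

    def test_small_roundtrip_error(self, rng):
        img = rng.integers(30, 220, size=(16, 16, 3), dtype=np.uint8)
        out = rp.hsv_shift(img, 0.0, 0.0, 0.0)
        assert np.abs(out.astype(int) - img.astype(int)).max() <= 1

    def test_value_jitter_keeps_gray_gray(self):
        img = np.full((8, 8, 3), 120, dtype=np.uint8)
        out = rp.hsv_shift(img, 0.0, 0.0, 0.2)
        assert np.all(out[..., 0] == out[..., 1])
        assert np.all(out[..., 1] == out[..., 2])

    def test_hue_rotation_red_to_green(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[..., 0] = 255
        out = rp.hsv_shift(img, 1.0 / 3.0, 0.0, 0.0)  # +120 degrees
        assert np.all(out[..., 1] == 255)
        assert np.all(out[..., 0] == 0) and np.all(out[..., 2] == 0)


class TestResize:
    def _lm(self):
        xy = np.column_stack([np.linspace(10, 100, 9), np.linspace(8, 60, 9)])
        return rp.LandmarkSet(xy)

    def test_identity_when_already_sized(self, rng):
        img = rng.integers(0, 255, (64, 128, 3), dtype=np.uint8)
        out, lm = rp.resize_for_input(img, self._lm(), (64, 128))
        assert out is img or np.array_equal(out, img)
        np.testing.assert_array_equal(lm.xy, self._lm().xy)

    def test_halving_width_halves_x(self, rng):
        img = rng.integers(0, 255, (64, 128, 3), dtype=np.uint8)
        _, lm = rp.resize_for_input(img, self._lm(), (64, 64))
        np.testing.assert_allclose(lm.xy[:, 0], self._lm().xy[:, 0] / 2)
        np.testing.assert_allclose(lm.xy[:, 1], self._lm().xy[:, 1])

    def test_full_scale_to_network_scale_factors(self):
        """1056x720 acquisition frames map to a 512x256 network input with
        per-axis factors 512/1056 and 256/720."""
        img = np.zeros((720, 1056, 3), dtype=np.uint8)
        xy = np.tile([528.0, 360.0], (9, 1))
        _, lm = rp.resize_for_input(img, rp.LandmarkSet(xy), (256, 512))
        np.testing.assert_allclose(lm.xy[0], [528 * 512 / 1056, 360 * 256 / 720])

    def test_empty_target_rejected(self, rng):
        img = rng.integers(0, 255, (8, 8, 3), dtype=np.uint8)
        with pytest.raises(ConfigurationError):
            rp.resize_for_input(img, None, (0, 8))


@pytest.fixture(scope="module")
def mini_sets(tmp_path_factory):
    out = tmp_path_factory.mktemp("mini")
    scene = rp.SceneConfig(noise_sigma=1.0)
    ds = rp.generate_dataset(16, str(out), scene=scene, seed=21)
    return rp.split_dataset(ds, 0.75, seed=21)


class TestTrainDriver:
    def _cfg(self, **kw):
        base = dict(epochs=2, batch_size=4, eval_every_epochs=2, seed=3,
                    hsv_ranges=(0.02, 0.1, 0.1))
        base.update(kw)
        return rp.TrainConfig(**base)

    def test_history_has_expected_eval_points(self, mini_sets):
        tr, te = mini_sets
        model = rp.build_model(small_model_config(init_seed=1))
        _, hist = rp.train(model, tr, te, self._cfg())
        assert hist.eval_epochs == [2]
        assert len(hist.stage_reports[0]) == 4  # one report per stage
        assert len(hist.epoch_losses) == 2

    def test_seed_determinism(self, mini_sets):
        tr, te = mini_sets
        losses = []
        for _ in range(2):
            model = rp.build_model(small_model_config(init_seed=1))
            _, hist = rp.train(model, tr, te, self._cfg())
            losses.append(hist.epoch_losses[-1])
        assert losses[0] == losses[1]

    def test_overlapping_splits_rejected(self, mini_sets):
        tr, _ = mini_sets
        model = rp.build_model(small_model_config())
        with pytest.raises(TrainingError):
            rp.train(model, tr, tr, self._cfg())

    def test_loss_decreases_on_tiny_problem(self, mini_sets):
        tr, te = mini_sets
        model = rp.build_model(small_model_config(init_seed=2))
        _, hist = rp.train(model, tr, te, self._cfg(epochs=4))
        assert hist.epoch_losses[-1] < hist.epoch_losses[0]

    @pytest.mark.parametrize(
        "structure,decoder",
        [("CCN", "HMP"), ("CCN", "FCR"), ("CHN", "HIR"), ("CHN", "HMP")],
    )
    def test_all_structure_decoder_pairs_train(self, mini_sets, structure, decoder):
        """One epoch of every structure/decoder combination runs end to end
        and produces finite losses and a per-stage report."""
        tr, te = mini_sets
        model = rp.build_model(
            small_model_config(structure=structure, decoder=decoder, init_seed=4)
        )
        _, hist = rp.train(model, tr, te, self._cfg(epochs=1, eval_every_epochs=1))
        assert np.isfinite(hist.epoch_losses[0])
        assert len(hist.stage_reports[0]) == model.cfg.stages

    def test_history_csv_written(self, mini_sets, tmp_path):
        tr, te = mini_sets
        model = rp.build_model(small_model_config(init_seed=1))
        _, hist = rp.train(model, tr, te, self._cfg())
        path = tmp_path / "hist.csv"
        rp.write_history(hist, str(path))
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns[:2]) == ["epoch", "stage"]
        assert len(df) == 4  # 1 eval point x 4 stages
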