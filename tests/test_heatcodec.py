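"""Gaussian encoding and HMP / HIR decoding, checked against independent
oracles (direct kernel evaluation, dense upsample + exhaustive argmax)."""

import math

import numpy as np
import pytest

import ratpose as rp
from ratpose.errors import ConfigurationError, DecodeError, EncodeError
from ratpose.heatcodec import _keys_kernel
from ratpose.landmarks import LandmarkSet


def _single_landmark(x, y):
    xy = np.tile([x, y], (9, 1))
    return LandmarkSet(xy)


#: logit scale for round-trip checks: large enough that the softmax mass is
#: dominated by the bump, small enough that it spans several grid cells
SHARP = rp.GaussianLabelConfig(amplitude=12.0)


class TestEncodeGaussian:
    def test_peak_value_is_amplitude_at_aligned_center(self):
        lm = _single_landmark(80.0, 56.0)  # /8 -> exactly on grid (10, 7)
        stack = rp.encode_gaussian(lm, 8, (128, 256))
        assert stack.values[0, 7, 10] == pytest.approx(1.0)

    def test_three_sigma_offset_value(self):
        """Value 3 cells from the centre along x: exp(-9/6) with the bump
        widths applied as printed variances (2*sigma in the denominator)."""
        lm = _single_landmark(80.0, 56.0)
        stack = rp.encode_gaussian(lm, 8, (128, 256))
        assert stack.values[0, 7, 13] == pytest.approx(math.exp(-9 / 6), abs=1e-12)
        assert stack.values[0, 7, 13] == pytest.approx(0.2231, abs=1e-4)

    def test_matches_direct_kernel_evaluation(self):
        """Whole map equals a two-loop evaluation of the label formula."""
        lm = _single_landmark(37.3, 52.9)
        cfg = rp.GaussianLabelConfig(amplitude=2.0, sigma_x=4.0, sigma_y=2.0)
        stack = rp.encode_gaussian(lm, 8, (128, 256), cfg)
        xc, yc = 37.3 / 8, 52.9 / 8
        for r in range(stack.values.shape[1]):
            for c in range(stack.values.shape[2]):
                expected = 2.0 * math.exp(
                    -((c - xc) ** 2 / (2 * 4.0) + (r - yc) ** 2 / (2 * 2.0))
                )
                assert stack.values[0, r, c] == pytest.approx(expected, rel=1e-12)

    def test_invisible_landmark_gives_zero_channel(self):
        lm = _single_landmark(80.0, 56.0)
        lm.visible[2] = False
        stack = rp.encode_gaussian(lm, 8, (128, 256))
        assert np.all(stack.values[2] == 0)
        assert np.any(stack.values[0] > 0)

    def test_off_grid_center_rejected(self):
        with pytest.raises(EncodeError):
            rp.encode_gaussian(_single_landmark(-5.0, 10.0), 8, (128, 256))

    def test_stack_shape_invariants(self):
        with pytest.raises(ConfigurationError):
            rp.HeatmapStack(np.zeros((9, 16, 30)), 8, (128, 256))
        with pytest.raises(ConfigurationError):
            rp.HeatmapStack(np.zeros((9, 16, 32)), 8, (130, 256))


class TestSoftArgmax1d:
    def test_uniform_gives_mean_index(self):
        assert rp.soft_argmax_1d(np.zeros(5)) == pytest.approx(2.0)

    def test_saturated_peak(self):
        assert rp.soft_argmax_1d(np.array([0.0, 50.0, 0.0])) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_hand_evaluated_weights(self):
        # softmax(0, ln3, 0) = (1, 3, 1)/5 -> index 1.0
        assert rp.soft_argmax_1d(np.array([0.0, math.log(3), 0.0])) == pytest.approx(
            1.0, abs=1e-12
        )
        # softmax(ln2, 0, 0) = (2, 1, 1)/4 -> (0*2 + 1 + 2)/4 = 0.75
        assert rp.soft_argmax_1d(np.array([math.log(2), 0.0, 0.0])) == pytest.approx(
            0.75, abs=1e-12
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rp.soft_argmax_1d(np.array([]))

    def test_stable_under_large_offsets(self):
        z = np.array([1000.0, 1000.0 + math.log(3), 1000.0])
        assert rp.soft_argmax_1d(z) == pytest.approx(1.0, abs=1e-9)


class TestDecodeHmp:
    def test_identity_stride_exact(self):
        maps = np.zeros((9, 16, 32))
        maps[:, 11, 5] = 1.0
        lm = rp.decode_hmp(rp.HeatmapStack(maps, 1, (16, 32)))
        assert np.all(lm.xy == (5, 11))

    def test_constant_channel_tie_breaks_to_origin(self):
        maps = np.ones((9, 8, 16))
        lm = rp.decode_hmp(rp.HeatmapStack(maps, 8, (64, 128)))
        assert np.all(lm.xy == 0)

    def test_gaussian_recovered_within_one_pixel(self):
        lm = _single_landmark(80.0, 56.0)  # stride-aligned interior point
        stack = rp.encode_gaussian(lm, 8, (128, 256))
        dec = rp.decode_hmp(stack)
        assert np.abs(dec.xy - lm.xy).max() <= 1.0

    def test_matches_bruteforce_oracle_on_random_stacks(self, rng):
        """Optimised separable upsampling + argmax equals a dense per-pixel
        evaluation of the Catmull-Rom kernel followed by an exhaustive scan."""
        for _ in range(10):
            h_map, w_map = int(rng.integers(3, 7)), int(rng.integers(3, 7))
            stride = int(rng.choice([2, 4]))
            maps = rng.normal(size=(9, h_map, w_map))
            stack = rp.HeatmapStack(maps, stride, (h_map * stride, w_map * stride))
            dec = rp.decode_hmp(stack)
            for k in range(9):
                best, best_val = None, -np.inf
                for py in range(h_map * stride):
                    for px in range(w_map * stride):
                        v = _bicubic_point(maps[k], px / stride, py / stride)
                        if v > best_val + 1e-12:
                            best_val, best = v, (px, py)
                assert tuple(dec.xy[k]) == best

    def test_all_nan_channel_rejected(self):
        maps = np.zeros((9, 4, 4))
        stack = rp.HeatmapStack(maps, 2, (8, 8))
        stack.values[3] = np.nan  # bypass constructor finiteness check
        with pytest.raises(DecodeError):
            rp.decode_hmp(stack)


def _bicubic_point(ch, sx, sy, a=-0.5):
    """Oracle: direct Catmull-Rom interpolation at one continuous point."""
    h, w = ch.shape
    bx, by = math.floor(sx), math.floor(sy)
    val = 0.0
    for ti in (-1, 0, 1, 2):
        for tj in (-1, 0, 1, 2):
            r = min(max(by + ti, 0), h - 1)
            c = min(max(bx + tj, 0), w - 1)
            wy = _keys_kernel(np.array([sy - (by + ti)]), a)[0]
            wx = _keys_kernel(np.array([sx - (bx + tj)]), a)[0]
            val += ch[r, c] * wy * wx
    return val


class TestBicubicUpsample:
    def test_equals_pointwise_oracle(self, rng):
        ch = rng.normal(size=(5, 6))
        up = rp.bicubic_upsample(ch, 4)
        assert up.shape == (20, 24)
        for py in range(0, 20, 3):
            for px in range(0, 24, 5):
                assert up[py, px] == pytest.approx(
                    _bicubic_point(ch, px / 4, py / 4), abs=1e-12
                )

    def test_reproduces_grid_samples(self, rng):
        ch = rng.normal(size=(4, 5))
        up = rp.bicubic_upsample(ch, 8)
        np.testing.assert_allclose(up[::8, ::8], ch, atol=1e-12)


class TestDecodeHir:
    def test_uniform_channel_decodes_to_grid_centroid(self):
        maps = np.zeros((9, 8, 4))
        lm = rp.decode_hir(rp.HeatmapStack(maps, 8, (64, 32)))
        assert np.all(lm.xy[:, 0] == pytest.approx(1.5 * 8))
        assert np.all(lm.xy[:, 1] == pytest.approx(3.5 * 8))

    def test_dominant_cell_decodes_to_cell_coordinates(self):
        maps = np.full((9, 8, 16), -1000.0)
        maps[:, 5, 11] = 0.0
        lm = rp.decode_hir(rp.HeatmapStack(maps, 8, (64, 128)))
        assert np.all(lm.xy[:, 0] == pytest.approx(11 * 8, abs=1e-9))
        assert np.all(lm.xy[:, 1] == pytest.approx(5 * 8, abs=1e-9))

    def test_round_trip_within_half_pixel_interior(self, rng):
        """Sharp Gaussian logits encode/decode to within 0.5 input px for
        landmarks at least 3 sigma from every border."""
        for _ in range(25):
            x = float(rng.uniform(48, 208))
            y = float(rng.uniform(48, 80))
            lm = _single_landmark(x, y)
            stack = rp.encode_gaussian(lm, 8, (128, 256), SHARP)
            dec = rp.decode_hir(stack)
            assert np.abs(dec.xy - lm.xy).max() < 0.5

    def test_softmax_marginals_normalised(self, rng):
        maps = rng.normal(size=(9, 6, 8))
        stack = rp.HeatmapStack(maps, 4, (24, 32))
        for k in range(9):
            p = rp.heatcodec.stable_softmax(maps[k])
            assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_translation_consistency(self):
        """Shifting the encoded centre by one map cell shifts the decoded
        coordinate by one stride within 0.5 px (interior centres)."""
        stride = 8
        base = _single_landmark(96.0, 64.0)
        a = rp.decode_hir(rp.encode_gaussian(base, stride, (128, 256), SHARP))
        shifted = _single_landmark(96.0 + stride, 64.0)
        b = rp.decode_hir(rp.encode_gaussian(shifted, stride, (128, 256), SHARP))
        assert b.xy[0, 0] - a.xy[0, 0] == pytest.approx(stride, abs=0.5)

    def test_gradient_matches_numerical(self, rng):
        """Analytic gradient of the differentiable decode agrees with
        central finite differences to 1e-4 relative error."""
        from ratpose.autodiff import Tensor
        from ratpose.models import hir_coordinates

        maps = rng.normal(size=(1, 9, 5, 7))
        t = Tensor(maps.copy(), requires_grad=True)
        coords = hir_coordinates(t, 4)
        w = rng.normal(size=(1, 9, 2))  # random projection to a scalar
        (coords * w).sum().backward()
        analytic = t.grad
        eps = 1e-6
        for _ in range(30):
            idx = (
                0,
                int(rng.integers(9)),
                int(rng.integers(5)),
                int(rng.integers(7)),
            )
            mp, mm = maps.copy(), maps.copy()
            mp[idx] += eps
            mm[idx] -= eps
            fp = float((hir_coordinates(Tensor(mp), 4) * w).sum().data)
            fm = float((hir_coordinates(Tensor(mm), 4) * w).sum().data)
            num = (fp - fm) / (2 * eps)
            denom = max(abs(num), abs(analytic[idx]), 1e-8)
            assert abs(analytic[idx] - num) / denom < 1e-4
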