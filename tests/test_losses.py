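"""Loss stack: SSIM oracle, warp exactness, consistency/smoothness closed forms."""

import numpy as np
import pytest

from endo3d.autodiff import Tensor
from endo3d.losses import (LossWeights, auto_mask, bilinear_sample, combine_terms,
                           disparity_search_oracle, edge_smoothness,
                           lr_consistency, min_reprojection, photometric_error,
                           ssim_map, stereo_loss, total_loss)
from endo3d.synthetic import (DisparitySpec, TextureSpec,
                              generate_disparity_field, generate_tissue_texture,
                              render_right_view)


def brute_force_ssim(x, y, window=3, L=1.0):
    """Independent sliding-window SSIM: explicit l*c*s product with
    c3 = c2/2, reflect-padded windows, biased moments."""
    c1, c2 = (0.01 * L) ** 2, (0.03 * L) ** 2
    c3 = c2 / 2
    p = window // 2
    out = np.zeros_like(x, dtype=np.float64)
    xp = np.pad(x.astype(np.float64), [(p, p), (p, p), (0, 0)], mode="reflect")
    yp = np.pad(y.astype(np.float64), [(p, p), (p, p), (0, 0)], mode="reflect")
    H, W, C = x.shape
    for i in range(H):
        for j in range(W):
            for c in range(C):
                wx = xp[i:i + window, j:j + window, c]
                wy = yp[i:i + window, j:j + window, c]
                mx, my = wx.mean(), wy.mean()
                vx, vy = wx.var(), wy.var()
                sx, sy = np.sqrt(vx), np.sqrt(vy)
                cov = ((wx - mx) * (wy - my)).mean()
                lum = (2 * mx * my + c1) / (mx ** 2 + my ** 2 + c1)
                con = (2 * sx * sy + c2) / (vx + vy + c2)
                stru = (cov + c3) / (sx * sy + c3)
                out[i, j, c] = lum * con * stru
    return out


class TestSSIM:
    def test_identical_images_score_one(self, texture_64x128):
        np.testing.assert_allclose(ssim_map(texture_64x128, texture_64x128), 1.0,
                                   atol=1e-6)

    def test_constant_images_closed_form(self):
        a, b = 0.2, 0.4
        x = np.full((16, 16, 3), a, np.float32)
        y = np.full((16, 16, 3), b, np.float32)
        c1 = 0.01 ** 2
        expect = (2 * a * b + c1) / (a ** 2 + b ** 2 + c1)
        np.testing.assert_allclose(ssim_map(x, y), expect, atol=1e-5)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(3):
            x = rng.random((12, 14, 3)).astype(np.float32)
            y = np.clip(x + 0.2 * rng.normal(size=x.shape), 0, 1).astype(np.float32)
            np.testing.assert_allclose(ssim_map(x, y), brute_force_ssim(x, y),
                                       atol=1e-5)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            ssim_map(np.zeros((2, 2, 3)), np.zeros((2, 2, 3)), window=5)


class TestWarp:
    def test_zero_disparity_identity(self, texture_64x128):
        d = np.zeros((64, 128), np.float32)
        for direction in ("right_to_left", "left_to_right"):
            out = bilinear_sample(texture_64x128, d, direction)
            np.testing.assert_array_equal(out, texture_64x128)

    def test_integer_shift_exact_on_interior(self, texture_64x128):
        d = np.full((64, 128), 3.0, np.float32)
        out = bilinear_sample(texture_64x128, d, "left_to_right")
        np.testing.assert_allclose(out[:, :-3], texture_64x128[:, 3:], atol=1e-6)
        out2 = bilinear_sample(texture_64x128, d, "right_to_left")
        np.testing.assert_allclose(out2[:, 3:], texture_64x128[:, :-3], atol=1e-6)

    def test_gradient_wrt_disparity_matches_finite_differences(self, texture_64x128):
        src = Tensor(texture_64x128.transpose(2, 0, 1)[None])
        d0 = 2.7
        d = Tensor(np.full((1, 1, 64, 128), d0, np.float32), requires_grad=True)
        out = bilinear_sample(src, d, "right_to_left")
        (out * out).sum().backward()
        assert np.abs(d.grad).max() > 0

        def val(v):
            dd = Tensor(np.full((1, 1, 64, 128), v, np.float32))
            o = bilinear_sample(src, dd, "right_to_left")
            return float((o * o).sum().data)

        fd = (val(d0 + 1e-2) - val(d0 - 1e-2)) / 2e-2
        assert fd == pytest.approx(float(d.grad.sum()), rel=0.05)

    def test_shape_mismatch_rejected(self, texture_64x128):
        with pytest.raises(ValueError):
            bilinear_sample(texture_64x128, np.zeros((10, 10), np.float32))


class TestPhotometric:
    def test_identical_images_zero_error(self, texture_64x128):
        pe = photometric_error(texture_64x128, texture_64x128)
        np.testing.assert_allclose(pe, 0.0, atol=1e-6)

    def test_alpha_zero_reduces_to_l1(self, texture_64x128):
        other = np.clip(texture_64x128 + 0.1, 0, 1)
        pe = photometric_error(texture_64x128, other, LossWeights(alpha=0.0))
        l1 = np.abs(texture_64x128 - other).mean(axis=-1)
        np.testing.assert_allclose(pe, l1, atol=1e-6)

    def test_constant_images_closed_form(self):
        a, b, alpha = 0.2, 0.4, 0.85
        x = np.full((16, 16, 3), a, np.float32)
        y = np.full((16, 16, 3), b, np.float32)
        c1 = 1e-4
        ssim = (2 * a * b + c1) / (a ** 2 + b ** 2 + c1)
        expect = alpha / 2 * (1 - ssim) + (1 - alpha) * abs(a - b)
        np.testing.assert_allclose(photometric_error(x, y), expect, atol=1e-5)


class TestMinReprojectionAndMask:
    def test_single_map_unchanged(self):
        m = np.random.default_rng(0).random((8, 8)).astype(np.float32)
        np.testing.assert_array_equal(min_reprojection([m]), m)

    def test_zero_map_wins(self):
        m = np.random.default_rng(0).random((8, 8)).astype(np.float32)
        np.testing.assert_allclose(min_reprojection([m, np.zeros_like(m)]), 0.0)

    def test_elementwise_min_oracle(self):
        rng = np.random.default_rng(1)
        maps = [rng.random((6, 7)).astype(np.float32) for _ in range(4)]
        np.testing.assert_array_equal(min_reprojection(maps),
                                      np.minimum.reduce(maps))

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            min_reprojection([])

    def test_static_pair_fully_masked(self, texture_64x128):
        warped = np.clip(texture_64x128 + 0.05, 0, 1)
        mu = auto_mask(texture_64x128, [texture_64x128], [warped])
        assert mu.sum() == 0  # unwarped error is exactly 0: strict < fails

    def test_perfect_warp_fully_kept(self, texture_64x128):
        source = np.clip(texture_64x128 + 0.1, 0, 1)
        mu = auto_mask(texture_64x128, [source], [texture_64x128.copy()])
        assert mu.min() == 1

    def test_mask_is_binary(self, small_pair):
        left, right, d = small_pair
        warped = bilinear_sample(right, d, "right_to_left")
        mu = auto_mask(left, [right], [warped])
        assert set(np.unique(mu)).issubset({0.0, 1.0})


class TestConsistencyAndSmoothness:
    def test_zero_fields_zero_loss(self):
        z = np.zeros((16, 32), np.float32)
        assert lr_consistency(z, z) == 0.0

    def test_equal_constants_zero_loss(self):
        c = np.full((16, 32), 5.0, np.float32)
        assert lr_consistency(c, c) == pytest.approx(0.0, abs=1e-6)

    def test_constant_gap_is_absolute_difference(self):
        dl = np.full((16, 32), 2.0, np.float32)
        dr = np.full((16, 32), 3.0, np.float32)
        assert lr_consistency(dl, dr) == pytest.approx(1.0, abs=1e-6)
        assert lr_consistency(dl, dr, side="right") == pytest.approx(1.0, abs=1e-6)

    def test_constant_disparity_zero_smoothness(self, texture_64x128):
        d = np.full((64, 128), 4.0, np.float32)
        assert edge_smoothness(d, texture_64x128) == pytest.approx(0.0, abs=1e-7)

    def test_ramp_on_flat_image_scores_slope(self):
        g = 0.25
        d = np.tile(np.arange(32, dtype=np.float32) * g, (16, 1))
        flat = np.full((16, 32, 3), 0.5, np.float32)
        assert edge_smoothness(d, flat) == pytest.approx(g, rel=1e-5)

    def test_image_edges_attenuate_disparity_jumps(self):
        d = np.zeros((16, 32), np.float32)
        d[:, 16:] = 4.0
        flat = np.full((16, 32, 3), 0.5, np.float32)
        edgy = flat.copy()
        edgy[:, 16:] = 0.9
        assert edge_smoothness(d, edgy) < edge_smoothness(d, flat)


class TestTotalLoss:
    def test_all_zero_components(self):
        w = LossWeights()
        assert float(combine_terms(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, w)) == 0.0

    def test_lambda_zero_keeps_photometric_only(self):
        w = LossWeights(lam=0.0)
        assert float(combine_terms(0.3, 0.2, 9.0, 9.0, 9.0, 9.0, w)) == pytest.approx(0.5)

    def test_hand_computed_combination(self):
        w = LossWeights(lam=0.1)
        got = float(combine_terms(0.3, 0.2, 0.4, 0.6, 1.0, 2.0, w))
        assert got == pytest.approx(0.5 + 0.1 * 4.0)

    def test_scale_averaging(self, small_pair):
        left, right, d = small_pair
        terms = [stereo_loss(left, right, d, d, scale=s) for s in (1, 2)]
        avg = total_loss(terms)
        expect = 0.5 * (float(terms[0].total.data) + float(terms[1].total.data))
        assert float(avg.data) == pytest.approx(expect, rel=1e-6)

    def test_stereo_loss_total_matches_components(self, small_pair):
        left, right, d = small_pair
        t = stereo_loss(left, right, d, d)
        s = t.scalars()
        recomputed = (s["photometric_left"] + s["photometric_right"]
                      + 0.1 * (s["lr_consistency_left"] + s["lr_consistency_right"]
                               + s["smoothness_left"] + s["smoothness_right"]))
        assert s["total"] == pytest.approx(recomputed, rel=1e-5)


class TestSearchOracle:
    def test_identical_pair_prefers_zero(self, texture_64x128):
        d = disparity_search_oracle(texture_64x128, texture_64x128, range(0, 6))
        assert np.median(d) == 0.0

    def test_recovers_constant_disparity(self):
        left = generate_tissue_texture(TextureSpec(seed=21, shape=(64, 128)))
        truth = generate_disparity_field(DisparitySpec("constant", 4.0), (64, 128))
        right = render_right_view(left, truth)
        d = disparity_search_oracle(left, right, range(0, 9))
        interior = d[:, 8:-8]
        vals, counts = np.unique(interior, return_counts=True)
        assert vals[np.argmax(counts)] == 4.0

    def test_ramp_recovery_correlates_with_truth(self):
        left = generate_tissue_texture(TextureSpec(seed=22, shape=(64, 128)))
        truth = generate_disparity_field(DisparitySpec("ramp", 8.0), (64, 128))
        right = render_right_view(left, truth)
        d = disparity_search_oracle(left, right, range(0, 10))
        a = d[8:-8, 12:-12].ravel()
        b = truth[8:-8, 12:-12].ravel()
        r = np.corrcoef(a, b)[0, 1]
        assert r > 0.8
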