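"""HSB blocks and the disparity network: unrolled oracle, parameter economy,
scale contracts, determinism."""

import numpy as np
import pytest
from scipy import ndimage

from endo3d.autodiff import Tensor
from endo3d.disparity import (DispNetSpec, DispTrainConfig, HSBConfig, HSBlock,
                              build_disp_net, hsb_param_count, predict_disparity,
                              train_disparity)


def _conv_np(x, weight, bias):
    """Plain stride-1 pad-same correlation, per output channel (oracle)."""
    c_out, c_in, k, _ = weight.shape
    out = np.zeros((c_out,) + x.shape[1:])
    for o in range(c_out):
        for c in range(c_in):
            out[o] += ndimage.correlate(x[c].astype(np.float64), weight[o, c],
                                        mode="constant")
        out[o] += bias[o]
    return out


class TestHSBlock:
    @pytest.mark.parametrize("width,s", [(8, 2), (20, 5), (24, 6), (7, 3), (2, 5)])
    def test_channel_conservation(self, width, s):
        blk = HSBlock(width, HSBConfig(s=s))
        x = Tensor(np.random.default_rng(0).random((1, width, 6, 8)).astype(np.float32))
        out = blk(x)
        assert out.shape == x.shape  # width and spatial size both preserved

    def test_unrolled_oracle_s3(self):
        """Hand-unrolled split/concat/conv sequence must match the block."""
        rng = np.random.default_rng(5)
        blk = HSBlock(9, HSBConfig(s=3))
        x = rng.random((1, 9, 5, 6)).astype(np.float32)
        got = blk(Tensor(x)).data[0]

        mixed = _conv_np(x[0], blk.mix.weight.data, blk.mix.bias.data)
        g1, g2, g3 = mixed[:3], mixed[3:6], mixed[6:9]
        y2 = np.maximum(_conv_np(g2, blk.convs[0].weight.data,
                                 blk.convs[0].bias.data), 0)
        emit2, carry = y2[: y2.shape[0] // 2], y2[y2.shape[0] // 2:]
        inp3 = np.concatenate([g3, carry], axis=0)
        y3 = np.maximum(_conv_np(inp3, blk.convs[1].weight.data,
                                 blk.convs[1].bias.data), 0)
        expect = np.concatenate([g1, emit2, y3], axis=0)
        np.testing.assert_allclose(got, expect, atol=1e-4)

    def test_wrong_width_rejected(self):
        blk = HSBlock(8, HSBConfig(s=2))
        with pytest.raises(ValueError):
            blk(Tensor(np.zeros((1, 6, 4, 4), np.float32)))


class TestHSBParameterEconomy:
    def test_standard_count_arithmetic(self):
        _, p_std = hsb_param_count(3, 4, 5)
        assert p_std == 9 * 25 * 16 == 3600

    @pytest.mark.parametrize("s", [2, 3, 4, 5, 6])
    def test_hsb_beats_standard_convolution(self, s):
        p_hsb, p_std = hsb_param_count(3, 4, s)
        assert p_hsb < p_std

    def test_monotone_in_group_width(self):
        counts = [hsb_param_count(3, w, 5)[0] for w in (2, 4, 8)]
        assert counts == sorted(counts)


class TestDispNet:
    def test_four_scales_with_halving_widths(self):
        net = build_disp_net(DispNetSpec(width_multiplier=0.125), seed=0)
        x = Tensor(np.random.default_rng(0).random((1, 3, 128, 256)).astype(np.float32))
        out = net(x)
        widths = {dv: t[0].shape[3] for dv, t in out.items()}
        assert widths == {1: 256, 2: 128, 4: 64, 8: 32}
        for dv, (dl, dr) in out.items():
            assert dl.shape == dr.shape
            bound = 0.3 * dl.shape[3]
            assert dl.data.min() >= 0 and dl.data.max() <= bound

    def test_zeroed_head_bias_centres_prediction(self):
        net = build_disp_net(DispNetSpec(width_multiplier=0.125), seed=0)
        for head in net.heads:
            head.weight.data[:] = 0
            head.bias.data[:] = 0
        x = Tensor(np.random.default_rng(1).random((1, 3, 64, 128)).astype(np.float32))
        out = net(x)
        for dv, (dl, _) in out.items():
            np.testing.assert_allclose(dl.data, 0.5 * 0.3 * dl.shape[3], atol=1e-5)

    def test_forward_is_pure(self):
        net = build_disp_net(DispNetSpec(width_multiplier=0.125), seed=0)
        img = np.random.default_rng(2).random((64, 128, 3)).astype(np.float32)
        np.testing.assert_array_equal(predict_disparity(net, img),
                                      predict_disparity(net, img))

    def test_prediction_shape_and_nonnegativity(self):
        net = build_disp_net(DispNetSpec(width_multiplier=0.125), seed=0)
        img = np.random.default_rng(3).random((64, 128, 3)).astype(np.float32)
        d = predict_disparity(net, img)
        assert d.shape == (64, 128)
        assert np.all(d >= 0)

    def test_non_multiple_of_32_input_padded_internally(self):
        net = build_disp_net(DispNetSpec(width_multiplier=0.125), seed=0)
        img = np.random.default_rng(4).random((50, 70, 3)).astype(np.float32)
        assert predict_disparity(net, img).shape == (50, 70)


class TestTrainingLoop:
    def test_zero_epochs_and_determinism(self, small_pair):
        left, right, _ = small_pair
        pairs = [(left, right)] * 4
        spec = DispNetSpec(width_multiplier=0.125)
        cfg = DispTrainConfig(input_size=(64, 128), epochs=0, seed=1)
        _, history = train_disparity(pairs, spec, cfg)
        assert history == []
        cfg2 = DispTrainConfig(input_size=(64, 128), epochs=2, batch_size=4,
                               learning_rate=1e-3, seed=1)
        _, h1 = train_disparity(pairs, spec, cfg2)
        _, h2 = train_disparity(pairs, spec, cfg2)
        assert h1 == h2
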