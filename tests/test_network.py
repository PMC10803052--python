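"""Network assembly: stage wiring, shape contracts, cost accounting."""

import numpy as np
import pytest

from cgmunet import (ConfigError, CrossGatedUNet, DimensionError,
                     NetworkConfig, count_flops, count_parameters)
from cgmunet.network import (BottleneckStage, DecoderStage, EncoderStage,
                             OutputStage)
from cgmunet.nn import ConvBlock, Tensor, downsample2, upsample2


def rand(shape, seed=0, grad=False):
    return Tensor(np.random.default_rng(seed).standard_normal(shape)
                  .astype(np.float32), requires_grad=grad)


TINY = NetworkConfig(depth=2, stage_widths=(8, 16), bottleneck_gate_width=16,
                     output_width=8, dropout_rate=0.0)


class TestConvBlock:
    def test_shape_and_parameter_formula(self):
        rng = np.random.default_rng(0)
        blk = ConvBlock(3, 64, rng)
        assert blk(rand((1, 8, 8, 3))).shape == (1, 8, 8, 64)
        assert blk.n_parameters() == 9 * 3 * 64 + 2 * 64

    def test_relu_zeroes_negative_preactivations(self):
        rng = np.random.default_rng(0)
        blk = ConvBlock(2, 4, rng)
        blk.eval()
        blk.bn.beta.data[...] = -100.0  # force negative pre-activations
        out = blk(rand((1, 4, 4, 2)))
        assert not out.data.any()


class TestEncoderStage:
    def test_shape_contract(self):
        enc = EncoderStage(3, 8, TINY, np.random.default_rng(0))
        out = enc(rand((1, 16, 16, 3)))
        assert out.skip.shape == (1, 16, 16, 8)
        assert out.down.shape == (1, 8, 8, 16)

    def test_skip_is_the_gated_map_itself(self):
        enc = EncoderStage(3, 8, TINY, np.random.default_rng(0))
        enc.eval()
        x = rand((1, 16, 16, 3))
        a = enc.conv_a(x)
        u = enc.conv_u(upsample2(enc.conv_d(downsample2(a))))
        expected = enc.mcg(a, u)
        assert np.array_equal(enc(x).skip.data, expected.data)

    def test_down_up_preserves_constant_map(self):
        const = Tensor(np.full((1, 8, 8, 4), 2.5, dtype=np.float32))
        assert np.allclose(upsample2(downsample2(const)).data, 2.5)


class TestDecoderStage:
    def make(self):
        # level 0 of the tiny plan: deep 16ch @ r/2, skips 8ch @ r / 16ch @ r/2
        return DecoderStage(16, 8, 16, 8, 16, TINY, np.random.default_rng(0))

    def test_shape_contract(self):
        dec = self.make()
        out = dec(rand((1, 8, 8, 16)), rand((1, 16, 16, 8)),
                  rand((1, 8, 8, 16)))
        assert out.shape == (1, 16, 16, 8)

    def test_resolution_mismatch_rejected(self):
        dec = self.make()
        with pytest.raises(DimensionError):
            dec(rand((1, 8, 8, 16)), rand((1, 16, 16, 8)),
                rand((1, 16, 16, 16)))
        with pytest.raises(DimensionError):
            dec(rand((1, 8, 8, 16)), rand((1, 8, 8, 8)),
                rand((1, 8, 8, 16)))

    def test_gradients_reach_all_three_inputs(self):
        dec = self.make()
        deep = rand((1, 8, 8, 16), 1, grad=True)
        same = rand((1, 16, 16, 8), 2, grad=True)
        below = rand((1, 8, 8, 16), 3, grad=True)
        (dec(deep, same, below) ** 2.0).sum().backward()
        for t in (deep, same, below):
            assert t.grad is not None and np.abs(t.grad).max() > 0

    def test_zeroing_skip_same_changes_output(self):
        dec = self.make()
        dec.eval()
        deep, below = rand((1, 8, 8, 16), 4), rand((1, 8, 8, 16), 5)
        same = rand((1, 16, 16, 8), 6)
        zeroed = Tensor(np.zeros_like(same.data))
        assert not np.array_equal(dec(deep, same, below).data,
                                  dec(deep, zeroed, below).data)


class TestBottleneckStage:
    def test_shape_and_gradients(self):
        bn = BottleneckStage(32, 16, 16, 16, TINY, np.random.default_rng(0))
        deep = rand((1, 4, 4, 32), 0, grad=True)
        below = rand((1, 4, 4, 16), 1, grad=True)
        out = bn(deep, below)
        assert out.shape == (1, 8, 8, 16)  # twice the bottleneck resolution
        (out ** 2.0).sum().backward()
        assert np.abs(deep.grad).max() > 0 and np.abs(below.grad).max() > 0

    def test_zeroing_skip_below_changes_output(self):
        bn = BottleneckStage(32, 16, 16, 16, TINY, np.random.default_rng(0))
        bn.eval()
        deep, below = rand((1, 4, 4, 32), 2), rand((1, 4, 4, 16), 3)
        zeroed = Tensor(np.zeros_like(below.data))
        assert not np.array_equal(bn(deep, below).data,
                                  bn(deep, zeroed).data)


class TestOutputStage:
    def test_logits_shape_and_head_count(self):
        out = OutputStage(8, 8, 1, TINY, np.random.default_rng(0))
        logits = out(rand((1, 8, 8, 8)))
        assert logits.shape == (1, 8, 8, 1)
        assert out.head.n_parameters() == 8 * 1 + 1

    def test_logits_are_unbounded(self):
        stage = OutputStage(8, 8, 1, TINY, np.random.default_rng(0))
        stage.head.bias.data[...] = 50.0
        logits = stage(rand((1, 8, 8, 8)))
        assert logits.data.max() > 10.0  # no clipping/saturation


class TestAssembledNetwork:
    def test_logits_match_input_resolution(self):
        model = CrossGatedUNet(TINY, seed=0)
        assert model(rand((1, 32, 32, 3))).shape == (1, 32, 32, 1)
        # non-square, unseen size
        assert model(rand((1, 16, 48, 3))).shape == (1, 16, 48, 1)

    def test_unbatched_input(self):
        model = CrossGatedUNet(TINY, seed=0)
        assert model(rand((32, 32, 3))).shape == (32, 32, 1)

    def test_invalid_size_reports_minimal_pad(self):
        model = CrossGatedUNet(TINY, seed=0)
        with pytest.raises(DimensionError, match="minimal valid padded size "
                                                 "is 32x48"):
            model(rand((1, 20, 42, 3)))

    def test_all_parameters_receive_gradient(self):
        """No dead branches: a scalar loss reaches every learnable scalar."""
        model = CrossGatedUNet(TINY, seed=0)
        x = rand((2, 16, 16, 3), 1)
        (model(x) ** 2.0).mean().backward()
        for name, p in model.named_parameters():
            assert p.grad is not None, f"no gradient for {name}"
            assert np.abs(p.grad).max() > 0, f"zero gradient for {name}"

    def test_determinism_across_builds(self):
        x = rand((1, 32, 32, 3), 5)
        outs = []
        for _ in range(2):
            model = CrossGatedUNet(TINY, seed=9)
            model.eval()
            outs.append(model(x).data)
        assert np.array_equal(outs[0], outs[1])

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            NetworkConfig(depth=2, stage_widths=(8,))
        with pytest.raises(ConfigError):
            NetworkConfig(depth=1, stage_widths=(10,))  # not divisible by 4


def _mcg_params(c):
    msm = 2 * c + 2 * (c * c + c) + 2 * (16 + 4) + 2 * (256 + 16)
    return 2 * (2 * c) + 4 * (c * c + c) + msm


def _conv_params(cin, cout):
    return 9 * cin * cout + 2 * cout


def test_count_parameters_matches_independent_bookkeeping():
    """Closed-form ledger of the default stage plan vs model enumeration."""
    cfg = NetworkConfig()
    w = cfg.stage_widths
    total, cin = 0, cfg.in_channels
    for wi in w:  # encoder stages
        total += _conv_params(cin, wi) + 2 * _conv_params(wi, wi) \
            + _mcg_params(wi)
        cin = 2 * wi
    w3, mb = w[-1], cfg.bottleneck_gate_width
    total += (_conv_params(2 * w3, w3) + _conv_params(w3, mb)
              + _conv_params(3 * w3, mb) + _mcg_params(mb)
              + _conv_params(mb + w3, w3))
    for i in (2, 1, 0):
        wi, wn, gi = w[i], w[i + 1], cfg.gate_widths[i]
        total += (_conv_params(wn, wi) + _conv_params(wi, gi)
                  + _conv_params(2 * wn, gi) + _mcg_params(gi)
                  + _conv_params(gi + 2 * wi, wi))
    v = cfg.output_width
    total += (_conv_params(w[0], v) + _conv_params(v, v) + _mcg_params(v)
              + v * cfg.num_classes + cfg.num_classes)
    assert count_parameters(cfg) == total


def test_count_parameters_monotone_and_size_free():
    small = NetworkConfig(depth=1, stage_widths=(16,),
                          bottleneck_gate_width=16, output_width=8)
    big = NetworkConfig(depth=1, stage_widths=(32,),
                        bottleneck_gate_width=16, output_width=8)
    assert count_parameters(small) < count_parameters(big)
    model = CrossGatedUNet(TINY, seed=0)
    n0 = model.n_parameters()
    model(rand((1, 32, 32, 3)))
    model(rand((1, 16, 16, 3)))
    assert model.n_parameters() == n0


def test_flops_scale_linearly_with_pixel_count():
    assert count_flops(TINY, (64, 64)) == pytest.approx(
        4 * count_flops(TINY, (32, 32)), rel=1e-9)


def test_flops_depth0_equals_output_stage_hand_sum():
    cfg = NetworkConfig(depth=0, stage_widths=(), output_width=8,
                        in_channels=3, num_classes=1)
    h = w = 16
    v = 8
    msm_macs = v * v + (v // 4) * (4 + 16) * 2 + v * v
    mcg_macs = 4 * v * v + 2 * msm_macs
    hand = (9 * 3 * v + 9 * v * v + mcg_macs + v * 1) * h * w
    assert count_flops(cfg, (h, w)) == pytest.approx(hand / 1e9, rel=1e-12)
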