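"""Scale-aware dense residual bottleneck: masks, fusion, receptive fields,
and the end-to-end composition."""

import numpy as np
import pytest

from sdrvessel.autograd import Tensor, relu
from sdrvessel.sdr import SDRConfig, SDRModule, fuse_pair, scale_masks


def make_module(rng, c_in=4, c_out=6, drop=0.0):
    return SDRModule(SDRConfig(c_in, c_out, drop_prob=drop), rng).eval()


class TestScaleMasks:
    def test_channel_sums_equal_one(self, rng):
        d = Tensor(rng.normal(size=(2, 5, 8, 8)))
        b1, b2 = scale_masks(d)
        np.testing.assert_allclose(b1.data.sum(axis=1), 1.0, atol=1e-6)
        assert b1 is b2  # beta1 == beta2 by construction

    def test_constant_channels_give_uniform_mask(self):
        d = Tensor(np.full((1, 4, 3, 3), 2.7))
        b1, _ = scale_masks(d)
        np.testing.assert_allclose(b1.data, 0.25, atol=1e-7)

    def test_dominant_channel_saturates(self, rng):
        d = rng.normal(size=(1, 3, 4, 4))
        d[0, 1, 2, 2] += 20.0
        b1, _ = scale_masks(Tensor(d))
        assert b1.data[0, 1, 2, 2] > 0.999


class TestFusePair:
    def test_zero_inputs_give_zero(self, rng):
        z = Tensor(np.zeros((1, 3, 4, 4)))
        mask, _ = scale_masks(Tensor(rng.normal(size=(1, 3, 4, 4))))
        np.testing.assert_array_equal(fuse_pair(z, z, mask).data, 0.0)

    def test_equals_mask_times_sum(self, rng):
        d_a = Tensor(rng.normal(size=(2, 4, 5, 5)))
        d_b = Tensor(rng.normal(size=(2, 4, 5, 5)))
        mask, _ = scale_masks(Tensor(rng.normal(size=(2, 4, 5, 5))))
        np.testing.assert_allclose(
            fuse_pair(d_a, d_b, mask).data, mask.data * (d_a.data + d_b.data), atol=1e-12
        )

    def test_uniform_mask_averages_over_channels(self, rng):
        c = 5
        d_a = Tensor(rng.normal(size=(1, c, 4, 4)))
        d_b = Tensor(rng.normal(size=(1, c, 4, 4)))
        mask, _ = scale_masks(Tensor(np.zeros((1, c, 4, 4))))
        np.testing.assert_allclose(
            fuse_pair(d_a, d_b, mask).data, (d_a.data + d_b.data) / c, atol=1e-7
        )

    def test_shape_mismatch_rejected(self, rng):
        a = Tensor(np.zeros((1, 3, 4, 4)))
        b = Tensor(np.zeros((1, 3, 8, 8)))
        with pytest.raises(ValueError, match="shapes"):
            fuse_pair(a, b, a)


class TestDilatedBranches:
    @pytest.mark.parametrize("idx,rate,support", [(0, 1, 3), (1, 3, 7), (2, 5, 11)])
    def test_impulse_response_support(self, rng, idx, rate, support):
        """A single-pixel impulse spreads to a (2r+1)^2 window and no further."""
        mod = make_module(rng, c_in=1, c_out=3)
        branch = mod.branches[idx]
        assert branch.rate == rate
        # passthrough normalization so the conv footprint is visible
        branch.bn.running_mean[...] = 0.0
        branch.bn.running_var[...] = 1.0 - branch.bn.eps
        x = np.zeros((1, 1, 32, 32), dtype=np.float32)
        x[0, 0, 16, 16] = 1.0
        out = np.abs(branch(Tensor(x)).data).sum(axis=(0, 1))
        ys, xs = np.nonzero(out)
        assert ys.min() >= 16 - support // 2 and ys.max() <= 16 + support // 2
        assert xs.min() >= 16 - support // 2 and xs.max() <= 16 + support // 2
        # support fills the full window in at least one direction
        assert ys.max() - ys.min() == support - 1

    def test_rate1_equals_plain_convolution(self, rng):
        """The rate-1 branch with shared weights is an ordinary 3x3 convolution."""
        from scipy.signal import correlate

        mod = make_module(rng, c_in=2, c_out=3)
        branch = mod.branches[0]
        x = rng.normal(size=(1, 2, 10, 10)).astype(np.float32)
        from sdrvessel.autograd import conv2d
        ours = conv2d(Tensor(x), branch.conv.weight).data
        for co in range(3):
            ref = sum(correlate(x[0, ci], branch.conv.weight.data[co, ci], mode="same") for ci in range(2))
            np.testing.assert_allclose(ours[0, co], ref, atol=1e-4)

    def test_branch_outputs_nonnegative(self, rng):
        mod = make_module(rng)
        x = Tensor(rng.normal(size=(2, 4, 8, 8)).astype(np.float32))
        for branch in mod.branches:
            assert (branch(x).data >= 0).all()

    def test_receptive_field_grows_with_rate(self, rng):
        mod = make_module(rng, c_in=1, c_out=2)
        supports = []
        for branch in mod.branches:
            branch.bn.running_mean[...] = 0.0
            branch.bn.running_var[...] = 1.0 - branch.bn.eps
            x = np.zeros((1, 1, 32, 32), dtype=np.float32)
            x[0, 0, 16, 16] = 1.0
            out = np.abs(branch(Tensor(x)).data).sum(axis=(0, 1))
            ys, _ = np.nonzero(out)
            supports.append(ys.max() - ys.min())
        assert supports[0] < supports[1] < supports[2]


class TestTransferLayer:
    def test_inference_deterministic(self, rng):
        mod = make_module(rng, drop=0.3)
        x = Tensor(rng.normal(size=(1, 6, 8, 8)).astype(np.float32))
        np.testing.assert_array_equal(mod.transfer12(x).data, mod.transfer12(x).data)

    def test_zero_input_gives_zero_output(self, rng):
        mod = make_module(rng)
        t = mod.transfer12
        t.bn.running_mean[...] = 0.0
        t.bn.running_var[...] = 1.0 - t.bn.eps
        out = t(Tensor(np.zeros((1, 6, 8, 8), dtype=np.float32)))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-7)

    def test_matches_manual_composition(self, rng):
        mod = make_module(rng)
        t = mod.transfer12
        x = Tensor(rng.normal(size=(2, 6, 8, 8)).astype(np.float32))
        manual = relu(t.bn(t.conv(x)))
        np.testing.assert_allclose(t(x).data, manual.data, atol=1e-6)


class TestSDRForward:
    def test_spatial_dims_preserved_and_nonnegative(self, rng):
        mod = make_module(rng, c_in=3, c_out=8)
        x = Tensor(rng.normal(size=(2, 3, 16, 16)).astype(np.float32))
        out = mod(x)
        assert out.shape == (2, 8, 16, 16)
        assert (out.data >= 0).all()

    def test_equals_explicit_suboperation_composition(self, rng):
        """Forward equals the five sub-operations invoked manually in order."""
        mod = make_module(rng, c_in=4, c_out=6)
        x = Tensor(rng.normal(size=(1, 4, 12, 12)).astype(np.float32))
        d1, d2, d3 = (mod.dilated_branch(x, i) for i in range(3))
        m12, _ = scale_masks(mod.transfer12(d1 + d2))
        m23, _ = scale_masks(mod.transfer23(d2 + d3))
        out12 = fuse_pair(d1, d2, m12)
        out23 = fuse_pair(d2, d3, m23)
        manual = relu(mod.fuse_bn(mod.fuse(out12 + out23 + mod.skip(x))))
        np.testing.assert_allclose(mod(x).data, manual.data, atol=1e-6)

    def test_skip_path_alone_carries_signal(self, rng):
        """Zeroing both fusion-branch contributions leaves the dense-residual path."""
        mod = make_module(rng, c_in=4, c_out=6)
        for branch in mod.branches:
            branch.conv.weight.data[...] = 0.0
            branch.bn.running_mean[...] = 0.0
            branch.bn.running_var[...] = 1.0 - branch.bn.eps
        for t in (mod.transfer12, mod.transfer23):
            t.conv.weight.data[...] = 0.0
            t.bn.running_mean[...] = 0.0
            t.bn.running_var[...] = 1.0 - t.bn.eps
        x = Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
        expected = relu(mod.fuse_bn(mod.fuse(mod.skip(x))))
        np.testing.assert_allclose(mod(x).data, expected.data, atol=1e-6)

    def test_channel_mismatch_rejected(self, rng):
        mod = make_module(rng, c_in=4, c_out=6)
        with pytest.raises(ValueError, match="channels"):
            mod(Tensor(np.zeros((1, 3, 8, 8), dtype=np.float32)))

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError, match="dilation_rates"):
            SDRConfig(4, 4, dilation_rates=(5, 3, 1))
        with pytest.raises(ValueError, match="dilation_rates"):
            SDRConfig(4, 4, dilation_rates=(1, 1, 3))
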