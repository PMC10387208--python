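"""Structured residual block, DropBlock and attention gate behavior."""

import numpy as np
import pytest

from sdrvessel.autograd import Tensor, relu
from sdrvessel.blocks import AttentionGate, BlockConfig, StructuredResidualBlock, drop_block
from sdrvessel.nn import dropblock_gamma


def _passthrough_bn(bn):
    """Make an inference-mode BatchNorm the identity (zero mean, unit var buffers)."""
    bn.running_mean[...] = 0.0
    bn.running_var[...] = 1.0 - bn.eps


class TestStructuredResidualBlock:
    def test_zero_main_path_identity_skip_returns_input(self, rng):
        """Zero main-path kernels + identity skip + final ReLU reproduce a nonnegative input."""
        block = StructuredResidualBlock(BlockConfig(4, 4, drop_prob=0.0), rng)
        block.eval()
        for conv in (block.conv1, block.conv2):
            conv.weight.data[...] = 0.0
        for bn in (block.bn1, block.bn2):
            _passthrough_bn(bn)
        x = Tensor(rng.random((2, 4, 8, 8)).astype(np.float32))  # nonnegative
        out = block(x)
        np.testing.assert_allclose(out.data, x.data, atol=1e-6)

    def test_inference_deterministic(self, rng):
        block = StructuredResidualBlock(BlockConfig(3, 8), rng).eval()
        x = Tensor(rng.normal(size=(1, 3, 16, 16)).astype(np.float32))
        np.testing.assert_array_equal(block(x).data, block(x).data)

    def test_matches_manual_layer_composition(self, rng):
        """Block output equals the stated conv/DropBlock/BN/ReLU sequence applied by hand."""
        block = StructuredResidualBlock(BlockConfig(3, 6, drop_prob=0.0), rng).eval()
        x = Tensor(rng.normal(size=(2, 3, 12, 12)).astype(np.float32))
        h = relu(block.bn1(block.conv1(x)))
        h = relu(block.bn2(block.conv2(h)))
        manual = relu(h + block.proj(x))
        np.testing.assert_allclose(block(x).data, manual.data, atol=1e-6)

    def test_channel_mismatch_rejected(self, rng):
        block = StructuredResidualBlock(BlockConfig(3, 6), rng)
        with pytest.raises(ValueError, match="channels"):
            block(Tensor(np.zeros((1, 5, 8, 8), dtype=np.float32)))

    def test_output_shape(self, rng):
        block = StructuredResidualBlock(BlockConfig(3, 10), rng).eval()
        out = block(Tensor(rng.normal(size=(2, 3, 16, 24)).astype(np.float32)))
        assert out.shape == (2, 10, 16, 24)


class TestDropBlock:
    def test_zero_prob_is_identity_in_training(self, rng):
        x = rng.random((2, 4, 16, 16)).astype(np.float32)
        out = drop_block(x, drop_prob=0.0, block_size=3, training=True, seed=0)
        np.testing.assert_array_equal(out.data, x)

    def test_inference_identity_any_prob(self, rng):
        x = rng.random((2, 4, 16, 16)).astype(np.float32)
        out = drop_block(x, drop_prob=0.5, block_size=3, training=False, seed=0)
        np.testing.assert_array_equal(out.data, x)

    def test_seeded_reproducible(self, rng):
        x = rng.random((1, 2, 32, 32)).astype(np.float32)
        a = drop_block(x, 0.18, 3, training=True, seed=42).data
        b = drop_block(x, 0.18, 3, training=True, seed=42).data
        np.testing.assert_array_equal(a, b)

    def test_zeroed_regions_are_blocks(self):
        x = np.ones((1, 1, 40, 40), dtype=np.float32)
        out = drop_block(x, 0.05, 3, training=True, seed=7).data[0, 0]
        dropped = out == 0
        assert dropped.any()
        # every dropped pixel belongs to at least one fully-dropped 3x3 square
        from scipy import ndimage
        cover = ndimage.minimum_filter(dropped, size=3, mode="constant")  # 3x3 all-dropped centers
        grown = ndimage.maximum_filter(cover, size=3, mode="constant")
        assert (dropped <= grown).all()

    def test_mean_preservation_with_rescaling(self):
        """Survivor rescaling keeps the expected activation equal to the input."""
        x = np.ones((1, 8, 32, 32), dtype=np.float32)
        means = [drop_block(x, 0.18, 3, training=True, seed=s).data.mean() for s in range(300)]
        assert abs(np.mean(means) - 1.0) < 0.01

    def test_drop_prob_one_rejected(self):
        with pytest.raises(ValueError, match="drop_prob"):
            drop_block(np.ones((1, 1, 8, 8)), 1.0, 3, training=True, seed=0)

    def test_block_size_larger_than_map_rejected(self):
        with pytest.raises(ValueError, match="block_size"):
            dropblock_gamma(0.18, 9, 4, 4)

    def test_empirical_drop_fraction_matches_probability(self):
        """Seed-rate calibration: realized zero fraction ~ drop_prob (quick check)."""
        x = np.ones((1, 8, 64, 64), dtype=np.float32)
        fracs = [(drop_block(x, 0.18, 3, training=True, seed=s).data == 0).mean() for s in range(150)]
        assert abs(np.mean(fracs) - 0.18) < 0.02


class TestAttentionGate:
    def test_output_shape_matches_encoder_input(self, rng):
        gate = AttentionGate(8, 12, rng).eval()
        x1 = Tensor(rng.normal(size=(2, 8, 10, 10)).astype(np.float32))
        x2 = Tensor(rng.normal(size=(2, 12, 10, 10)).astype(np.float32))
        assert gate(x1, x2).shape == x2.shape

    def test_mask_bounded_and_output_below_input(self, rng):
        gate = AttentionGate(4, 6, rng).eval()
        x1 = Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
        x2 = Tensor(rng.random((1, 6, 8, 8)).astype(np.float32))  # nonnegative
        mask = gate.mask(x1, x2)
        assert (mask.data > 0).all() and (mask.data < 1).all()
        out = gate(x1, x2)
        assert (out.data >= 0).all() and (out.data <= x2.data + 1e-7).all()

    def test_zero_kernels_give_constant_half_mask(self, rng):
        """With all 1x1 kernels zero and zero final bias, mask = sigmoid(0) = 0.5."""
        gate = AttentionGate(4, 4, rng).eval()
        for conv in (gate.f_dec, gate.f_enc, gate.psi):
            conv.weight.data[...] = 0.0
            conv.bias.data[...] = 0.0
        gate.bn.running_mean[...] = 0.0
        gate.bn.running_var[...] = 1.0
        x1 = Tensor(rng.normal(size=(1, 4, 6, 6)).astype(np.float32))
        x2 = Tensor(np.ones((1, 4, 6, 6), dtype=np.float32))
        np.testing.assert_allclose(gate(x1, x2).data, 0.5, atol=1e-7)

    def test_spatial_mismatch_rejected(self, rng):
        gate = AttentionGate(4, 4, rng)
        with pytest.raises(ValueError, match="spatial"):
            gate(Tensor(np.zeros((1, 4, 8, 8), dtype=np.float32)),
                 Tensor(np.zeros((1, 4, 16, 16), dtype=np.float32)))

    def test_single_channel_mask_broadcasts_across_channels(self, rng):
        gate = AttentionGate(3, 5, rng).eval()
        x1 = Tensor(rng.normal(size=(1, 3, 8, 8)).astype(np.float32))
        x2 = Tensor(rng.normal(size=(1, 5, 8, 8)).astype(np.float32))
        mask = gate.mask(x1, x2)
        assert mask.shape == (1, 1, 8, 8)
        np.testing.assert_allclose(gate(x1, x2).data, x2.data * mask.data, atol=1e-7)
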