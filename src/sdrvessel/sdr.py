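"""Scale-aware dense residual (SDR) bottleneck.

Three parallel dilated 3x3 branches (rates 1/3/5 by default) extract features
at growing receptive fields (a rate-r 3x3 kernel spans 2r+1 pixels).  Adjacent
branch pairs (D1, D2) and (D2, D3) are merged by elementwise addition, passed
through a transfer layer (conv3x3 -> DropBlock -> BN -> ReLU), and the
transfer output is turned into a channel-softmax weight mask that reweights
the merged pair.  A 1x1 convolution of the block input provides a dense
residual skip, and a final 1x1 conv -> BN -> ReLU fuses the two pair outputs
with the skip:

    D_i    = ReLU(BN(conv3x3_dil(x, rate_i)))
    D'_ab  = ReLU(BN(DropBlock(conv3x3(D_a + D_b))))
    beta   = softmax_channels(D'_ab)           (beta1 == beta2)
    Out_ab = beta * (D_a + D_b)
    X'     = conv1x1(x)
    out    = ReLU(BN(conv1x1(Out_12 + Out_23 + X')))
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, relu, softmax_channels
from .nn import BatchNorm2d, Conv2d, DropBlock2d, Module

__all__ = ["SDRConfig", "SDRModule", "scale_masks", "fuse_pair"]


@dataclass
class SDRConfig:
    in_channels: int
    out_channels: int
    dilation_rates: tuple = (1, 3, 5)
    drop_prob: float = 0.18
    block_size: int = 3

    def __post_init__(self):
        rates = tuple(self.dilation_rates)
        if len(rates) != 3 or any(r < 1 for r in rates) or list(rates) != sorted(set(rates)):
            raise ValueError(f"dilation_rates must be 3 strictly increasing integers >= 1, got {rates}")
        self.dilation_rates = rates


def scale_masks(d_prime: Tensor) -> tuple[Tensor, Tensor]:
    """Two identical channel-softmax weight masks from a transfer-layer output.

    At every spatial location the mask values sum to 1 across channels.
    """
    m = softmax_channels(d_prime, axis=1)
    return m, m


def fuse_pair(d_a: Tensor, d_b: Tensor, mask: Tensor) -> Tensor:
    """Scale-aware fusion: beta1*D_a + beta2*D_b with beta1 == beta2 == mask."""
    if not (d_a.shape == d_b.shape == mask.shape):
        raise ValueError(f"fuse_pair shapes differ: {d_a.shape}, {d_b.shape}, {mask.shape}")
    return mask * d_a + mask * d_b


class _DilatedBranch(Module):
    def __init__(self, c_in: int, c_out: int, rate: int, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.conv = Conv2d(c_in, c_out, 3, rng, dilation=rate, bias=False)
        self.bn = BatchNorm2d(c_out)

    def forward(self, x: Tensor) -> Tensor:
        return relu(self.bn(self.conv(x)))


class _TransferLayer(Module):
    def __init__(self, c: int, drop_prob: float, block_size: int,
                 rng: np.random.Generator, drop_seed=None):
        super().__init__()
        self.conv = Conv2d(c, c, 3, rng, bias=False)
        self.drop = DropBlock2d(drop_prob, block_size, seed=drop_seed)
        self.bn = BatchNorm2d(c)

    def forward(self, d_merged: Tensor) -> Tensor:
        return relu(self.bn(self.drop(self.conv(d_merged))))


class SDRModule(Module):
    """The full bottleneck; the two transfer layers have independent weights."""

    def __init__(self, cfg: SDRConfig, rng: np.random.Generator, drop_seed: int | None = None):
        super().__init__()
        self.cfg = cfg
        if drop_seed is None:
            ss = [None, None]
        else:
            seq = drop_seed if isinstance(drop_seed, np.random.SeedSequence) else np.random.SeedSequence(drop_seed)
            ss = seq.spawn(2)
        self.branches = [
            _DilatedBranch(cfg.in_channels, cfg.out_channels, r, rng) for r in cfg.dilation_rates
        ]
        self.transfer12 = _TransferLayer(cfg.out_channels, cfg.drop_prob, cfg.block_size, rng, ss[0])
        self.transfer23 = _TransferLayer(cfg.out_channels, cfg.drop_prob, cfg.block_size, rng, ss[1])
        self.skip = Conv2d(cfg.in_channels, cfg.out_channels, 1, rng, bias=False)
        self.fuse = Conv2d(cfg.out_channels, cfg.out_channels, 1, rng, bias=False)
        self.fuse_bn = BatchNorm2d(cfg.out_channels)

    def dilated_branch(self, x: Tensor, index: int) -> Tensor:
        """D_i for branch ``index`` in {0, 1, 2}."""
        return self.branches[index](x)

    def _pair(self, d_a: Tensor, d_b: Tensor, transfer: _TransferLayer) -> Tensor:
        merged = d_a + d_b
        d_prime = transfer(merged)
        beta1, _ = scale_masks(d_prime)
        return fuse_pair(d_a, d_b, beta1)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(f"SDR expects {self.cfg.in_channels} channels, got {x.shape[1]}")
        d1, d2, d3 = (b(x) for b in self.branches)
        out12 = self._pair(d1, d2, self.transfer12)
        out23 = self._pair(d2, d3, self.transfer23)
        x_skip = self.skip(x)
        return relu(self.fuse_bn(self.fuse(out12 + out23 + x_skip)))
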