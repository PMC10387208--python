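"""Reusable backbone blocks: structured residual convolution, DropBlock,
and the spatial attention gate.

The structured residual block is the encoder/decoder workhorse: two
``conv3x3 -> DropBlock -> BatchNorm -> ReLU`` stages plus an additive skip
(identity when channel counts match, 1x1 projection otherwise) and a final
ReLU.  The attention gate reweights an encoder skip ``x2`` by a single-channel
spatial mask computed from the decoder gating signal ``x1``:

    mask = sigmoid( conv1x1( BN( ReLU( conv1x1(x1) + conv1x1(x2) ) ) ) )
    out  = x2 * mask          (mask broadcast across x2's channels)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, relu, sigmoid
from .nn import BatchNorm2d, Conv2d, DropBlock2d, Module, _dropblock_mask

__all__ = ["BlockConfig", "StructuredResidualBlock", "AttentionGate", "drop_block"]


@dataclass
class BlockConfig:
    in_channels: int
    out_channels: int
    drop_prob: float = 0.18
    block_size: int = 3

    def __post_init__(self):
        if not 0.0 <= self.drop_prob < 1.0:
            raise ValueError(f"drop_prob must be in [0, 1), got {self.drop_prob}")
        if self.block_size < 1 or self.block_size % 2 == 0:
            raise ValueError(f"block_size must be odd and >= 1, got {self.block_size}")


def drop_block(x, drop_prob: float, block_size: int, training: bool, seed: int):
    """Functional DropBlock on a (B, C, H, W) tensor or array.

    Identity when ``training`` is off or ``drop_prob`` is zero; otherwise zeroes
    contiguous ``block_size x block_size`` regions around Bernoulli seed points
    (rate calibrated so the realized drop fraction matches ``drop_prob``) and
    rescales survivors by total/kept so the expected activation is preserved.
    """
    if not 0.0 <= drop_prob < 1.0:
        raise ValueError(f"drop_prob must be in [0, 1), got {drop_prob}")
    if block_size % 2 == 0 or block_size < 1:
        raise ValueError(f"block_size must be odd and >= 1, got {block_size}")
    t = x if isinstance(x, Tensor) else Tensor(x)
    if not training or drop_prob == 0.0:
        return t
    rng = np.random.default_rng(seed)
    mask = _dropblock_mask(t.shape, drop_prob, block_size, rng)
    kept = mask.sum()
    scale = mask.size / kept if kept > 0 else 0.0
    return t * Tensor((mask * scale).astype(t.dtype))


class StructuredResidualBlock(Module):
    """[conv3x3 -> DropBlock -> BN -> ReLU] x 2 with additive skip + final ReLU."""

    def __init__(self, cfg: BlockConfig, rng: np.random.Generator, drop_seed: int | None = None):
        super().__init__()
        self.cfg = cfg
        c_in, c_out = cfg.in_channels, cfg.out_channels
        if drop_seed is None:
            ss = [None, None]
        else:
            seq = drop_seed if isinstance(drop_seed, np.random.SeedSequence) else np.random.SeedSequence(drop_seed)
            ss = seq.spawn(2)
        self.conv1 = Conv2d(c_in, c_out, 3, rng, bias=False)
        self.drop1 = DropBlock2d(cfg.drop_prob, cfg.block_size, seed=ss[0])
        self.bn1 = BatchNorm2d(c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, rng, bias=False)
        self.drop2 = DropBlock2d(cfg.drop_prob, cfg.block_size, seed=ss[1])
        self.bn2 = BatchNorm2d(c_out)
        self.proj = Conv2d(c_in, c_out, 1, rng, bias=True) if c_in != c_out else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"residual block expects {self.cfg.in_channels} channels, got {x.shape[1]}"
            )
        h = relu(self.bn1(self.drop1(self.conv1(x))))
        h = relu(self.bn2(self.drop2(self.conv2(h))))
        skip = self.proj(x) if self.proj is not None else x
        return relu(h + skip)


class AttentionGate(Module):
    """Spatial attention over an encoder skip connection.

    ``inter_channels`` is the common width both inputs are projected to before
    merging; it defaults to half the encoder width (at least 1).  The two 1x1
    projections have independent weights.
    """

    def __init__(self, decoder_channels: int, encoder_channels: int,
                 rng: np.random.Generator, inter_channels: int | None = None):
        super().__init__()
        if inter_channels is None:
            inter_channels = max(encoder_channels // 2, 1)
        self.f_dec = Conv2d(decoder_channels, inter_channels, 1, rng, bias=True)
        self.f_enc = Conv2d(encoder_channels, inter_channels, 1, rng, bias=True)
        self.bn = BatchNorm2d(inter_channels)
        self.psi = Conv2d(inter_channels, 1, 1, rng, bias=True)

    def mask(self, x1: Tensor, x2: Tensor) -> Tensor:
        if x1.shape[2:] != x2.shape[2:]:
            raise ValueError(
                f"attention gate inputs must share spatial shape, got {x1.shape[2:]} vs {x2.shape[2:]}"
            )
        merged = relu(self.f_dec(x1) + self.f_enc(x2))
        return sigmoid(self.psi(self.bn(merged)))

    def forward(self, x1: Tensor, x2: Tensor) -> Tensor:
        return x2 * self.mask(x1, x2)
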