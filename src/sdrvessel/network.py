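"""Full segmentation network: 4-stage residual encoder, SDR bottleneck,
4-stage attention-gated residual decoder, and four deeply-supervised output
heads.

Resolution flow for an H x W input (H, W divisible by 16): encoder stages run
at /1, /2, /4, /8 with 2x2 max pooling between them; the SDR bottleneck sits
at /16; decoder stages d4..d1 run at /8, /4, /2, /1.  Each decoder stage
upsamples 2x, gates the matching encoder skip with a spatial attention gate
(the upsampled decoder features are the gating signal), concatenates, and
applies a structured residual block.

Each decoder stage i has an output head: upsample by factor (8, 4, 2, 1 for
d4..d1) -> conv1x1 to one channel -> BatchNorm -> ReLU -> sigmoid, giving a
full-resolution probability map.  ``out1`` (from the shallowest stage d1,
factor 1) is the final prediction; the deeper heads exist for the
multi-output training loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, concat_channels, max_pool2x2, no_grad, relu, sigmoid, upsample_bilinear
from .blocks import AttentionGate, BlockConfig, StructuredResidualBlock
from .nn import BatchNorm2d, Conv2d, ConvTranspose2x2, Module
from .sdr import SDRConfig, SDRModule

__all__ = ["NetworkConfig", "DecoderOutputs", "SDRVesselNet", "build_network", "predict_mask"]


@dataclass
class NetworkConfig:
    input_channels: int = 3
    stage_widths: tuple = (32, 64, 128, 256)
    bottleneck_width: int | None = None  # default: last encoder width
    upsample_mode: str = "bilinear"  # or "transposed"
    head: str = "eq_head"  # "eq_head": conv1x1->BN->ReLU->sigmoid; "sigmoid": conv1x1->sigmoid
    drop_prob: float = 0.18
    block_size: int = 3
    dilation_rates: tuple = (1, 3, 5)

    def __post_init__(self):
        self.stage_widths = tuple(self.stage_widths)
        if len(self.stage_widths) != 4:
            raise ValueError(f"exactly 4 encoder stages are required, got {len(self.stage_widths)}")
        if self.upsample_mode not in ("bilinear", "transposed"):
            raise ValueError(f"unknown upsample_mode {self.upsample_mode!r}")
        if self.head not in ("eq_head", "sigmoid"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.bottleneck_width is None:
            self.bottleneck_width = self.stage_widths[-1]

    def to_dict(self) -> dict:
        return {
            "input_channels": self.input_channels,
            "stage_widths": list(self.stage_widths),
            "bottleneck_width": self.bottleneck_width,
            "upsample_mode": self.upsample_mode,
            "head": self.head,
            "drop_prob": self.drop_prob,
            "block_size": self.block_size,
            "dilation_rates": list(self.dilation_rates),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


@dataclass
class DecoderOutputs:
    """Four full-resolution probability maps; ``out(1)`` is the prediction."""

    maps: tuple  # (out1, out2, out3, out4) as Tensors, each (B, 1, H, W)
    factors: tuple = (1, 2, 4, 8)

    def out(self, i: int) -> Tensor:
        return self.maps[i - 1]

    @property
    def final(self) -> Tensor:
        return self.maps[0]


class _Upsampler(Module):
    def __init__(self, mode: str, channels: int, rng: np.random.Generator):
        super().__init__()
        self.mode = mode
        self.deconv = ConvTranspose2x2(channels, channels, rng) if mode == "transposed" else None

    def forward(self, x: Tensor) -> Tensor:
        if self.mode == "bilinear":
            return upsample_bilinear(x, 2)
        return self.deconv(x)


class _Head(Module):
    def __init__(self, in_channels: int, factor: int, kind: str, rng: np.random.Generator):
        super().__init__()
        self.factor = factor
        self.kind = kind
        self.conv = Conv2d(in_channels, 1, 1, rng, bias=(kind == "sigmoid"))
        self.bn = BatchNorm2d(1) if kind == "eq_head" else None

    def forward(self, x: Tensor) -> Tensor:
        up = upsample_bilinear(x, self.factor)
        if self.kind == "eq_head":
            return sigmoid(relu(self.bn(self.conv(up))))
        return sigmoid(self.conv(up))


class _DecoderStage(Module):
    def __init__(self, in_channels: int, skip_channels: int, out_channels: int,
                 cfg: NetworkConfig, rng: np.random.Generator, drop_seed):
        super().__init__()
        self.up = _Upsampler(cfg.upsample_mode, in_channels, rng)
        self.gate = AttentionGate(in_channels, skip_channels, rng)
        self.block = StructuredResidualBlock(
            BlockConfig(in_channels + skip_channels, out_channels, cfg.drop_prob, cfg.block_size),
            rng, drop_seed,
        )

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        up = self.up(x)
        gated = self.gate(up, skip)
        return self.block(concat_channels([up, gated]))


class SDRVesselNet(Module):
    """Attention-residual U-shape network with an SDR bottleneck."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        ss = np.random.SeedSequence(seed)
        init_seed, drop_root = ss.spawn(2)
        rng = np.random.default_rng(init_seed)
        drops = drop_root.spawn(16)
        w = cfg.stage_widths

        def bcfg(ci, co):
            return BlockConfig(ci, co, cfg.drop_prob, cfg.block_size)

        self.enc = [
            StructuredResidualBlock(bcfg(cfg.input_channels, w[0]), rng, drops[0]),
            StructuredResidualBlock(bcfg(w[0], w[1]), rng, drops[1]),
            StructuredResidualBlock(bcfg(w[1], w[2]), rng, drops[2]),
            StructuredResidualBlock(bcfg(w[2], w[3]), rng, drops[3]),
        ]
        self.bottleneck = SDRModule(
            SDRConfig(w[3], cfg.bottleneck_width, cfg.dilation_rates, cfg.drop_prob, cfg.block_size),
            rng, drops[4],
        )
        # decoder stages deepest (d4, /8) to shallowest (d1, /1)
        self.dec = [
            _DecoderStage(cfg.bottleneck_width, w[3], w[3], cfg, rng, drops[5]),
            _DecoderStage(w[3], w[2], w[2], cfg, rng, drops[6]),
            _DecoderStage(w[2], w[1], w[1], cfg, rng, drops[7]),
            _DecoderStage(w[1], w[0], w[0], cfg, rng, drops[8]),
        ]
        # heads indexed 1..4 = shallowest..deepest decoder stage
        self.heads = [
            _Head(w[0], 1, cfg.head, rng),
            _Head(w[1], 2, cfg.head, rng),
            _Head(w[2], 4, cfg.head, rng),
            _Head(w[3], 8, cfg.head, rng),
        ]

    def forward(self, image: Tensor) -> DecoderOutputs:
        x = image if isinstance(image, Tensor) else Tensor(image)
        h, w = x.shape[2], x.shape[3]
        if h % 16 or w % 16:
            raise ValueError(f"input spatial dims must be divisible by 16, got {h}x{w}")
        if x.shape[1] != self.cfg.input_channels:
            raise ValueError(f"expected {self.cfg.input_channels} input channels, got {x.shape[1]}")
        e1 = self.enc[0](x)
        e2 = self.enc[1](max_pool2x2(e1))
        e3 = self.enc[2](max_pool2x2(e2))
        e4 = self.enc[3](max_pool2x2(e3))
        b = self.bottleneck(max_pool2x2(e4))
        d4 = self.dec[0](b, e4)
        d3 = self.dec[1](d4, e3)
        d2 = self.dec[2](d3, e2)
        d1 = self.dec[3](d2, e1)
        outs = (
            self.heads[0](d1),
            self.heads[1](d2),
            self.heads[2](d3),
            self.heads[3](d4),
        )
        return DecoderOutputs(maps=outs)


def build_network(cfg: NetworkConfig, seed: int = 0) -> SDRVesselNet:
    return SDRVesselNet(cfg, seed=seed)


def predict_mask(model: SDRVesselNet, image, threshold: float = 0.5) -> np.ndarray:
    """Binarize the final head at a fixed threshold (foreground iff p > t, strict).

    ``image`` is (B, C, H, W) or (C, H, W); returns a uint8 {0, 1} mask of the
    same spatial shape (batch axis preserved if given).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    arr = image.data if isinstance(image, Tensor) else np.asarray(image)
    squeeze = arr.ndim == 3
    if squeeze:
        arr = arr[None]
    was_training = model.training
    model.eval()
    try:
        with no_grad():
            prob = model(Tensor(arr)).final.data[:, 0]
    finally:
        if was_training:
            model.train()
    mask = (prob > threshold).astype(np.uint8)
    return mask[0] if squeeze else mask


def count_parameters(model: Module) -> int:
    return int(sum(p.data.size for p in model.parameters()))
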