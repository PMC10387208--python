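"""Layers and optimizer built on the autodiff core.

``Module`` provides recursive parameter/buffer traversal with stable,
attribute-path names (used for checkpoints), ``train()``/``eval()`` mode
switching, and seeded initialization: every weighted layer takes a
``numpy.random.Generator`` at construction so a whole network is a pure
function of its config and seed.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .autograd import Tensor, batch_norm, conv2d, conv_transpose2x2

__all__ = ["Module", "Parameter", "Conv2d", "ConvTranspose2x2", "BatchNorm2d", "DropBlock2d", "Adam", "dropblock_gamma"]


class Parameter(Tensor):
    """A tensor that is trainable by default."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- traversal ----------------------------------------------------------
    def _children(self):
        for name, value in self.__dict__.items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def state_dict(self) -> dict:
        state = {f"param:{k}": v.data for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            kind, name = key.split(":", 1)
            if kind == "param":
                if name not in params:
                    raise KeyError(f"unknown parameter in checkpoint: {name}")
                if params[name].data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {name}: checkpoint {value.shape} vs model {params[name].data.shape}"
                    )
                params[name].data = value.astype(params[name].data.dtype)
            else:
                if name not in buffers:
                    raise KeyError(f"unknown buffer in checkpoint: {name}")
                buffers[name][...] = value

    # -- mode ---------------------------------------------------------------
    def train(self):
        self.training = True
        for _, child in self._children():
            child.train()
        return self

    def eval(self):
        self.training = False
        for _, child in self._children():
            child.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """'Same' convolution; He-normal weight init, optional bias.

    Layers feeding directly into BatchNorm are built with ``bias=False``:
    normalization cancels a constant channel offset, so such a bias is
    unidentifiable and receives an identically-zero gradient.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dilation: int = 1, bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.dilation = dilation
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, size=(out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(f"Conv2d configured for {self.in_channels} input channels, got {x.shape[1]}")
        return conv2d(x, self.weight, self.bias, dilation=self.dilation)


class ConvTranspose2x2(Module):
    """Learned 2x upsampling (2x2 kernel, stride 2)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        std = np.sqrt(2.0 / in_channels)
        self.weight = Parameter(rng.normal(0.0, std, size=(in_channels, out_channels, 2, 2)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.num_features = num_features
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=np.float64)
        self.running_var = np.ones(num_features, dtype=np.float64)

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum, eps=self.eps,
        )


def dropblock_gamma(drop_prob: float, block_size: int, height: int, width: int) -> float:
    """Seed-point rate calibrated so the realized drop fraction matches drop_prob.

    gamma = p / b^2 * (H W) / ((H - b + 1)(W - b + 1)) — each seed zeroes a
    b x b block and seeds may only be placed where the block fits entirely.
    """
    if block_size > min(height, width):
        raise ValueError(f"block_size {block_size} exceeds feature map {height}x{width}")
    valid = (height - block_size + 1) * (width - block_size + 1)
    return drop_prob / (block_size**2) * (height * width) / valid


def _dropblock_mask(shape, drop_prob: float, block_size: int, rng: np.random.Generator) -> np.ndarray:
    """Binary keep-mask (1 = keep) with contiguous zero blocks, per feature map."""
    b, c, h, w = shape
    gamma = dropblock_gamma(drop_prob, block_size, h, w)
    half = block_size // 2
    seeds = np.zeros(shape, dtype=bool)
    valid = rng.random((b, c, h - block_size + 1, w - block_size + 1)) < gamma
    seeds[:, :, half : h - block_size + 1 + half, half : w - block_size + 1 + half] = valid
    dropped = ndimage.maximum_filter(seeds, size=(1, 1, block_size, block_size), mode="constant")
    return ~dropped


class DropBlock2d(Module):
    """Structured dropout: zero contiguous square blocks, rescale survivors.

    Identity in inference mode.  Holds its own Generator so a fixed
    construction seed gives a reproducible sequence of masks.
    """

    def __init__(self, drop_prob: float = 0.18, block_size: int = 3, seed: int | None = None):
        super().__init__()
        if not 0.0 <= drop_prob < 1.0:
            raise ValueError(f"drop_prob must be in [0, 1), got {drop_prob}")
        if block_size < 1 or block_size % 2 == 0:
            raise ValueError(f"block_size must be odd and >= 1, got {block_size}")
        self.drop_prob = drop_prob
        self.block_size = block_size
        self.rng = np.random.default_rng(seed)

    def forward(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.drop_prob == 0.0:
            return x
        mask = _dropblock_mask(x.shape, self.drop_prob, self.block_size, rng or self.rng)
        kept = mask.sum()
        scale = mask.size / kept if kept > 0 else 0.0
        return x * Tensor((mask * scale).astype(x.dtype))


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, parameters, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.parameters = list(parameters)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.parameters]
        self.v = [np.zeros_like(p.data) for p in self.parameters]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.parameters, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.parameters:
            p.grad = None
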