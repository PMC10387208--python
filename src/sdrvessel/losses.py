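"""Class-weighted binary cross-entropy and the multi-output total loss.

Per pixel, with prediction p in (0, 1) and label y in {0, 1}:

    WBCE = -[ w1 * y * ln(p) + w2 * (1 - y) * ln(1 - p) ]

averaged over all pixels (mean reduction, so the loss magnitude is
independent of image size).  The four decoder heads give losses
loss1..loss4 (loss1 = final full-resolution head), combined as

    TotalLoss = alpha * (loss2 + loss3 + loss4) + (beta - alpha) * loss1

so auxiliary heads carry weight alpha each and the final head beta - alpha.
Default alpha = 0.125 with beta = 1.0 (DRIVE profile) or 0.9 (STARE profile);
foreground/background weights default to w1 = 0.8, w2 = 0.2, countering the
~10:1 background/vessel class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, clip, log

__all__ = ["LossWeights", "weighted_bce", "multi_output_loss", "total_training_loss", "EPS"]

EPS = 1e-7  # probability clamp away from {0, 1} before logarithms

_BETA_PROFILES = {"drive": 1.0, "stare": 0.9}


@dataclass
class LossWeights:
    alpha: float = 0.125
    beta: float = 1.0
    w1: float = 0.8  # foreground (vessel)
    w2: float = 0.2  # background

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.beta < self.alpha:
            raise ValueError(
                f"beta ({self.beta}) must be >= alpha ({self.alpha}); otherwise the final head is weighted negatively"
            )
        if self.w1 <= 0 or self.w2 <= 0:
            raise ValueError("w1 and w2 must be positive")

    @classmethod
    def for_profile(cls, profile: str, alpha: float = 0.125, w1: float = 0.8, w2: float = 0.2) -> "LossWeights":
        if profile not in _BETA_PROFILES:
            raise ValueError(f"unknown dataset profile {profile!r}; choose from {sorted(_BETA_PROFILES)}")
        return cls(alpha=alpha, beta=_BETA_PROFILES[profile], w1=w1, w2=w2)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def weighted_bce(probabilities, labels, w1: float = 0.8, w2: float = 0.2) -> Tensor:
    """Mean class-weighted binary cross-entropy over all pixels.

    Accepts Tensors or arrays of identical shape; labels must be binary.
    Returns a scalar Tensor (differentiable when inputs carry gradients).
    """
    p = _as_tensor(probabilities)
    y_arr = labels.data if isinstance(labels, Tensor) else np.asarray(labels)
    if p.shape != y_arr.shape:
        raise ValueError(f"shape mismatch: probabilities {p.shape} vs labels {y_arr.shape}")
    if not np.isin(y_arr, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    y = y_arr.astype(p.dtype)
    pc = clip(p, EPS, 1.0 - EPS)
    per_pixel = -(w1 * Tensor(y) * log(pc) + w2 * Tensor(1.0 - y) * log(1.0 - pc))
    return per_pixel.mean()


def multi_output_loss(loss1, loss2, loss3, loss4, alpha: float = 0.125, beta: float = 1.0) -> Tensor:
    """alpha * (loss2 + loss3 + loss4) + (beta - alpha) * loss1."""
    if alpha < 0 or beta < alpha:
        raise ValueError(f"require beta >= alpha >= 0, got alpha={alpha}, beta={beta}")
    l1, l2, l3, l4 = (_as_tensor(v) for v in (loss1, loss2, loss3, loss4))
    return (l2 + l3 + l4) * alpha + l1 * (beta - alpha)


def total_training_loss(outputs, labels, weights: LossWeights = LossWeights()) -> Tensor:
    """Weighted BCE on each of the four heads against the same ground truth,
    combined by the multi-output weighting.

    ``outputs`` is a DecoderOutputs; ``labels`` is a binary map broadcastable
    to each head's (B, 1, H, W) shape.
    """
    y = labels.data if isinstance(labels, Tensor) else np.asarray(labels)
    if y.ndim == 2:
        y = y[None, None]
    elif y.ndim == 3:
        y = y[:, None]
    head_losses = []
    for m in outputs.maps:
        if m.shape != y.shape:
            raise ValueError(f"label shape {y.shape} does not match head output {m.shape}")
        head_losses.append(weighted_bce(m, y, weights.w1, weights.w2))
    return multi_output_loss(*head_losses, alpha=weights.alpha, beta=weights.beta)
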