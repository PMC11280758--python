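"""Composite segmentation objective: CE + Dice + Focal under learnable weights.

The three component losses target complementary failure modes — cross-entropy
treats every pixel equally, soft Dice counteracts class imbalance by scoring
region overlap, and focal loss down-weights easy pixels so training
concentrates on ambiguous boundary regions.  Rather than hand-tuning the
mixture, the three mixing weights are trainable scalars initialised to
(0.3, 0.4, 0.3) and updated by the same optimizer as the network, so the
balance is learned jointly with the model.

All functions accept logits of shape (N, 2, H, W) (or unbatched (2, H, W))
and an integer mask in {0, 1}; the coating is class 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import autodiff as ad
from .nn.autodiff import Tensor


@dataclass
class LossConfig:
    """Hyperparameters of the component losses.

    focal_gamma: focusing exponent; 0 recovers plain cross-entropy.
    focal_alpha: optional weight for the coating class (None disables).
    dice_smooth: additive smoothing in the soft-Dice ratio.
    """

    focal_gamma: float = 2.0
    focal_alpha: float | None = None
    dice_smooth: float = 1.0

    def validate(self) -> None:
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")
        if self.dice_smooth <= 0:
            raise ValueError("dice_smooth must be > 0")
        if self.focal_alpha is not None and not (0.0 <= self.focal_alpha <= 1.0):
            raise ValueError("focal_alpha must lie in [0, 1]")


class LossWeights(nn.Module):
    """Three trainable scalars mixing CE / Dice / Focal.

    Because the total is linear in the weights, the gradient each weight
    receives is its component's (non-negative) value, so raw weights under
    gradient descent decrease monotonically, cross zero and then make the
    objective unbounded below.  The default ``simplex`` constraint therefore
    parametrizes the weights through a softmax (scaled to preserve the sum
    of the initial values), which keeps them positive and the mixture a
    convex combination while remaining fully trainable.  ``constraint=
    "none"`` exposes the raw linear form for analysis.
    """

    INIT = (0.3, 0.4, 0.3)

    def __init__(self, constraint: str = "simplex"):
        super().__init__()
        if constraint not in ("simplex", "none"):
            raise ValueError(f"unknown constraint {constraint!r}")
        self.constraint = constraint
        if constraint == "none":
            self.w1 = nn.Parameter(np.array(self.INIT[0]))
            self.w2 = nn.Parameter(np.array(self.INIT[1]))
            self.w3 = nn.Parameter(np.array(self.INIT[2]))
        else:
            self.scale = float(sum(self.INIT))
            self.theta = nn.Parameter(np.log(np.asarray(self.INIT) / self.scale))

    def weight_tensors(self) -> tuple[Tensor, Tensor, Tensor]:
        """The three mixing weights as live graph tensors."""
        if self.constraint == "none":
            return (self.w1, self.w2, self.w3)
        w = ad.softmax(self.theta, axis=0) * self.scale
        return (w[0], w[1], w[2])

    def values(self) -> tuple[float, float, float]:
        w1, w2, w3 = self.weight_tensors()
        return (float(w1.data), float(w2.data), float(w3.data))


def _check_target(target: np.ndarray) -> np.ndarray:
    target = np.asarray(target)
    if not np.isin(target, (0, 1)).all():
        raise ValueError("target mask must be binary {0, 1}")
    return target.astype(np.int64)


def _batched(logits: Tensor, target: np.ndarray):
    if logits.ndim == 3:
        logits = logits.reshape(1, *logits.shape)
        target = target[None]
    if logits.ndim != 4 or logits.shape[1] != 2:
        raise ValueError(f"expected (N, 2, H, W) logits, got {logits.shape}")
    if logits.shape[0] != target.shape[0] or logits.shape[2:] != target.shape[1:]:
        raise ValueError("logits and target shapes are inconsistent")
    return logits, target


def _one_hot(target: np.ndarray) -> np.ndarray:
    n, h, w = target.shape
    oh = np.zeros((n, 2, h, w), dtype=np.float32)
    oh[:, 1][target == 1] = 1.0
    oh[:, 0][target == 0] = 1.0
    return oh


def ce_loss(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean per-pixel cross-entropy."""
    target = _check_target(target)
    logits, target = _batched(ad.as_tensor(logits), target)
    ls = ad.log_softmax(logits, axis=1)
    picked = (ls * Tensor(_one_hot(target))).sum(axis=1)
    return -picked.mean()


def dice_loss(
    prob: Tensor, target: np.ndarray, cfg: LossConfig | None = None
) -> Tensor:
    """Soft Dice on the coating channel: 1 - (2*sum(p*t)+s)/(sum(p)+sum(t)+s).

    ``prob`` is the coating probability map (values in [0, 1]); a full
    (N, 2, H, W) probability tensor is also accepted, channel 1 is used.
    """
    cfg = cfg or LossConfig()
    cfg.validate()
    target = _check_target(target)
    prob = ad.as_tensor(prob)
    if prob.ndim == 4 and prob.shape[1] == 2:
        prob = prob[:, 1]
    if prob.ndim == target.ndim - 1 and target.shape[0] == 1:
        target = target[0]
    if prob.shape != target.shape:
        raise ValueError("prob and target shapes differ")
    if prob.data.min() < -1e-6 or prob.data.max() > 1 + 1e-6:
        raise ValueError("prob must lie in [0, 1]")
    t = Tensor(target.astype(np.float32))
    inter = (prob * t).sum()
    denom = prob.sum() + t.sum()
    return 1.0 - (2.0 * inter + cfg.dice_smooth) / (denom + cfg.dice_smooth)


def focal_loss(
    logits: Tensor, target: np.ndarray, cfg: LossConfig | None = None
) -> Tensor:
    """Mean of (1 - p_true)^gamma * (-log p_true), optionally alpha-balanced."""
    cfg = cfg or LossConfig()
    cfg.validate()
    target = _check_target(target)
    logits, target = _batched(ad.as_tensor(logits), target)
    ls = ad.log_softmax(logits, axis=1)
    oh = Tensor(_one_hot(target))
    log_p_true = (ls * oh).sum(axis=1)
    p_true = ad.exp(log_p_true)
    modulator = (1.0 - p_true) ** cfg.focal_gamma if cfg.focal_gamma != 0 else 1.0
    per_pixel = modulator * (-log_p_true)
    if cfg.focal_alpha is not None:
        alpha_map = np.where(target == 1, cfg.focal_alpha, 1.0 - cfg.focal_alpha)
        per_pixel = per_pixel * Tensor(alpha_map.astype(np.float32))
    return per_pixel.mean()


def combined_loss(
    logits: Tensor,
    target: np.ndarray,
    weights: LossWeights,
    cfg: LossConfig | None = None,
    return_parts: bool = False,
):
    """w1*CE + w2*Dice + w3*Focal with the w_i live in the graph.

    Because the total is linear in each w_i, dLoss/dw_i equals the i-th
    component's value — the weights receive exactly that gradient signal.
    """
    cfg = cfg or LossConfig()
    ce = ce_loss(logits, target)
    prob = ad.softmax(ad.as_tensor(logits), axis=1 if ad.as_tensor(logits).ndim == 4 else 0)
    dice = dice_loss(prob if prob.ndim == 4 else prob[1], target, cfg)
    focal = focal_loss(logits, target, cfg)
    w1, w2, w3 = weights.weight_tensors()
    total = w1 * ce + w2 * dice + w3 * focal
    if return_parts:
        return total, {"ce": ce, "dice": dice, "focal": focal}
    return total
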