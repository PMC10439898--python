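"""The joint multi-task objective.

Segmentation path: soft Dice (class-averaged overlap) plus cross-entropy,
combined as  L_seg = lambda1 * CE + lambda2 * Dice  with lambda1 = 1,
lambda2 = 1.5.  Regression path: MSE over the 11 indices plus binary
cross-entropy on the phase,  L_reg = MSE + BCE.  The unified objective is

    L = lambda3 * L_seg + lambda4 * L_reg,   lambda3 = 4, lambda4 = 1,

weighting the segmentation task higher because the regression path feeds on
its features.  All functions accept numpy arrays or autodiff Tensors and
return a scalar Tensor, so gradients flow to both paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, softmax

__all__ = ["LossWeights", "soft_dice_loss", "cross_entropy_loss", "seg_loss",
           "bce_loss", "mse_loss", "reg_loss", "unified_loss",
           "phase_probability"]

EPS_DICE = 1e-5     # symmetric smoothing in the per-class overlap ratio
# probability floor inside logarithms; must stay representable next to 1.0
# in float32, where 1 - 1e-12 rounds back to exactly 1
FLOOR = 1e-7


@dataclass
class LossWeights:
    """Weights of the joint objective (all strictly positive)."""

    lambda1: float = 1.0    # cross-entropy weight inside the segmentation loss
    lambda2: float = 1.5    # Dice weight inside the segmentation loss
    lambda3: float = 4.0    # segmentation-path weight in the unified loss
    lambda4: float = 1.0    # regression-path weight in the unified loss

    def __post_init__(self):
        if min(self.lambda1, self.lambda2, self.lambda3, self.lambda4) <= 0:
            raise ValueError("loss weights must be positive")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _check_probs(probs: Tensor, target: Tensor):
    if probs.shape != target.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs target {target.shape}")
    if probs.ndim < 2:
        raise ValueError("expected (batch, classes, ...) layout")


def soft_dice_loss(probs, target) -> Tensor:
    """1 minus the class-averaged soft overlap; in [0, 1].

    `probs` are per-class probability maps and `target` one-hot maps, both
    laid out (batch, classes, ...).  Overlap sums pool over batch and pixels.
    """
    p, y = _as_tensor(probs), _as_tensor(target)
    _check_probs(p, y)
    k = p.shape[1]
    axes = tuple(i for i in range(p.ndim) if i != 1)
    num = (p * y).sum(axis=axes)                 # (K,)
    den = (p + y).sum(axis=axes)
    dice_per_class = (2.0 * num + EPS_DICE) / (den + EPS_DICE)
    return 1.0 - dice_per_class.sum() * (1.0 / k)


def cross_entropy_loss(probs, target) -> Tensor:
    """Mean pixelwise cross-entropy  -(1/N) sum_i sum_c y_ic log p_ic."""
    p, y = _as_tensor(probs), _as_tensor(target)
    _check_probs(p, y)
    n = p.data.size / p.shape[1]    # pixels (x batch), not counting classes
    return -(y * p.clip(FLOOR, 1.0).log()).sum() * (1.0 / n)


def seg_loss(probs, target, weights: LossWeights | None = None) -> Tensor:
    w = weights or LossWeights()
    return w.lambda1 * cross_entropy_loss(probs, target) \
        + w.lambda2 * soft_dice_loss(probs, target)


def bce_loss(phase_prob, phase_target) -> Tensor:
    """Mean binary cross-entropy over the batch (probabilities floored)."""
    p, y = _as_tensor(phase_prob), _as_tensor(phase_target)
    if p.shape != y.shape:
        raise ValueError("phase probability / target shape mismatch")
    pc = p.clip(FLOOR, 1.0 - FLOOR)
    n = max(p.data.size, 1)
    return -(y * pc.log() + (1.0 - y) * (1.0 - pc).log()).sum() * (1.0 / n)


def mse_loss(pred_indices, target_indices) -> Tensor:
    """Mean squared error over all samples and all 11 indices jointly."""
    p, y = _as_tensor(pred_indices), _as_tensor(target_indices)
    if p.shape != y.shape:
        raise ValueError("index shape mismatch")
    if p.shape[-1] != 11:
        raise ValueError(f"expected 11 indices per sample, got {p.shape[-1]}")
    d = p - y
    return (d * d).sum() * (1.0 / p.data.size)


def reg_loss(pred_indices, target_indices, phase_prob, phase_target) -> Tensor:
    """Regression-path loss: MSE on indices + BCE on phase (unit weights)."""
    return mse_loss(pred_indices, target_indices) + bce_loss(phase_prob, phase_target)


def unified_loss(seg_term, reg_term, weights: LossWeights | None = None) -> Tensor:
    """lambda3 * L_seg + lambda4 * L_reg (defaults 4 and 1)."""
    w = weights or LossWeights()
    return w.lambda3 * _as_tensor(seg_term) + w.lambda4 * _as_tensor(reg_term)


def phase_probability(phase_logits) -> Tensor:
    """Probability of systole from the 2-neuron phase head, shape (B,)."""
    logits = _as_tensor(phase_logits)
    return softmax(logits, axis=-1)[:, 1]
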