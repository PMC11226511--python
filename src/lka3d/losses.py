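"""Training losses: class-weighted soft Dice and BCE + Dice.

The weighted soft Dice loss drives multi-organ training, with per-class
weights of one minus the foreground/background voxel ratio (rare classes
get weight near 1, dominant ones are shrunk toward 0).  Region-channel
training (nested tumor regions with sigmoid heads) uses the sum of binary
cross-entropy and an unweighted soft Dice loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import warnings

import numpy as np

from .nn import Tensor, as_tensor

__all__ = [
    "ClassWeights",
    "class_weights_from_labels",
    "soft_dice_loss",
    "bce_dice_loss",
    "deep_supervision_weights",
]

EPS = 1e-5


@dataclass(frozen=True)
class ClassWeights:
    """One weight in [0, 1] per foreground class, ordered by class index."""

    weights: tuple[float, ...]

    def __post_init__(self):
        if any(not (0.0 <= w <= 1.0) for w in self.weights):
            raise ValueError(f"class weights must lie in [0, 1]: {self.weights}")

    def __len__(self):
        return len(self.weights)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=np.float32)


def class_weights_from_labels(labels, n_classes: int) -> ClassWeights:
    """Dataset-level weights 1 - (foreground voxels / background voxels).

    ``labels`` is an iterable of integer volumes with 0 = background and
    classes 1..n_classes-1 as foreground.  Ratios are clamped to [0, 1];
    a class absent from every volume gets weight 1 with a warning.
    """
    fg = np.zeros(n_classes, dtype=np.int64)
    bg = 0
    for lab in labels:
        lab = np.asarray(lab)
        counts = np.bincount(lab.ravel(), minlength=n_classes)
        fg += counts
        bg += int(counts[0])
    ws = []
    for c in range(1, n_classes):
        if fg[c] == 0:
            warnings.warn(f"class {c} absent from all label volumes; weight set to 1")
            ws.append(1.0)
        else:
            ws.append(float(np.clip(1.0 - fg[c] / max(bg, 1), 0.0, 1.0)))
    return ClassWeights(tuple(ws))


def _per_class_soft_dice(probs: Tensor, target: Tensor) -> Tensor:
    """Soft Dice per class: (2 sum(p t) + eps) / (sum p + sum t + eps).

    Inputs are (N, C, D, H, W); returns a length-C tensor, sums taken over
    batch and space.
    """
    axes = (0, 2, 3, 4)
    inter = (probs * target).sum(axis=axes)
    denom = probs.sum(axis=axes) + target.sum(axis=axes)
    return (2.0 * inter + EPS) / (denom + EPS)


def soft_dice_loss(probs, target, weights: ClassWeights,
                   include_background: bool = False) -> Tensor:
    """Weighted soft Dice loss over foreground classes.

    1 - sum_c w_c * softDice_c / sum_c w_c.  ``probs`` are post-softmax
    class probabilities (N, C, D, H, W); ``target`` is one-hot of the same
    shape.  Background (channel 0) is excluded unless requested.
    """
    probs, target = as_tensor(probs), as_tensor(target)
    if probs.shape != target.shape:
        raise ValueError(f"shape mismatch: {probs.shape} vs {target.shape}")
    n_fg = probs.shape[1] - (0 if include_background else 1)
    if len(weights) != n_fg:
        raise ValueError(
            f"{len(weights)} weights for {n_fg} loss classes"
        )
    if not include_background:
        probs = probs.narrow(1, 1, n_fg)
        target = target.narrow(1, 1, n_fg)
    dice = _per_class_soft_dice(probs, target)
    w = Tensor(weights.as_array())
    wsum = float(weights.as_array().sum())
    if wsum == 0.0:
        raise ValueError("all class weights are zero")
    return 1.0 - (dice * w).sum() * (1.0 / wsum)


def bce_dice_loss(probs, target) -> Tensor:
    """Mean binary cross-entropy plus unweighted soft Dice loss.

    For per-channel sigmoid probabilities over region channels
    (N, C, D, H, W) and binary targets of the same shape; the two terms
    are weighted 1:1.
    """
    probs, target = as_tensor(probs), as_tensor(target)
    if probs.shape != target.shape:
        raise ValueError(f"shape mismatch: {probs.shape} vs {target.shape}")
    p = probs.clip(1e-7, 1.0 - 1e-7)
    bce = -(target * p.log() + (1.0 - target) * (1.0 - p).log()).mean()
    dice = _per_class_soft_dice(probs, target)
    dice_loss = 1.0 - dice.mean()
    return bce + dice_loss


def deep_supervision_weights(n_heads: int) -> np.ndarray:
    """Geometric head weights 1, 1/2, 1/4, ... normalised to sum to one."""
    w = 0.5 ** np.arange(n_heads)
    return (w / w.sum()).astype(np.float32)
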