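"""Soft Dice loss and the composite fusion-network loss.

The single-network objective is the soft Dice loss

    L(p, g) = 1 - (2 * sum(p*g) + s) / (sum(p) + sum(g) + s)

with smoothing constant ``s`` guarding the empty-mask 0/0 case.  The fusion
network is trained with a weighted composite: one Dice term per phase-specific
sub-network, weighted by alpha_i, plus a Dice term on the fused output,

    L_total = sum_i alpha_i * L(p_i, g) + L(p_out, g).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["dice_loss", "dice_loss_grad", "CompositeLossBreakdown", "composite_loss", "binarize"]


def _check_pair(pred: np.ndarray, target: np.ndarray) -> None:
    if pred.shape != target.shape:
        raise ValueError(f"pred shape {pred.shape} != target shape {target.shape}")


def dice_loss(pred: np.ndarray, target: np.ndarray, smooth: float = 1.0) -> float:
    """Soft Dice loss between a probability map and a binary target.

    Both arguments may be a single map or a batch; the loss is computed over
    all elements jointly.  Returns a value in ``[0, 1]`` for ``smooth >= 0``.
    """
    _check_pair(pred, target)
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    num = 2.0 * float((pred * target).sum()) + smooth
    den = float(pred.sum()) + float(target.sum()) + smooth
    if den == 0.0:
        return 0.0  # both empty, smooth == 0: perfect agreement
    return 1.0 - num / den


def dice_loss_grad(pred: np.ndarray, target: np.ndarray,
                   smooth: float = 1.0) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to ``pred``.

    d/dp_j [1 - (2*sum(pt)+s)/(sum p + sum g + s)] =
        (num - 2 * t_j * den) / den**2  with num/den as in :func:`dice_loss`.
    """
    _check_pair(pred, target)
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    num = 2.0 * float((p * t).sum()) + smooth
    den = float(p.sum()) + float(t.sum()) + smooth
    if den == 0.0:
        return 0.0, np.zeros_like(p)
    grad = (num - 2.0 * t * den) / (den * den)
    return 1.0 - num / den, grad


@dataclass(frozen=True)
class CompositeLossBreakdown:
    """Per-term values of the composite fusion loss."""

    subnet_losses: tuple[float, ...]
    fusion_loss: float
    total: float


def composite_loss(gt: np.ndarray, sub_maps: Sequence[np.ndarray], fused: np.ndarray,
                   alphas: Sequence[float], smooth: float = 1.0) -> CompositeLossBreakdown:
    """Weighted composite loss: ``sum_i alpha_i * L_i + L_fusion``."""
    alphas = tuple(float(a) for a in alphas)
    if len(alphas) != len(sub_maps):
        raise ValueError("one alpha per sub-network required")
    if any(a < 0 for a in alphas):
        raise ValueError("loss weights alpha must be non-negative")
    subs = tuple(dice_loss(m, gt, smooth) for m in sub_maps)
    fusion = dice_loss(fused, gt, smooth)
    total = sum(a * l for a, l in zip(alphas, subs)) + fusion
    return CompositeLossBreakdown(subnet_losses=subs, fusion_loss=fusion, total=total)


def binarize(score_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a score map into a binary mask (``>=`` convention)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return (np.asarray(score_map) >= threshold).astype(np.uint8)
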