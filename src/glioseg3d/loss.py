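"""Compound Dice(Tversky-form) + Focal training objective.

Per class b over all N voxels the soft counts are
TP = sum p*g, FN = sum (1-p)*g, FP = sum p*(1-g); the Dice part is
B - sum_b TP/(TP + alpha*FN + beta*FP) and the Focal part is
-(lambda/N) * sum_b sum_n g*(1-p)^2*log(p).  With alpha = beta = 0.5 the
Dice part reduces to the standard soft-Dice loss; both parts are
non-negative, so the total vanishes only at a perfect prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .volumes import InvalidInputError, InvalidSpecError

_P_CLAMP = 1e-7


@dataclass
class LossConfig:
    alpha: float = 0.5   # false-negative weight
    beta: float = 0.5    # false-positive weight
    lam: float = 1.0     # Focal-term weight
    eps: float = 1e-6    # denominator guard
    log_base: str = "e"  # "e" (natural log, standard for Focal loss) or "10"

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.lam < 0:
            raise InvalidSpecError("alpha, beta and lam must be non-negative")
        if self.alpha + self.beta <= 0:
            raise InvalidSpecError("alpha + beta must be positive")
        if self.eps <= 0:
            raise InvalidSpecError("eps must be positive")
        if self.log_base not in ("e", "10"):
            raise InvalidSpecError("log_base must be 'e' or '10'")


@dataclass
class SoftCounts:
    """Per-class soft confusion counts; tp + fn = sum(g), tp + fp = sum(p)."""

    tp: np.ndarray
    fn: np.ndarray
    fp: np.ndarray


def _validate(p: np.ndarray, g: np.ndarray, tol: float = 1e-3) -> None:
    if p.shape != g.shape:
        raise InvalidInputError(f"probability shape {p.shape} != one-hot shape {g.shape}")
    if p.ndim < 2:
        raise InvalidInputError("expected (B, ...) class-first arrays")
    if np.min(p) < -tol or np.max(p) > 1 + tol:
        raise InvalidInputError("probabilities must lie in [0, 1]")
    sums = p.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=tol):
        raise InvalidInputError("per-voxel class probabilities must sum to 1")
    g_sums = g.sum(axis=0)
    if not (np.allclose(g_sums, 1.0) and np.isin(g, (0, 1)).all()):
        raise InvalidInputError("g must be one-hot over the class axis")


def soft_counts(p: np.ndarray, g: np.ndarray) -> SoftCounts:
    """Soft TP/FN/FP per class (class axis first)."""
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    _validate(p, g)
    axes = tuple(range(1, p.ndim))
    tp = (p * g).sum(axis=axes)
    fn = ((1.0 - p) * g).sum(axis=axes)
    fp = (p * (1.0 - g)).sum(axis=axes)
    return SoftCounts(tp=tp, fn=fn, fp=fp)


def combined_loss_tensor(p: Tensor, g: np.ndarray, cfg: LossConfig | None = None) -> Tensor:
    """Differentiable loss on a probability Tensor (class axis first).

    ``g`` is a constant one-hot array of the same shape.
    """
    cfg = cfg or LossConfig()
    g = np.asarray(g, dtype=p.data.dtype)
    num_classes = p.shape[0]
    n_vox = int(np.prod(p.shape[1:]))
    axes = tuple(range(1, p.ndim))

    gt = Tensor(g)
    tp = (p * gt).sum(axis=axes)
    fn = ((1.0 - p) * gt).sum(axis=axes)
    fp = (p * (1.0 - gt)).sum(axis=axes)
    dice_terms = tp / (tp + cfg.alpha * fn + cfg.beta * fp + cfg.eps)
    loss_dice = float(num_classes) - dice_terms.sum()

    p_safe = p.clip(_P_CLAMP, 1.0 - _P_CLAMP)
    log_p = p_safe.log()
    if cfg.log_base == "10":
        log_p = log_p * (1.0 / math.log(10.0))
    focal_sum = (gt * (1.0 - p) ** 2.0 * log_p).sum()
    loss_focal = -(cfg.lam / float(n_vox)) * focal_sum
    return loss_dice + loss_focal


def combined_loss(p: np.ndarray, g: np.ndarray, cfg: LossConfig | None = None) -> float:
    """Scalar loss on plain arrays (validates inputs)."""
    p_arr = np.asarray(p, dtype=np.float64)
    g_arr = np.asarray(g, dtype=np.float64)
    _validate(p_arr, g_arr)
    return combined_loss_tensor(Tensor(p_arr), g_arr, cfg).item()


def one_hot(labels_internal: np.ndarray, num_classes: int) -> np.ndarray:
    """One-hot encode internal labels {0..C-1}; output (C, *labels.shape)."""
    lab = np.asarray(labels_internal)
    if lab.min() < 0 or lab.max() >= num_classes:
        raise InvalidInputError(
            f"labels out of range [0, {num_classes - 1}]: "
            f"{sorted(set(np.unique(lab)) - set(range(num_classes)))}"
        )
    eye = np.eye(num_classes, dtype=np.float32)
    return np.moveaxis(eye[lab], -1, 0)
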