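"""Penalty-reduced pixel-wise logistic focal loss.

For a target heatmap ``Y`` with exact-1 pixels at cell centres and a
Gaussian-weighted neighbourhood elsewhere,

    L = -(1/N) * sum_xyc [ (1 - p)^alpha * log(p)               if Y = 1
                           (1 - Y)^beta * p^alpha * log(1 - p)  otherwise ]

where ``p`` is the predicted probability, ``N`` the number of centre pixels
(clamped to >= 1) and the ``(1 - Y)^beta`` factor reduces the background
penalty near centres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ValidationError


@dataclass
class LossConfig:
    alpha: float = 2.0
    beta: float = 2.0
    clamp_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValidationError("alpha and beta must be >= 0")


def focal_loss(
    pred: np.ndarray,
    target: np.ndarray,
    cfg: LossConfig | None = None,
    return_grad: bool = False,
) -> float | tuple[float, np.ndarray]:
    """Evaluate the loss (and optionally its gradient w.r.t. ``pred``).

    ``pred`` and ``target`` may be any matching-shape arrays (heatmap
    tensors, batches, or scalars); the sum runs over all elements.
    """
    cfg = cfg or LossConfig()
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValidationError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    eps = cfg.clamp_epsilon
    p = np.clip(pred, eps, 1.0 - eps)
    pos = target == 1.0
    n = max(int(pos.sum()), 1)
    a, b = cfg.alpha, cfg.beta

    log_p = np.log(p)
    log_1p = np.log1p(-p)
    pos_term = (1.0 - p) ** a * log_p
    neg_term = (1.0 - target) ** b * p**a * log_1p
    loss = -(pos_term[pos].sum() + neg_term[~pos].sum()) / n
    if not return_grad:
        return float(loss)

    # d/dp of each branch; the clamp is treated as pass-through
    dpos = -a * (1.0 - p) ** (a - 1.0) * log_p + (1.0 - p) ** a / p
    dneg = (1.0 - target) ** b * (a * p ** (a - 1.0) * log_1p - p**a / (1.0 - p))
    grad = np.where(pos, dpos, dneg) * (-1.0 / n)
    return float(loss), grad


def focal_loss_heatmaps(pred_hm, target_hm, cfg: LossConfig | None = None) -> float:
    """Convenience wrapper over two ``HeatmapTensor`` objects."""
    return focal_loss(pred_hm.values, target_hm.values, cfg)
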