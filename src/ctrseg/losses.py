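"""Training losses and the Gaussian ramp-up schedule.

The supervised loss pairs pixel-mean binary cross-entropy with Dice loss,
averaged over the labeled part of the batch.  The unsupervised
(consistency) loss is the mean over auxiliary predictions of the
per-image pixel *sum* of squared differences between the main decoder's
output and each perturbed auxiliary output.  The total loss is

    L = L_S + w_U(t) * L_U

where w_U ramps from ~0 to 1 over the first ``ramp_length`` epochs as
exp(-5 (1 - t/L)^2) and is 1 afterwards.

The literal pixel sum in the consistency distance makes L_U scale with
image area while L_S does not; ``unsupervised_loss(pixel_mean=True)``
optionally normalises by W*H.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

BCE_EPS = 1e-7
DICE_EPS = 1e-6


@dataclass
class LossTerms:
    supervised: float
    unsupervised: float
    weight: float
    total: float


def bce(y: np.ndarray, p: np.ndarray, eps: float = BCE_EPS) -> float:
    """Pixel-mean binary cross-entropy; probabilities clipped to [eps, 1-eps]."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {p.shape}")
    pc = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))


def dice_loss(y: np.ndarray, p: np.ndarray, eps: float = DICE_EPS) -> float:
    """1 - (2 Σyp + ε) / (Σy + Σp + ε)."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {p.shape}")
    num = 2.0 * float(np.sum(y * p)) + eps
    den = float(np.sum(y)) + float(np.sum(p)) + eps
    return 1.0 - num / den


def supervised_loss(pairs) -> float:
    """Mean of bce + dice over a batch of (mask, probability-map) pairs."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty batch")
    return float(
        np.mean([bce(y, p) + dice_loss(y, p) for y, p in pairs])
    )


def unsupervised_loss(main, aux, k: int | None = None,
                      pixel_mean: bool = False) -> float:
    """Consistency MSE between main outputs and k auxiliary outputs each.

    ``main`` is a sequence of bs_u probability maps; ``aux`` a sequence of
    bs_u lists of k maps.  Returns
    (1 / (k * bs_u)) * Σ_j Σ_p Σ_pixels (main_j - aux_jp)^2 — the inner
    sum runs over pixels (optionally a pixel mean instead).  Main outputs
    are plain targets here; gradient routing is the trainer's concern.
    """
    main = [np.asarray(m, dtype=float) for m in main]
    aux = [[np.asarray(a, dtype=float) for a in row] for row in aux]
    if not main or len(aux) != len(main):
        raise ValueError("aux rows must match main outputs")
    if k is None:
        k = len(aux[0])
    bs_u = len(main)
    total = 0.0
    for m, row in zip(main, aux):
        if len(row) != k:
            raise ValueError("ragged auxiliary list")
        for a in row:
            if a.shape != m.shape:
                raise ValueError("aux/main shape mismatch")
            d = float(np.sum((m - a) ** 2))
            if pixel_mean:
                d /= m.size
            total += d
    return total / (k * bs_u)


def rampup_weight(t: float, L: int) -> float:
    """Gaussian ramp-up: exp(-5 (1 - t/L)^2) for t < L, else 1."""
    if t < 0 or L < 1:
        raise ValueError("require t >= 0 and L >= 1")
    if t >= L:
        return 1.0
    return math.exp(-5.0 * (1.0 - t / L) ** 2)


def total_loss(supervised: float, unsupervised: float,
               t: float, L: int) -> LossTerms:
    """Combine the two loss terms with the ramp-up weight at epoch t."""
    w = rampup_weight(t, L)
    return LossTerms(
        supervised=float(supervised),
        unsupervised=float(unsupervised),
        weight=w,
        total=float(supervised) + w * float(unsupervised),
    )
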