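"""Stochastic perturbations of latent representations.

Cross-consistency training feeds the auxiliary decoder *perturbed*
versions of the latent representation of each unlabeled image and
penalises disagreement with the main decoder.  Three perturbations are
used, in this fixed order:

* **F-Noise** — multiplicative uniform noise:  z' = z + z ⊙ N with
  N ~ U(-0.3, 0.3) sampled elementwise.
* **F-Drop** — threshold masking of the most active regions: the
  channel-mean of z is min-max normalised to [0, 1] per sample, a
  threshold γ ~ U(0.6, 0.9) is drawn, and positions whose normalised
  mean is ≤ γ are zeroed across all channels (so only the most active
  regions *survive*; ``invert=True`` drops them instead, the convention
  of the original cross-consistency scheme).
* **Dropout** — elementwise zeroing with a uniformly sampled rate
  r ~ U(0.1, 0.7); survivors are unscaled by default
  (``rescale=True`` applies inverted scaling 1/(1-r)).

All functions are pure in (z, rng): they never modify their input, and a
fixed generator state makes them deterministic.  ``*_vjp`` variants also
return the vector-Jacobian product used for backpropagation.  Arrays may
be a single latent or a batch; ``channel_axis`` locates the channel
dimension (default -1 for an H×W×C latent; the trainer passes 1 for
NCHW batches with ``batch_axis=0``, which draws γ and r per sample).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NOISE_RANGE = (-0.3, 0.3)
GAMMA_RANGE = (0.6, 0.9)
DROPOUT_RANGE = (0.1, 0.7)


@dataclass(frozen=True)
class PerturbationParams:
    noise_low: float = NOISE_RANGE[0]
    noise_high: float = NOISE_RANGE[1]
    gamma_low: float = GAMMA_RANGE[0]
    gamma_high: float = GAMMA_RANGE[1]
    dropout_low: float = DROPOUT_RANGE[0]
    dropout_high: float = DROPOUT_RANGE[1]
    k: int = 3
    fdrop_invert: bool = False
    dropout_rescale: bool = False

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")


def f_noise_vjp(z, rng, low=NOISE_RANGE[0], high=NOISE_RANGE[1]):
    z = np.asarray(z)
    n = rng.uniform(low, high, size=z.shape).astype(z.dtype, copy=False)
    out = z + z * n
    return out, lambda g: g * (1.0 + n)


def f_noise(z, rng, low=NOISE_RANGE[0], high=NOISE_RANGE[1]):
    """z + z ⊙ N, N ~ U(low, high) elementwise."""
    return f_noise_vjp(z, rng, low, high)[0]


def _fdrop_mask(z, gamma, channel_axis, invert):
    ztil = z.mean(axis=channel_axis)
    lo, hi = ztil.min(), ztil.max()
    if hi > lo:
        ztil = (ztil - lo) / (hi - lo)
    else:
        # constant latent: min-max normalisation undefined -> everything
        # falls below the threshold and is dropped
        ztil = np.zeros_like(ztil)
    keep = ztil <= gamma if invert else ztil > gamma
    return np.expand_dims(keep, axis=channel_axis).astype(z.dtype)


def f_drop_vjp(z, rng, low=GAMMA_RANGE[0], high=GAMMA_RANGE[1],
               channel_axis=-1, batch_axis=None, invert=False):
    z = np.asarray(z)
    if batch_axis is None:
        gamma = rng.uniform(low, high)
        mask = _fdrop_mask(z, gamma, channel_axis, invert)
    else:
        masks = []
        for zi in np.moveaxis(z, batch_axis, 0):
            gamma = rng.uniform(low, high)
            ca = channel_axis - 1 if channel_axis > batch_axis else channel_axis
            masks.append(_fdrop_mask(zi, gamma, ca, invert))
        mask = np.moveaxis(np.stack(masks, axis=0), 0, batch_axis)
    return z * mask, lambda g: g * mask


def f_drop(z, rng, low=GAMMA_RANGE[0], high=GAMMA_RANGE[1],
           channel_axis=-1, batch_axis=None, invert=False):
    """Mask positions by thresholding the normalised channel-mean at γ."""
    return f_drop_vjp(z, rng, low, high, channel_axis, batch_axis, invert)[0]


def rand_dropout_vjp(z, rng, low=DROPOUT_RANGE[0], high=DROPOUT_RANGE[1],
                     batch_axis=None, rescale=False):
    z = np.asarray(z)
    if batch_axis is None:
        r = rng.uniform(low, high)
        mask = (rng.random(z.shape) >= r).astype(z.dtype)
        if rescale:
            mask = mask / (1.0 - r)
    else:
        parts = []
        for zi in np.moveaxis(z, batch_axis, 0):
            r = rng.uniform(low, high)
            mi = (rng.random(zi.shape) >= r).astype(z.dtype)
            if rescale:
                mi = mi / (1.0 - r)
            parts.append(mi)
        mask = np.moveaxis(np.stack(parts, axis=0), 0, batch_axis)
    return z * mask, lambda g: g * mask


def rand_dropout(z, rng, low=DROPOUT_RANGE[0], high=DROPOUT_RANGE[1],
                 batch_axis=None, rescale=False):
    """Elementwise dropout with rate r ~ U(low, high)."""
    return rand_dropout_vjp(z, rng, low, high, batch_axis, rescale)[0]


_ORDER = ("noise", "drop", "dropout")


def perturbation_names(k: int) -> list:
    """Cycle [noise, drop, dropout] out to length k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return [_ORDER[i % 3] for i in range(k)]


def apply_perturbation_vjp(name: str, z, rng, params: PerturbationParams,
                           channel_axis=-1, batch_axis=None):
    if name == "noise":
        return f_noise_vjp(z, rng, params.noise_low, params.noise_high)
    if name == "drop":
        return f_drop_vjp(z, rng, params.gamma_low, params.gamma_high,
                          channel_axis, batch_axis, params.fdrop_invert)
    if name == "dropout":
        return rand_dropout_vjp(z, rng, params.dropout_low,
                                params.dropout_high, batch_axis,
                                params.dropout_rescale)
    raise ValueError(f"unknown perturbation {name!r}")


def make_perturbation_set(params: PerturbationParams, rng,
                          channel_axis=-1, batch_axis=None):
    """Ordered list of k callables z -> perturbed z (fresh draws per call)."""
    names = perturbation_names(params.k)
    return [
        (lambda z, _n=n: apply_perturbation_vjp(
            _n, z, rng, params, channel_axis, batch_axis)[0])
        for n in names
    ]
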