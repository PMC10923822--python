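"""From probability maps to a cardiothoracic ratio and a screening call.

The detection head is purely geometric: binarize each organ's
probability map, keep the plausible connected components (one for the
heart, up to two lung fields), take the tightest axis-aligned bounding
box of each mask, and form

    CTR = heart box width / lungs box width.

The image is called *cardiomegaly* when CTR strictly exceeds the
protocol threshold π (0.50 by default; 0.55 under the stricter reading
protocol) and *normal* otherwise.  Boxes use 0-based inclusive pixel
indices, so width = x_max - x_min + 1.

An image whose post-processed heart or lungs mask is empty is reported
as indeterminate rather than silently classified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .evalmetrics import CARDIOMEGALY, NORMAL

DEFAULT_PI = 0.50
BINARIZE_THRESHOLD = 0.5
MIN_COMPONENT_FRAC = 0.001  # discard specks below 0.1% of image area


class EmptyMaskError(ValueError):
    """No usable foreground after binarization and component selection."""


@dataclass(frozen=True)
class BoundingBox:
    x_min: int
    x_max: int
    y_min: int
    y_max: int

    def __post_init__(self):
        if self.x_min > self.x_max or self.y_min > self.y_max:
            raise ValueError("degenerate bounding box")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min + 1

    @property
    def height(self) -> int:
        return self.y_max - self.y_min + 1

    def as_dict(self) -> dict:
        return {"x_min": self.x_min, "x_max": self.x_max,
                "y_min": self.y_min, "y_max": self.y_max}


@dataclass
class CTRResult:
    ctr: float | None
    pi: float
    label: str | None
    heart_box: BoundingBox | None
    lungs_box: BoundingBox | None
    valid: bool
    status: str = "ok"


def binarize_and_select(p: np.ndarray, organ: str,
                        threshold: float = BINARIZE_THRESHOLD,
                        min_component_frac: float = MIN_COMPONENT_FRAC
                        ) -> np.ndarray:
    """Threshold a probability map and keep the organ's main component(s).

    Heart keeps the single largest connected component, lungs the union
    of the two largest; components smaller than ``min_component_frac``
    of the image area are discarded first.
    """
    if organ not in ("heart", "lungs"):
        raise ValueError(f"organ must be heart or lungs, got {organ!r}")
    p = np.asarray(p)
    binary = p > threshold
    labels = measure.label(binary, connectivity=2)
    if labels.max() == 0:
        raise EmptyMaskError("no foreground after thresholding")
    areas = np.bincount(labels.ravel())[1:]
    min_area = min_component_frac * p.size
    keep_ids = [i + 1 for i, a in enumerate(areas) if a >= min_area]
    if not keep_ids:
        raise EmptyMaskError("all components below minimum area")
    keep_ids.sort(key=lambda i: areas[i - 1], reverse=True)
    n_keep = 1 if organ == "heart" else 2
    mask = np.isin(labels, keep_ids[:n_keep])
    return mask.astype(np.uint8)


def bounding_box(mask: np.ndarray) -> BoundingBox:
    """Tightest axis-aligned box around the mask's foreground."""
    mask = np.asarray(mask)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise EmptyMaskError("empty mask has no bounding box")
    return BoundingBox(x_min=int(cols[0]), x_max=int(cols[-1]),
                       y_min=int(rows[0]), y_max=int(rows[-1]))


def compute_ctr(heart_box: BoundingBox, lungs_box: BoundingBox) -> float:
    """Heart box width divided by lungs box width."""
    if lungs_box.width <= 0:
        raise ValueError("undefined CTR: lungs box has zero width")
    return heart_box.width / lungs_box.width


def classify(ctr: float, pi: float = DEFAULT_PI) -> str:
    """Cardiomegaly iff CTR strictly exceeds π."""
    if not np.isfinite(ctr) or ctr <= 0:
        raise ValueError(f"invalid CTR {ctr}")
    return CARDIOMEGALY if ctr > pi else NORMAL


def ctr_from_masks(heart_mask: np.ndarray, lungs_mask: np.ndarray,
                   pi: float = DEFAULT_PI) -> CTRResult:
    """CTR and label from already-binary organ masks."""
    try:
        hb = bounding_box(heart_mask)
        lb = bounding_box(lungs_mask)
    except EmptyMaskError:
        return CTRResult(None, pi, None, None, None, False, "indeterminate")
    ctr = compute_ctr(hb, lb)
    return CTRResult(ctr, pi, classify(ctr, pi), hb, lb, True)


def ctr_from_probability_maps(heart_p: np.ndarray, lungs_p: np.ndarray,
                              pi: float = DEFAULT_PI,
                              threshold: float = BINARIZE_THRESHOLD
                              ) -> CTRResult:
    """Full post-processing chain from the two network outputs."""
    try:
        hm = binarize_and_select(heart_p, "heart", threshold)
        lm = binarize_and_select(lungs_p, "lungs", threshold)
    except EmptyMaskError:
        return CTRResult(None, pi, None, None, None, False, "indeterminate")
    return ctr_from_masks(hm, lm, pi)
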