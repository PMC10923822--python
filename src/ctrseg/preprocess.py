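"""Input standardization and label-consistent augmentation.

Standardization follows a fixed pipeline: resize to a square target
(default 299), convert to single-channel grayscale, apply Contrast
Limited Adaptive Histogram Equalization (CLAHE), replicate the enhanced
channel three times, and divide by the maximum 8-bit value 255 so the
result lies in [0, 1].  Images are resized bilinearly; masks always use
nearest-neighbour so labels stay binary.

Augmentation applies one jointly sampled geometric transform to an
image/mask pair: random horizontal and vertical flips, rotation with
magnitude uniform in [0°, 10°] and random sign, and a 10% zoom-in
(center-crop to 90% of each side, then resize back).  The same sampled
transform hits image and mask, so pixel-level labels stay consistent.
"""

from __future__ import annotations

import numpy as np
from skimage import exposure, transform

DEFAULT_SIZE = 299
DEFAULT_CLAHE_CLIP = 2.0   # OpenCV-style clip limit; mapped to skimage below
DEFAULT_CLAHE_GRID = 8
DEFAULT_MAX_ROTATION = 10.0
DEFAULT_ZOOM = 0.10


class InvalidInputError(ValueError):
    pass


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Luminance grayscale for RGB(A); identity for single channel."""
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] in (3, 4):
        rgb = img[..., :3].astype(float)
        return rgb @ np.array([0.2125, 0.7154, 0.0721])
    if img.ndim == 3 and img.shape[2] == 1:
        return img[..., 0]
    raise InvalidInputError(f"unsupported image shape {img.shape}")


def standardize(raw: np.ndarray, size: int = DEFAULT_SIZE,
                clahe_clip: float = DEFAULT_CLAHE_CLIP,
                clahe_grid: int = DEFAULT_CLAHE_GRID) -> np.ndarray:
    """8-bit image -> (size, size, 3) float array in [0, 1].

    Pipeline order: resize → grayscale → CLAHE → replicate to three
    channels → divide by 255.  ``clahe_clip`` uses the familiar
    OpenCV-style scale (default 2.0) and is mapped onto skimage's
    fractional clip limit; ``clahe_grid`` is the tile count per side.
    """
    raw = np.asarray(raw)
    if raw.size == 0 or raw.ndim < 2:
        raise InvalidInputError("empty or non-2-D input")
    resized = transform.resize(raw.astype(float), (size, size),
                               order=1, preserve_range=True,
                               anti_aliasing=True)
    gray = to_grayscale(resized)
    gray01 = np.clip(gray / 255.0, 0.0, 1.0)
    kernel = max(1, size // clahe_grid)
    eq = exposure.equalize_adapthist(gray01, kernel_size=kernel,
                                     clip_limit=clahe_clip / 100.0)
    eq8 = np.round(eq * 255.0)
    out = np.repeat(eq8[:, :, None], 3, axis=2) / 255.0
    return out


def _resize_pair(image, mask, shape):
    img = transform.resize(image, shape + image.shape[2:], order=1,
                           preserve_range=True, anti_aliasing=False)
    msk = transform.resize(mask, shape, order=0, preserve_range=True,
                           anti_aliasing=False)
    return img, (msk > 0.5).astype(mask.dtype)


def augment(image: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
            max_rotation_deg: float = DEFAULT_MAX_ROTATION,
            zoom: float = DEFAULT_ZOOM,
            hflip: bool | None = None, vflip: bool | None = None,
            angle_deg: float | None = None, do_zoom: bool | None = None):
    """Jointly transform an image/mask pair; returns a new pair.

    Decisions not forced through the keyword overrides are sampled from
    ``rng``: each flip with probability 1/2, the rotation magnitude
    uniform in [0, max_rotation_deg] with a random sign, and the zoom-in
    with probability 1/2.  The mask is resampled nearest-neighbour and
    stays binary.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError(
            f"image/mask spatial shapes differ: {image.shape} vs {mask.shape}"
        )
    if hflip is None:
        hflip = bool(rng.random() < 0.5)
    if vflip is None:
        vflip = bool(rng.random() < 0.5)
    if angle_deg is None:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        angle_deg = sign * float(rng.uniform(0.0, max_rotation_deg))
    if do_zoom is None:
        do_zoom = bool(rng.random() < 0.5)

    img, msk = image.astype(float), mask.copy()
    if hflip:
        img, msk = img[:, ::-1].copy(), msk[:, ::-1].copy()
    if vflip:
        img, msk = img[::-1, :].copy(), msk[::-1, :].copy()
    if angle_deg:
        img = transform.rotate(img, angle_deg, order=1, mode="constant",
                               cval=0.0, preserve_range=True)
        msk = transform.rotate(msk.astype(float), angle_deg, order=0,
                               mode="constant", cval=0.0, preserve_range=True)
        msk = (msk > 0.5).astype(mask.dtype)
    if do_zoom and zoom > 0:
        h, w = img.shape[:2]
        ch, cw = round(h * (1 - zoom)), round(w * (1 - zoom))
        top, left = (h - ch) // 2, (w - cw) // 2
        img = img[top:top + ch, left:left + cw]
        msk = msk[top:top + ch, left:left + cw]
        img, msk = _resize_pair(img, msk, (h, w))
    return img, msk.astype(mask.dtype)
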