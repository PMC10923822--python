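"""Synthetic chest-radiograph phantoms with pixel-exact ground truth.

A phantom emulates a posteroanterior chest radiograph at the level the
segmentation pipeline needs: two dark elliptical lung fields on a brighter
body background, a bright central cardiac silhouette whose horizontal
extent is controlled exactly, an optional intensity gradient, optional
rib-like bands, and additive Gaussian noise.  Each phantom carries binary
heart and lung masks and the true cardiothoracic ratio (CTR) implied by
the drawn geometry, so every downstream stage — preprocessing, training,
bounding boxes, CTR thresholding, evaluation — can be tested without
clinical data.

The true CTR is defined exactly as the detection pipeline measures it:
horizontal pixel extent of the heart ellipse divided by the horizontal
pixel extent of the lung-field union.  The heart width is synthesised as
``round(target_ctr * lung_union_width)``, so the mask-derived CTR matches
the requested one up to pixelisation (within 2/image_size).

Noise and gradients perturb only the rendered image; masks are a
deterministic function of the geometry alone.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .evalmetrics import CARDIOMEGALY, NORMAL


class InvalidSpecError(ValueError):
    """Phantom geometry violates its invariants."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and rendering parameters of one phantom.

    Positions and semi-axes are fractions of the (square) image size.
    ``target_ctr`` is the requested heart-width / lung-union-width ratio.
    """

    image_size: int = 128
    lung_centers: tuple = ((0.30, 0.47), (0.70, 0.47))
    lung_semiaxes: tuple = ((0.155, 0.30), (0.155, 0.30))
    heart_center: tuple = (0.50, 0.60)
    heart_semi_b: float = 0.17
    target_ctr: float = 0.50
    noise_sd: float = 0.0
    gradient_amp: float = 0.0
    ribs: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.target_ctr <= 1.0):
            raise InvalidSpecError(
                f"target_ctr must be in (0, 1], got {self.target_ctr}"
            )
        if self.image_size < 16:
            raise InvalidSpecError("image_size too small")
        for (cx, cy), (a, b) in zip(self.lung_centers, self.lung_semiaxes):
            if cx - a < 0 or cx + a > 1 or cy - b < 0 or cy + b > 1:
                raise InvalidSpecError("lung ellipse outside image")
        if not (0.0 < self.heart_semi_b < 0.5):
            raise InvalidSpecError("heart_semi_b out of range")
        cy = self.heart_center[1]
        if cy - self.heart_semi_b < 0 or cy + self.heart_semi_b > 1:
            raise InvalidSpecError("heart ellipse outside image")


def _ellipse_mask(size: int, cx: float, cy: float, a: float, b: float
                  ) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def _mask_h_extent(mask: np.ndarray) -> tuple:
    cols = np.flatnonzero(mask.any(axis=0))
    if cols.size == 0:
        raise InvalidSpecError("empty mask")
    return int(cols[0]), int(cols[-1])


def generate_phantom(spec: PhantomSpec):
    """Render one phantom.

    Returns ``(image, heart_mask, lungs_mask, true_ctr)`` where the image
    is float in [0, 1], the masks are uint8 {0, 1}, and ``true_ctr`` is
    the ratio of the horizontal pixel extents of the two masks.
    """
    spec.validate()
    s = spec.image_size

    lungs = np.zeros((s, s), dtype=bool)
    for (cx, cy), (a, b) in zip(spec.lung_centers, spec.lung_semiaxes):
        lungs |= _ellipse_mask(s, cx * s, cy * s, a * s, b * s)

    x0, x1 = _mask_h_extent(lungs)
    lung_w = x1 - x0 + 1
    heart_w = max(1, int(round(spec.target_ctr * lung_w)))

    # Exact-width ellipse: integer center for odd widths, half-integer for
    # even ones, so the pixel extent equals heart_w exactly.
    cx_frac = spec.heart_center[0] * s
    if heart_w % 2 == 1:
        hx = float(round(cx_frac))
        ha = (heart_w - 1) / 2.0 + 0.25
    else:
        hx = np.floor(cx_frac) + 0.5
        ha = (heart_w - 1) / 2.0 + 0.25
    hy = spec.heart_center[1] * s
    heart = _ellipse_mask(s, hx, hy, max(ha, 0.3), spec.heart_semi_b * s)

    hx0, hx1 = _mask_h_extent(heart)
    if spec.target_ctr < 1.0 and not (hx0 >= x0 and hx1 <= x1):
        raise InvalidSpecError(
            "heart extent exceeds lung-union extent for target_ctr < 1"
        )

    rng = np.random.default_rng(spec.seed)
    img = np.full((s, s), 0.55)
    if spec.gradient_amp:
        ramp = np.linspace(-0.5, 0.5, s)
        img += spec.gradient_amp * ramp[:, None]
    img[lungs] = 0.25
    if spec.ribs:
        yy = np.arange(s)[:, None]
        bands = 0.08 * (np.sin(2 * np.pi * yy / max(8, s // 9)) > 0.3)
        img = np.where(lungs, img + bands, img)
    img[heart] = 0.78
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=(s, s))
    img = np.clip(img, 0.0, 1.0)

    true_ctr = (hx1 - hx0 + 1) / lung_w
    return img, heart.astype(np.uint8), lungs.astype(np.uint8), float(true_ctr)


def _resolve_ctr_law(ctr_law):
    """Accept a callable rng->float, a constant, or ('uniform', lo, hi)."""
    if callable(ctr_law):
        return ctr_law
    if isinstance(ctr_law, (int, float)):
        return lambda rng: float(ctr_law)
    if isinstance(ctr_law, (tuple, list)) and ctr_law[0] == "uniform":
        lo, hi = float(ctr_law[1]), float(ctr_law[2])
        return lambda rng: float(rng.uniform(lo, hi))
    raise ValueError(f"unrecognised ctr_law: {ctr_law!r}")


def _jittered(base: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """Randomly vary lung/heart geometry so a dataset is not one template."""
    def j(v, amp):
        return v * (1.0 + rng.uniform(-amp, amp))

    lc = tuple(
        (c[0] + rng.uniform(-0.02, 0.02), c[1] + rng.uniform(-0.03, 0.03))
        for c in base.lung_centers
    )
    ls = tuple((j(a, 0.08), j(b, 0.08)) for a, b in base.lung_semiaxes)
    hc = (base.heart_center[0] + rng.uniform(-0.015, 0.015),
          base.heart_center[1] + rng.uniform(-0.03, 0.03))
    return replace(base, lung_centers=lc, lung_semiaxes=ls, heart_center=hc,
                   heart_semi_b=j(base.heart_semi_b, 0.08))


MANIFEST_COLUMNS = ["path", "heart_mask", "lungs_mask", "true_ctr", "label"]


def _write_png(path: Path, arr: np.ndarray) -> None:
    Image.fromarray(arr.astype(np.uint8), mode="L").save(path)


def generate_dataset(n_labeled: int, m_unlabeled: int, out_dir,
                     ctr_law=("uniform", 0.35, 0.75), pi: float = 0.50,
                     image_size: int = 128, noise_sd: float = 0.03,
                     gradient_amp: float = 0.10, seed: int = 0,
                     base_spec: PhantomSpec | None = None) -> Path:
    """Write a phantom dataset and its manifest CSV; return the manifest path.

    Labeled rows carry mask paths, the true CTR, and the image-level label
    (cardiomegaly iff true_ctr > pi); unlabeled rows have those fields
    empty, mirroring a pixel-annotated set alongside a larger unannotated
    one.  Deterministic for fixed arguments and seed.
    """
    if n_labeled < 0 or m_unlabeled < 0:
        raise ValueError("counts must be non-negative")
    out_dir = Path(out_dir)
    try:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create output directory {out_dir}: {e}") from e

    draw_ctr = _resolve_ctr_law(ctr_law)
    rng = np.random.default_rng(seed)
    base = base_spec or PhantomSpec(image_size=image_size, noise_sd=noise_sd,
                                    gradient_amp=gradient_amp)
    rows = []
    for i in range(n_labeled + m_unlabeled):
        labeled = i < n_labeled
        spec = replace(
            _jittered(base, rng),
            target_ctr=draw_ctr(rng),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        img, heart, lungs, true_ctr = generate_phantom(spec)
        name = f"{'lab' if labeled else 'unl'}_{i:05d}"
        img_rel = f"images/{name}.png"
        _write_png(out_dir / img_rel, np.round(img * 255))
        if labeled:
            h_rel = f"masks/{name}_heart.png"
            l_rel = f"masks/{name}_lungs.png"
            _write_png(out_dir / h_rel, heart * 255)
            _write_png(out_dir / l_rel, lungs * 255)
            label = CARDIOMEGALY if true_ctr > pi else NORMAL
            rows.append([img_rel, h_rel, l_rel, f"{true_ctr:.6f}", label])
        else:
            rows.append([img_rel, "", "", "", ""])

    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(MANIFEST_COLUMNS)
        w.writerows(rows)
    return manifest
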