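"""Apply a correction matrix to full images: forward splat, holes, fills.

Correction relocates every source pixel outward (lam >= 1 undoes the
inward pincushion pull), so the forward-mapped image contains *holes*:
output cells in which no source pixel landed.  Because the map expands,
the number of holes is essentially the number of source pixels pushed
out of frame — a boundary effect proportional to the distortion
magnitude.  Holes are filled from the Euclidean-nearest populated cell,
which preserves the continuous structure of skin texture better than
leaving gaps and is cheap enough for real-time use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dcm_core import DCM
from .patterns import GrayImage

__all__ = [
    "HoleMask",
    "correct_image",
    "fill_holes_nearest",
    "subtract_images",
    "hole_fraction",
]


@dataclass
class HoleMask:
    """Boolean mask of output cells that received no source pixel."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("hole mask must be 2-D")

    @property
    def hole_fraction(self) -> float:
        return float(self.mask.mean())


def correct_image(image: GrayImage, dcm: DCM) -> tuple[GrayImage, HoleMask]:
    """Forward-map an image through the correction matrix.

    Every source pixel is relocated by its lam coefficient and splatted
    to the nearest integer target cell; targets falling outside the
    frame are dropped.  When several sources collide on one cell the
    source with the smaller distorted radius wins (it carries the less
    distorted information); exact radius ties go to the earlier pixel in
    row-major order.  The traversal order is fixed, so output is
    bit-reproducible.
    """
    if image.pixels.shape != dcm.lam.shape:
        raise ValueError(
            f"image {image.pixels.shape} and DCM {dcm.lam.shape} dimensions differ"
        )
    h, w = image.pixels.shape
    xc, yc = dcm.center
    xs = np.arange(w, dtype=float) - xc
    ys = np.arange(h, dtype=float) - yc
    xx, yy = np.meshgrid(xs, ys)
    tx = np.rint(dcm.lam * xx + xc).astype(np.int64).ravel()
    ty = np.rint(dcm.lam * yy + yc).astype(np.int64).ravel()
    rd = np.hypot(xx, yy).ravel()
    vals = image.pixels.ravel()
    rows, cols = np.divmod(np.arange(vals.size), w)
    inb = (tx >= 0) & (tx < w) & (ty >= 0) & (ty < h)
    tx, ty, rd, vals = tx[inb], ty[inb], rd[inb], vals[inb]
    rows, cols = rows[inb], cols[inb]
    # sort so the intended winner is written last (descending rd, then
    # descending row-major position; numpy fancy assignment keeps the last)
    order = np.lexsort((-cols, -rows, -rd))
    out = np.zeros((h, w), dtype=float)
    hit = np.zeros((h, w), dtype=bool)
    out[ty[order], tx[order]] = vals[order]
    hit[ty[order], tx[order]] = True
    return GrayImage(out, image.px_per_mm), HoleMask(~hit)


def fill_holes_nearest(image: GrayImage, mask: HoleMask) -> GrayImage:
    """Fill each hole with the intensity of its Euclidean-nearest donor.

    Non-hole cells are unchanged; filling an image with no holes is the
    identity, and the operation is idempotent.
    """
    m = mask.mask
    if m.shape != image.pixels.shape:
        raise ValueError("mask and image dimensions differ")
    if not m.any():
        return GrayImage(image.pixels.copy(), image.px_per_mm)
    if m.all():
        raise ValueError("mask covers the entire image; no donor pixels exist")
    _, (ir, ic) = ndimage.distance_transform_edt(m, return_indices=True)
    filled = image.pixels.copy()
    filled[m] = image.pixels[ir[m], ic[m]]
    return GrayImage(filled, image.px_per_mm)


def subtract_images(a: GrayImage, b: GrayImage) -> GrayImage:
    """Per-pixel absolute difference, clipped to [0, 1].

    The subtraction image of a distorted frame and its correction
    visualises where the correction acted: energy concentrates toward
    the left/right borders where radial displacement is largest.
    """
    if a.pixels.shape != b.pixels.shape:
        raise ValueError("image dimensions differ")
    return GrayImage(np.clip(np.abs(a.pixels - b.pixels), 0.0, 1.0), a.px_per_mm)


def hole_fraction(mask: HoleMask) -> float:
    """Fraction of output cells that received no source pixel."""
    return mask.hole_fraction
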