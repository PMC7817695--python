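"""Synthetic joint-surface-replica images with known damage ground truth.

Emulates back-scattered electron SEM images of resin casts of the tibial
plateau: a textured mid-gray field carrying dark, elongated crack-like
lesions (the damage of interest), compact near-circular debris (soft tissue
or bubbles in the mold, to be rejected by the circularity filter or a debris
mask), and sub-4-pixel bright speckle (to be despeckled).  Only the
statistical and geometric structure consumed by the quantitation pipeline is
modelled, not SEM image formation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import disk as disk_selem

from .._util import JSR_FIELD_OF_VIEW_UM, JSR_IMAGE_SIZE_PX, substream
from ..jsr import PlateauImage

__all__ = ["SurfaceSpec", "generate_surface"]

_BG_LEVEL = 30000  # mid-gray of the 16-bit replica field
_CRACK_DEPTH = 14000  # gray-level drop inside a crack
_DEBRIS_DEPTH = 9000  # gray-level drop inside a debris blob
_SPECKLE_GAIN = 18000  # gray-level rise of a bright speckle


@dataclass
class SurfaceSpec:
    """Parameters of one synthetic plateau image.

    Defaults reproduce the imaging geometry of the acquisition setup
    (1536 x 1536 px over an 1800 x 1800 um field) with a handful of cracks
    at the low damage fractions seen in healthy joints.
    """

    image_shape: tuple[int, int] = (JSR_IMAGE_SIZE_PX, JSR_IMAGE_SIZE_PX)
    field_of_view: float = JSR_FIELD_OF_VIEW_UM  # um, square
    n_cracks: int = 4
    crack_length_px: tuple[int, int] = (80, 320)
    crack_aspect_ratio: float = 12.0  # length/width; >= 6 keeps circularity < 0.5
    n_debris_blobs: int = 3
    n_speckles: int = 30
    background_texture_amplitude: float = 500.0  # gray levels (free knob)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crack_aspect_ratio < 6:
            raise ValueError(
                "crack_aspect_ratio must be >= 6 so digital circularity stays below 0.5"
            )
        lo, hi = self.crack_length_px
        if not (0 < lo <= hi):
            raise ValueError("crack_length_px must be a positive (lo, hi) range")
        if self.n_cracks < 0 or self.n_debris_blobs < 0 or self.n_speckles < 0:
            raise ValueError("counts must be non-negative")

    @property
    def pixel_area(self) -> float:
        """um^2 per pixel."""
        return (self.field_of_view / self.image_shape[0]) * (
            self.field_of_view / self.image_shape[1]
        )


def _draw_crack(rng: np.random.Generator, shape, length: int, width: int):
    """Rasterize one jagged polyline crack; returns a boolean mask or None."""
    margin = width + 4
    rows, cols = shape
    if rows - 2 * margin <= 0 or cols - 2 * margin <= 0:
        return None
    r = float(rng.integers(margin, rows - margin))
    c = float(rng.integers(margin, cols - margin))
    theta = rng.uniform(0, 2 * np.pi)
    n_seg = 3
    seg = length / n_seg
    pts = []
    for _ in range(n_seg):
        r2 = r + seg * np.sin(theta)
        c2 = c + seg * np.cos(theta)
        if not (margin <= r2 < rows - margin and margin <= c2 < cols - margin):
            return None
        rr, cc = draw_line(int(round(r)), int(round(c)), int(round(r2)), int(round(c2)))
        pts.append((rr, cc))
        r, c = r2, c2
        theta += rng.uniform(-0.35, 0.35)
    mask = np.zeros(shape, dtype=bool)
    all_r = np.concatenate([p[0] for p in pts])
    all_c = np.concatenate([p[1] for p in pts])
    mask[all_r, all_c] = True
    radius = max(0, int(round((width - 1) / 2)))
    if radius:
        # dilate only within the crack's bounding box for speed
        r0 = max(0, all_r.min() - radius - 1)
        r1 = min(rows, all_r.max() + radius + 2)
        c0 = max(0, all_c.min() - radius - 1)
        c1 = min(cols, all_c.max() + radius + 2)
        mask[r0:r1, c0:c1] = ndi.binary_dilation(
            mask[r0:r1, c0:c1], structure=disk_selem(radius)
        )
    return mask


def generate_surface(spec: SurfaceSpec):
    """Render one plateau replica image with pixel-exact ground truth.

    Returns
    -------
    image : PlateauImage
        16-bit textured field with cracks, debris and speckle rendered in.
    damage_mask : ndarray of bool
        Exactly the crack pixels (debris and speckle excluded).
    plateau_mask : ndarray of bool
        The plateau support; the synthetic replica fills the full frame.

    Raises
    ------
    ValueError
        If the image is too small to hold the requested crack length.
    """
    shape = tuple(spec.image_shape)
    lo, hi = spec.crack_length_px
    max_width = max(1, int(round(hi / spec.crack_aspect_ratio)))
    if spec.n_cracks > 0 and hi + 2 * (max_width + 4) >= min(shape):
        raise ValueError(
            f"image {shape} too small for cracks of length up to {hi} px"
        )

    rng_tex = substream(spec.seed, 1)
    rng_geom = substream(spec.seed, 2)

    texture = ndi.gaussian_filter(rng_tex.standard_normal(shape), sigma=2.0)
    if texture.std() > 0:
        texture *= spec.background_texture_amplitude / texture.std()
    image = _BG_LEVEL + texture

    occupied = np.zeros(shape, dtype=bool)  # placed objects, with clearance
    damage_mask = np.zeros(shape, dtype=bool)
    clear = 5  # minimum gap between rendered objects, px

    def _mark(mask, r0, r1, c0, c1):
        # dilate only the object's window into the occupancy map
        r0, c0 = max(0, r0 - clear - 1), max(0, c0 - clear - 1)
        r1, c1 = min(shape[0], r1 + clear + 1), min(shape[1], c1 + clear + 1)
        occupied[r0:r1, c0:c1] |= ndi.binary_dilation(
            mask[r0:r1, c0:c1], structure=disk_selem(clear)
        )

    # Cracks: rejection-sampled so components stay disjoint and countable.
    placed = 0
    attempts = 0
    while placed < spec.n_cracks:
        attempts += 1
        if attempts > 200 * max(1, spec.n_cracks):
            raise ValueError(
                f"could not place {spec.n_cracks} non-overlapping cracks in {shape}"
            )
        length = int(rng_geom.integers(lo, hi + 1))
        width = max(1, int(round(length / spec.crack_aspect_ratio)))
        mask = _draw_crack(rng_geom, shape, length, width)
        if mask is None:
            continue
        rr, cc = np.nonzero(mask)
        if occupied[rr, cc].any():
            continue
        damage_mask |= mask
        _mark(mask, rr.min(), rr.max() + 1, cc.min(), cc.max() + 1)
        placed += 1
    image[damage_mask] = _BG_LEVEL - _CRACK_DEPTH

    # Debris: compact near-circular blobs, dark like damage but round.
    placed = 0
    attempts = 0
    while placed < spec.n_debris_blobs and attempts < 200 * max(1, spec.n_debris_blobs):
        attempts += 1
        radius = int(rng_geom.integers(10, 18))
        r = int(rng_geom.integers(radius + 2, shape[0] - radius - 2))
        c = int(rng_geom.integers(radius + 2, shape[1] - radius - 2))
        rr, cc = draw_disk((r, c), radius, shape=shape)
        if occupied[rr, cc].any():
            continue
        blob = np.zeros(shape, dtype=bool)
        blob[rr, cc] = True
        image[blob] = _BG_LEVEL - _DEBRIS_DEPTH
        _mark(blob, rr.min(), rr.max() + 1, cc.min(), cc.max() + 1)
        placed += 1

    # Bright speckle: isolated components of area 1-3 px (< 4 px).
    placed = 0
    attempts = 0
    while placed < spec.n_speckles and attempts < 300 * max(1, spec.n_speckles):
        attempts += 1
        area = int(rng_geom.integers(1, 4))
        r = int(rng_geom.integers(2, shape[0] - 2))
        c = int(rng_geom.integers(2, shape[1] - 2))
        px = [(r, c)]
        if area >= 2:
            px.append((r, c + 1))
        if area >= 3:
            px.append((r + 1, c))
        rr = np.array([q[0] for q in px])
        cc = np.array([q[1] for q in px])
        if occupied[rr, cc].any():
            continue
        spot = np.zeros(shape, dtype=bool)
        spot[rr, cc] = True
        image[spot] = _BG_LEVEL + _SPECKLE_GAIN
        _mark(spot, rr.min(), rr.max() + 1, cc.min(), cc.max() + 1)
        placed += 1

    pixels = np.clip(image, 0, 65535).astype(np.uint16)
    plateau_mask = np.ones(shape, dtype=bool)
    return (
        PlateauImage(pixels=pixels, pixel_area=spec.pixel_area),
        damage_mask,
        plateau_mask,
    )
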