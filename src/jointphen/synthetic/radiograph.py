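"""Synthetic microradiographs with calibration standards and a bone object.

Emulates a point-projection radiograph of a proximal tibia imaged alongside
uniform plastic (low density) and steel (high density) calibration patches.
The bone object is a simple rectangular "tibia" whose top surface provides
the ROI anchor and whose width at the growth-plate row is known, so ROI
scaling and median-bin densitometry can be checked against construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._util import substream
from ..xrm import Radiograph

__all__ = ["RadiographSpec", "generate_radiograph"]


@dataclass
class RadiographSpec:
    image_shape: tuple[int, int] = (600, 400)
    plastic_gray: float = 5000.0
    steel_gray: float = 60000.0
    bone_gray_range: tuple[float, float] = (25000.0, 40000.0)
    growth_plate_row: int = 320
    tibia_width_px: int = 200
    bone_top_row: int = 60  # topmost bone row (the subchondral anchor)
    noise_sd: float = 0.0
    pixel_size: float = 10.0  # um
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plastic_gray >= self.steel_gray:
            raise ValueError("plastic_gray must be below steel_gray")
        lo, hi = self.bone_gray_range
        if lo > hi:
            raise ValueError("bone_gray_range must be (lo, hi)")
        if not (self.plastic_gray <= lo and hi <= self.steel_gray):
            raise ValueError("bone grays must lie between the plastic and steel levels")
        for g in (self.plastic_gray, self.steel_gray, lo, hi):
            if not (0 <= g <= 65535):
                raise ValueError(f"gray level {g} outside 16-bit range")
        if not (0 <= self.bone_top_row < self.growth_plate_row < self.image_shape[0]):
            raise ValueError("need bone_top_row < growth_plate_row within the image")
        if self.tibia_width_px >= self.image_shape[1]:
            raise ValueError("tibia wider than the image")


def generate_radiograph(spec: RadiographSpec):
    """Render one radiograph.

    Returns
    -------
    radiograph : Radiograph
        16-bit image with standard levels recorded (as a bench operator
        would record patch medians).
    standards : dict
        ``{"plastic": box, "steel": box}`` with (top, left, bottom, right)
        pixel rectangles of the uniform standard patches.
    bone_mask : ndarray of bool
        Ground-truth bone pixels.
    """
    rows, cols = spec.image_shape
    rng = substream(spec.seed, 10)

    background = spec.plastic_gray * 0.5
    image = np.full((rows, cols), background, dtype=float)

    # Standards: plastic top-right, steel bottom strip (uniform before noise).
    patch_h, patch_w = max(10, rows // 12), max(10, cols // 8)
    plastic_box = (5, cols - patch_w - 5, 5 + patch_h, cols - 5)
    steel_box = (rows - patch_h - 5, 5, rows - 5, 5 + patch_w)
    image[plastic_box[0] : plastic_box[2], plastic_box[1] : plastic_box[3]] = (
        spec.plastic_gray
    )
    image[steel_box[0] : steel_box[2], steel_box[1] : steel_box[3]] = spec.steel_gray

    # Bone object: rectangle of tibia_width_px centered horizontally,
    # spanning bone_top_row down to the bottom, with a vertical density
    # gradient across bone_gray_range (uniform when lo == hi).
    left = (cols - spec.tibia_width_px) // 2
    right = left + spec.tibia_width_px
    bone_mask = np.zeros((rows, cols), dtype=bool)
    bone_mask[spec.bone_top_row :, left:right] = True
    lo, hi = spec.bone_gray_range
    n_bone_rows = rows - spec.bone_top_row
    profile = np.linspace(lo, hi, n_bone_rows)
    image[spec.bone_top_row :, left:right] = profile[:, None]

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)

    pixels = np.clip(np.round(image), 0, 65535).astype(np.uint16)
    radiograph = Radiograph(
        pixels=pixels,
        pixel_size=spec.pixel_size,
        plastic_level=spec.plastic_gray,
        steel_level=spec.steel_gray,
    )
    standards = {"plastic": plastic_box, "steel": steel_box}
    return radiograph, standards, bone_mask
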