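"""Subchondral X-ray microradiography: calibration and relative BMC.

Raw microradiographs are calibrated by linearly stretching gray levels
between the plastic standard (bin 0) and the steel standard (bin 255) into
256 density bins.  A subchondral region of interest is scaled from the
tibial width at the growth plate (height 9%, width 34%) and anchored at
the topmost bone pixel directly beneath the plateau.  The relative bone
mineral content of the ROI is the median calibrated bin: the smallest bin
at which the cumulative pixel frequency reaches 50%.

Only relative BMC is produced; no absolute mineral mass calibration.
The aluminum standard present in the physical images is not used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._util import round_half_up

__all__ = [
    "Radiograph",
    "CalibratedImage",
    "SubchondralROI",
    "BMCResult",
    "calibrate",
    "place_roi",
    "median_gray",
    "DEFAULT_BONE_BIN_THRESHOLD",
]

#: Calibrated bin separating soft background from bone when anchoring the
#: ROI.  Bin 48 is the upper edge of the lowest band of the 16-color
#: pseudocolour lookup used to display these images (3 x 256/16), i.e. the
#: "lowest mineralized" band boundary.  Configurable per call.
DEFAULT_BONE_BIN_THRESHOLD = 48


@dataclass
class Radiograph:
    """Raw microradiograph with the gray levels of its density standards."""

    pixels: np.ndarray
    pixel_size: float = 10.0  # um
    plastic_level: float = 0.0
    steel_level: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("Radiograph requires a 2D array")


@dataclass
class CalibratedImage:
    bins: np.ndarray  # integer array, values 0..255

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins)
        if self.bins.min() < 0 or self.bins.max() > 255:
            raise ValueError("calibrated bins must lie in 0..255")


@dataclass
class SubchondralROI:
    side: str  # "medial" | "lateral"
    box: tuple[int, int, int, int]  # (top, left, bottom, right), exclusive stops
    growth_plate_width: int
    anchor: tuple[int, int]  # topmost bone pixel beneath the plateau


@dataclass
class BMCResult:
    median_bin: int
    histogram: np.ndarray  # 256 counts


def calibrate(raw: Radiograph) -> CalibratedImage:
    """Stretch raw grays between the plastic (0) and steel (255) standards.

    bin = round_half_up(255 * (g - plastic) / (steel - plastic)), clipped
    to [0, 255].
    """
    if raw.steel_level <= raw.plastic_level:
        raise ValueError("steel standard level must exceed plastic standard level")
    g = raw.pixels.astype(float)
    frac = (g - raw.plastic_level) / (raw.steel_level - raw.plastic_level)
    bins = np.clip(round_half_up(255.0 * frac), 0, 255)
    return CalibratedImage(bins=bins)


def place_roi(
    image: CalibratedImage,
    side: str,
    growth_plate_width: int,
    plateau_column_range: Optional[tuple[int, int]] = None,
    bone_bin_threshold: int = DEFAULT_BONE_BIN_THRESHOLD,
) -> SubchondralROI:
    """Scale and anchor the subchondral ROI from the growth-plate width.

    The box is ``round(0.09 * w)`` pixels tall and ``round(0.34 * w)``
    pixels wide, its top edge at the topmost pixel at or above
    ``bone_bin_threshold`` within ``plateau_column_range`` (the columns
    spanned by the plateau on the requested side), centered horizontally on
    that range.  The box is clipped to the image if necessary.
    """
    if side not in ("medial", "lateral"):
        raise ValueError("side must be 'medial' or 'lateral'")
    if growth_plate_width <= 0:
        raise ValueError("growth_plate_width must be positive")
    bins = image.bins
    n_rows, n_cols = bins.shape
    c0, c1 = (0, n_cols) if plateau_column_range is None else plateau_column_range
    if not (0 <= c0 < c1 <= n_cols):
        raise ValueError("plateau_column_range outside image")

    height = int(round_half_up(0.09 * growth_plate_width))
    width = int(round_half_up(0.34 * growth_plate_width))
    height = max(height, 1)
    width = max(width, 1)

    sub = bins[:, c0:c1]
    bone = sub >= bone_bin_threshold
    rows_with_bone = np.flatnonzero(bone.any(axis=1))
    if rows_with_bone.size == 0:
        raise ValueError(
            f"no pixel >= bone_bin_threshold ({bone_bin_threshold}) in the "
            "plateau column range"
        )
    top = int(rows_with_bone[0])
    anchor_col = int(c0 + np.flatnonzero(bone[top])[0])

    center = (c0 + c1) // 2
    left = center - width // 2
    right = left + width
    bottom = top + height
    # clip to image bounds
    left = max(0, min(left, n_cols - width))
    right = left + min(width, n_cols)
    bottom = min(bottom, n_rows)
    return SubchondralROI(
        side=side,
        box=(top, left, bottom, right),
        growth_plate_width=growth_plate_width,
        anchor=(top, anchor_col),
    )


def median_gray(calibrated: CalibratedImage, roi: SubchondralROI) -> BMCResult:
    """Median calibrated bin of the ROI: the relative BMC.

    The histogram spans bins 0..255; the median bin is the smallest bin at
    which the cumulative count reaches half the ROI pixel count.
    """
    top, left, bottom, right = roi.box
    patch = calibrated.bins[top:bottom, left:right]
    if patch.size == 0:
        raise ValueError("empty ROI")
    hist = np.bincount(patch.ravel().astype(int), minlength=256)
    cum = np.cumsum(hist)
    median_bin = int(np.flatnonzero(cum * 2 >= patch.size)[0])
    return BMCResult(median_bin=median_bin, histogram=hist)
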