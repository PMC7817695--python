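"""Small shared numerics: rounding conventions and seeded sub-streams."""

from __future__ import annotations

import numpy as np

#: Pixel geometry of the joint-surface imaging setup: an 1800 x 1800 um field
#: of view sampled at 1536 x 1536 px.  All particle-size cutoffs in the damage
#: pipeline are quoted in this geometry.
JSR_FIELD_OF_VIEW_UM = 1800.0
JSR_IMAGE_SIZE_PX = 1536
JSR_PIXEL_AREA_UM2 = (JSR_FIELD_OF_VIEW_UM / JSR_IMAGE_SIZE_PX) ** 2


def round_half_up(x):
    """Round to nearest integer, ties away from zero toward +inf.

    numpy's ``round`` uses banker's rounding; the image-calibration and
    ROI-scaling conventions here round .5 up, so make that explicit.
    """
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def round_to_half(x: float) -> float:
    """Round to the nearest 0.5, ties rounding up (x.25/x.75 -> up)."""
    return float(np.floor(2.0 * x + 0.5)) / 2.0


def substream(seed: int, *key: int) -> np.random.Generator:
    """Independent child generator for (seed, key).

    A single user-facing seed drives every synthetic generator; each named
    sub-stream is derived through ``SeedSequence`` so adding one generator
    call never perturbs another's stream.
    """
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(key)))
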