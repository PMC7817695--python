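"""Quantitation of articular-cartilage surface damage in joint-surface replicas.

The pipeline mirrors the semi-automated macro chain used on back-scattered
electron SEM images of plateau casts: select the plateau, despeckle bright
sub-4-pixel outliers, detect damage edges with a Sobel operator, erase
debris, threshold, and measure damage particles with a size filter
(> 20 px) and a circularity filter (0-0.5) that rejects round objects
unlikely to be genuine cracks.  Damage is reported as a percentage of the
total plateau area (components > 100 px, circularity unrestricted).

Manual steps of the bench protocol (freehand plateau selection, debris
erasure, threshold choice) are explicit inputs here, each with an automated
default (full frame, empty mask, Otsu), so the pipeline runs unattended;
provenance records which mode ran.

Conventions: row-major pixel coordinates, origin top-left, 0-based;
8-connected components; particle perimeters by boundary-contour length
(straight steps 1, diagonal steps sqrt(2)); circularity 4*pi*area/perimeter^2
capped at 1.0; holes inside a particle count toward its area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage import measure as skmeasure
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu

from ._util import JSR_PIXEL_AREA_UM2

__all__ = [
    "PlateauImage",
    "Particle",
    "ParticleSet",
    "DamageQuantResult",
    "JSRConfig",
    "select_plateau",
    "remove_bright_outliers",
    "find_edges",
    "apply_debris_mask",
    "threshold_damage",
    "analyze_particles",
    "measure_plateau_area",
    "run_jsr_pipeline",
]


@dataclass
class PlateauImage:
    """Calibrated 2D grayscale field of one tibial plateau replica.

    ``pixel_area`` is the physical area per pixel in um^2 (1.3733 um^2 for
    the standard 1800 um / 1536 px geometry).  ``plateau_mask`` marks the
    selected plateau; ``None`` means the full frame.
    """

    pixels: np.ndarray
    pixel_area: float = JSR_PIXEL_AREA_UM2
    plateau_polygon: Optional[np.ndarray] = None
    plateau_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("PlateauImage requires a single-channel 2D array")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")

    @property
    def mask(self) -> np.ndarray:
        if self.plateau_mask is None:
            return np.ones(self.pixels.shape, dtype=bool)
        return self.plateau_mask


@dataclass
class Particle:
    area_px: int
    area_um2: float
    perimeter: float
    circularity: float
    centroid: tuple[float, float]
    pixels: np.ndarray  # (n, 2) row/col coordinates


@dataclass
class ParticleSet:
    particles: list[Particle] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.particles)

    def __iter__(self):
        return iter(self.particles)

    @property
    def total_area_px(self) -> int:
        return int(sum(p.area_px for p in self.particles))

    @property
    def total_area_um2(self) -> float:
        return float(sum(p.area_um2 for p in self.particles))


@dataclass
class DamageQuantResult:
    damage_area_um2: float
    plateau_area_um2: float
    damage_percent: float
    n_damage_particles: int
    provenance: dict = field(default_factory=dict)


@dataclass
class JSRConfig:
    """Tunables of the damage pipeline (all sizes in this image's pixels)."""

    speckle_max_px: int = 4
    brightness_delta: Optional[float] = None  # None -> 2x background MAD
    threshold_method: str = "otsu"  # "otsu" | "manual"
    threshold_value: Optional[float] = None
    min_area_px: int = 20
    circularity_range: tuple[float, float] = (0.0, 0.5)
    plateau_min_area_px: int = 100
    # Robustness floor for the automated threshold: background texture alone
    # must not be read as damage.  Ignored in manual mode.
    edge_floor_mads: float = 10.0


def _as_array(image) -> np.ndarray:
    return image.pixels if isinstance(image, PlateauImage) else np.asarray(image)


def _wrap_like(image, pixels: np.ndarray, **extra):
    if isinstance(image, PlateauImage):
        kwargs = dict(
            pixel_area=image.pixel_area,
            plateau_polygon=image.plateau_polygon,
            plateau_mask=image.plateau_mask,
        )
        kwargs.update(extra)
        return PlateauImage(pixels=pixels, **kwargs)
    return pixels


def select_plateau(image: PlateauImage, polygon: Sequence) -> PlateauImage:
    """Restrict the image to a closed plateau polygon (row, col vertices).

    Pixels outside the polygon are set to 0 and excluded from all
    downstream measurements.  Self-intersecting or degenerate polygons are
    rejected.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise ValueError("polygon must be an (n >= 3, 2) array of (row, col) vertices")
    shp = _ShapelyPolygon(poly)
    if shp.area == 0:
        raise ValueError("polygon encloses zero area (empty selection)")
    if not shp.is_valid:
        raise ValueError("polygon is self-intersecting or otherwise invalid")
    arr = _as_array(image)
    mask = polygon2mask(arr.shape, poly)
    if not mask.any():
        raise ValueError("polygon selects no pixels")
    out = arr.copy()
    out[~mask] = 0
    return PlateauImage(
        pixels=out,
        pixel_area=image.pixel_area,
        plateau_polygon=poly,
        plateau_mask=mask,
    )


def remove_bright_outliers(image, max_area_px: int = 4, brightness_delta=None):
    """Replace bright connected components smaller than ``max_area_px``.

    A pixel belongs to a candidate speckle when it exceeds its 5x5 local
    median by ``brightness_delta`` gray levels (default: 2x the scaled MAD
    of the background gray levels).  Candidate components with area strictly
    below ``max_area_px`` are replaced by the local median; nothing else
    changes.
    """
    if max_area_px < 1:
        raise ValueError("max_area_px must be >= 1")
    arr = _as_array(image)
    f = arr.astype(float)
    local_med = ndi.median_filter(f, size=5)
    resid = f - local_med
    if brightness_delta is None:
        # 2x the scaled MAD of the background gray levels
        mad = float(np.median(np.abs(f - np.median(f))))
        brightness_delta = max(2.0 * 1.4826 * mad, 1.0)
    candidates = resid > brightness_delta
    labels, n = ndi.label(candidates, structure=np.ones((3, 3), dtype=int))
    if n:
        sizes = np.bincount(labels.ravel())
        small = np.zeros(n + 1, dtype=bool)
        small[1:] = sizes[1:] < max_area_px
        kill = small[labels]
        f = np.where(kill, local_med, f)
    out = f
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        out = np.clip(np.round(f), info.min, info.max).astype(arr.dtype)
    return _wrap_like(image, out)


def find_edges(image) -> np.ndarray:
    """Sobel gradient magnitude sqrt(Gx^2 + Gy^2), clipped to the bit depth.

    Uses the unnormalized 3x3 Sobel kernels, so an ideal step of height h
    responds with magnitude 4h at the pixels adjoining the edge.
    """
    arr = _as_array(image)
    if arr.ndim != 2:
        raise ValueError("find_edges expects a single-channel 2D image")
    f = arr.astype(float)
    gx = ndi.sobel(f, axis=1)
    gy = ndi.sobel(f, axis=0)
    mag = np.hypot(gx, gy)
    if np.issubdtype(arr.dtype, np.integer):
        mag = np.clip(mag, 0, np.iinfo(arr.dtype).max)
    return mag


def apply_debris_mask(image, debris_mask: np.ndarray):
    """Zero out operator-marked debris pixels (soft tissue, mold bubbles)."""
    arr = _as_array(image)
    debris_mask = np.asarray(debris_mask, dtype=bool)
    if debris_mask.shape != arr.shape:
        raise ValueError(
            f"debris mask shape {debris_mask.shape} != image shape {arr.shape}"
        )
    out = arr.copy()
    out[debris_mask] = 0
    return _wrap_like(image, out)


def threshold_damage(
    edge_image: np.ndarray,
    method: str = "otsu",
    value: Optional[float] = None,
    plateau_mask: Optional[np.ndarray] = None,
    edge_floor_mads: float = 0.0,
) -> np.ndarray:
    """Binarize the edge image: foreground = pixels >= threshold in the plateau.

    ``manual`` uses the given value verbatim (the operator's choice).
    ``otsu`` picks the between-class-variance-maximizing threshold over
    plateau pixels; with ``edge_floor_mads`` > 0 the automated threshold is
    floored at median + k*MAD of the plateau edge magnitudes so that pure
    background texture yields an (almost) empty foreground.
    """
    edge = np.asarray(edge_image, dtype=float)
    mask = (
        np.ones(edge.shape, dtype=bool)
        if plateau_mask is None
        else np.asarray(plateau_mask, dtype=bool)
    )
    vals = edge[mask]
    if vals.size == 0:
        raise ValueError("empty plateau selection")
    if method == "manual":
        if value is None:
            raise ValueError("manual thresholding requires a value")
        thr = float(value)
    elif method == "otsu":
        if np.ptp(vals) == 0:
            thr = vals.flat[0] + 1.0  # constant edge image: nothing to detect
        else:
            thr = float(threshold_otsu(vals))
        if edge_floor_mads > 0:
            med = float(np.median(vals))
            mad = 1.4826 * float(np.median(np.abs(vals - med)))
            thr = max(thr, med + edge_floor_mads * mad)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return (edge >= thr) & mask


def _contour_perimeter(mask: np.ndarray) -> float:
    """Length of the outer iso-contour of a padded binary blob."""
    padded = np.pad(mask.astype(float), 1)
    contours = skmeasure.find_contours(padded, 0.5)
    if not contours:
        return 0.0
    lengths = [np.sum(np.hypot(*np.diff(c, axis=0).T)) for c in contours]
    return float(max(lengths))  # outer boundary is the longest contour


def _measure_particles(binary: np.ndarray, pixel_area: float) -> list[Particle]:
    labels = skmeasure.label(binary, connectivity=2)
    particles = []
    for region in skmeasure.regionprops(labels):
        rmin, cmin, rmax, cmax = region.bbox
        perim = _contour_perimeter(region.image)
        area = int(region.area)
        circ = 1.0 if perim == 0 else min(1.0, 4.0 * np.pi * area / perim**2)
        particles.append(
            Particle(
                area_px=area,
                area_um2=area * pixel_area,
                perimeter=perim,
                circularity=circ,
                centroid=tuple(region.centroid),
                pixels=region.coords,
            )
        )
    return particles


def analyze_particles(
    binary: np.ndarray,
    min_area_px: int = 20,
    circularity_range: tuple[float, float] = (0.0, 0.5),
    pixel_area: float = JSR_PIXEL_AREA_UM2,
    fill_holes: bool = True,
) -> ParticleSet:
    """8-connected component analysis with size and circularity filters.

    Keeps components with area strictly greater than ``min_area_px`` whose
    circularity (4*pi*area/perimeter^2, capped at 1) lies in
    ``circularity_range``.  Holes are filled before measurement, so a
    detected crack outline counts with its enclosed area, as the bench
    macro's particle tool measures it.
    """
    lo, hi = circularity_range
    if lo > hi:
        raise ValueError("circularity range lower bound exceeds upper bound")
    binary = np.asarray(binary, dtype=bool)
    if fill_holes:
        binary = ndi.binary_fill_holes(binary)
    particles = [
        p
        for p in _measure_particles(binary, pixel_area)
        if p.area_px > min_area_px and lo <= p.circularity <= hi
    ]
    return ParticleSet(particles=particles)


def measure_plateau_area(
    selection: np.ndarray,
    min_area_px: int = 100,
    pixel_area: float = JSR_PIXEL_AREA_UM2,
) -> float:
    """Total plateau area (um^2): components > ``min_area_px``, any circularity."""
    selection = np.asarray(selection, dtype=bool)
    if not selection.any():
        raise ValueError("empty plateau selection")
    labels = skmeasure.label(selection, connectivity=2)
    sizes = np.bincount(labels.ravel())[1:]
    kept = sizes[sizes > min_area_px]
    if kept.size == 0:
        warnings.warn(
            "plateau selection is fragmented into components below the size "
            "filter; plateau area is 0",
            stacklevel=2,
        )
        return 0.0
    return float(kept.sum() * pixel_area)


def run_jsr_pipeline(
    image: PlateauImage,
    polygon: Optional[Sequence] = None,
    debris_mask: Optional[np.ndarray] = None,
    config: Optional[JSRConfig] = None,
) -> DamageQuantResult:
    """Chain the full damage-quantitation pipeline on one plateau image."""
    cfg = config or JSRConfig()
    img = select_plateau(image, polygon) if polygon is not None else image
    mask = img.mask

    despeckled = remove_bright_outliers(
        img, max_area_px=cfg.speckle_max_px, brightness_delta=cfg.brightness_delta
    )
    edges = find_edges(despeckled)
    if debris_mask is not None:
        edges = apply_debris_mask(edges, debris_mask)

    binary = threshold_damage(
        edges,
        method=cfg.threshold_method,
        value=cfg.threshold_value,
        plateau_mask=mask,
        edge_floor_mads=cfg.edge_floor_mads if cfg.threshold_method == "otsu" else 0.0,
    )
    damage = analyze_particles(
        binary,
        min_area_px=cfg.min_area_px,
        circularity_range=cfg.circularity_range,
        pixel_area=img.pixel_area,
    )
    plateau_area = measure_plateau_area(
        mask, min_area_px=cfg.plateau_min_area_px, pixel_area=img.pixel_area
    )

    damage_area = min(damage.total_area_um2, plateau_area)
    if plateau_area == 0:
        warnings.warn("plateau area is zero; damage percent reported as 0", stacklevel=2)
        percent = 0.0
    else:
        percent = 100.0 * damage_area / plateau_area
    if debris_mask is not None and np.all(np.asarray(debris_mask, dtype=bool)):
        warnings.warn("debris mask covers the entire image", stacklevel=2)

    provenance = {
        "plateau_selection": "polygon" if polygon is not None else "full_frame",
        "debris_mask": debris_mask is not None,
        "threshold_method": cfg.threshold_method,
        "threshold_value": cfg.threshold_value,
        "speckle_max_px": cfg.speckle_max_px,
        "brightness_delta": cfg.brightness_delta,
        "min_area_px": cfg.min_area_px,
        "circularity_range": list(cfg.circularity_range),
        "plateau_min_area_px": cfg.plateau_min_area_px,
        "pixel_area_um2": img.pixel_area,
    }
    return DamageQuantResult(
        damage_area_um2=damage_area,
        plateau_area_um2=plateau_area,
        damage_percent=percent,
        n_damage_particles=len(damage),
        provenance=provenance,
    )
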