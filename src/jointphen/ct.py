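"""Contrast-enhanced uCT morphometry of articular cartilage and subchondral bone.

The joint is imaged immersed in an iodinated contrast bath with X-ray
absorption similar to mineralized tissue, so soft tissue including the
articular cartilage is dark: cartilage segments *below* a density
threshold of 200 mg HA/cm^3 and subchondral bone *above* 300 mg HA/cm^3,
within volumes of interest scaled automatically from tibial landmark
dimensions (width 14% of the medial-lateral axis, depth 33% of the
anterior-posterior axis; medial VOI centered at 61.5% and lateral at 68.5%
along the AP axis, the lateral VOI additionally shifted 7% of the ML axis
medially).

Seven parameters are reported: cartilage volume (Cg.V), median and maximum
cartilage thickness (Median/Max Cg.Th), subchondral bone volume fraction
(SC BV/TV), trabecular thickness (SC Tb.Th), trabecular number (SC Tb.N)
and tissue mineral density (SC TMD).  Thickness uses the maximal-inscribed-
sphere (distance-transform) method.  Because the contrast agent raises
apparent subchondral density systematically, outputs are relative measures
for within-study comparison, not absolute scanner-equivalent values.

Axis convention: arrays are (z, y, x) = (proximal->distal,
anterior->posterior, medial->lateral), z = 0 at the articular surface side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import ball

from ._util import round_half_up

__all__ = [
    "DensityVolume",
    "TibiaLandmarks",
    "VOI",
    "MorphometryResult",
    "CTConfig",
    "place_vois",
    "preprocess",
    "segment_cartilage",
    "segment_subchondral_bone",
    "local_thickness",
    "cartilage_metrics",
    "trabecular_metrics",
    "run_morphometry",
]

CARTILAGE_THRESHOLD = 200.0  # mg HA/cm^3, cartilage is below this
BONE_THRESHOLD = 300.0  # mg HA/cm^3, subchondral bone is above this


@dataclass
class DensityVolume:
    """3D mineral-density field (mg HA/cm^3) on an isotropic voxel grid."""

    voxels: np.ndarray  # (z, y, x)
    voxel_size: float  # um, isotropic

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("DensityVolume requires a 3D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("densities must be finite")


@dataclass
class TibiaLandmarks:
    """Manually determined tibial landmarks in voxel coordinates.

    ``ml_extent`` spans the medial-lateral (x) axis from the medial edge a
    to the lateral edge b; ``ap_extent`` spans anterior (c) to posterior
    (d); ``plateau_edges`` holds per-side (x0, x1) ranges of the tibial
    plateaux; ``growth_plate_z`` is the z index of the growth plate.
    """

    ml_extent: tuple[int, int]
    ap_extent: tuple[int, int]
    plateau_edges: dict[str, tuple[int, int]]
    growth_plate_z: int

    def __post_init__(self) -> None:
        a, b = self.ml_extent
        c, d = self.ap_extent
        if not (a < b and c < d):
            raise ValueError("landmark extents must be increasing (a<b, c<d)")
        for side, (x0, x1) in self.plateau_edges.items():
            if not (a <= x0 < x1 <= b):
                raise ValueError(f"{side} plateau range outside the ML extent")


@dataclass
class VOI:
    side: str
    box: tuple[int, int, int, int, int, int]  # (z0, z1, y0, y1, x0, x1)

    def slices(self) -> tuple[slice, slice, slice]:
        z0, z1, y0, y1, x0, x1 = self.box
        return (slice(z0, z1), slice(y0, y1), slice(x0, x1))


@dataclass
class MorphometryResult:
    cg_v_mm3: float
    median_cg_th_mm: float
    max_cg_th_mm: float
    sc_bv_tv: float
    sc_tb_th_mm: float
    sc_tb_n_per_mm: float
    sc_tmd: float
    provenance: dict = field(default_factory=dict)


@dataclass
class CTConfig:
    cartilage_threshold: float = CARTILAGE_THRESHOLD
    bone_threshold: float = BONE_THRESHOLD
    cartilage_closing_radius: int = 5
    bone_closing_radius: int = 3
    cartilage_keep_largest: int = 5
    bone_keep_largest: int = 20
    gaussian_sigma: float = 0.8
    gaussian_support: float = 1.0
    tb_n_method: str = "direct"  # "direct" | "plate"


_CONN26 = np.ones((3, 3, 3), dtype=int)


def place_vois(
    landmarks: TibiaLandmarks,
    volume_shape: Optional[tuple[int, int, int]] = None,
) -> tuple[VOI, VOI]:
    """Scale the medial and lateral VOIs from the tibial landmarks.

    Each box is 14% of the ML axis wide and 33% of the AP axis deep,
    centered on its plateau ML midpoint (the lateral box offset a further
    7% of the ML axis toward medial) with AP midpoints at 61.5% (medial)
    and 68.5% (lateral) of the AP axis, spanning z from the articular
    surface to the growth plate.  Boxes are clipped to the volume with a
    warning.
    """
    a, b = landmarks.ml_extent
    c, d = landmarks.ap_extent
    ml = b - a
    ap = d - c
    width = int(round_half_up(0.14 * ml))
    depth = int(round_half_up(0.33 * ap))

    vois = []
    for side, ap_frac in (("medial", 0.615), ("lateral", 0.685)):
        x0p, x1p = landmarks.plateau_edges[side]
        x_mid = (x0p + x1p) / 2.0
        if side == "lateral":
            x_mid -= 0.07 * ml  # shift medially
        y_mid = c + ap_frac * ap
        x0 = int(round_half_up(x_mid - width / 2.0))
        y0 = int(round_half_up(y_mid - depth / 2.0))
        box = [0, landmarks.growth_plate_z, y0, y0 + depth, x0, x0 + width]
        if volume_shape is not None:
            clipped = [
                max(0, min(box[0], volume_shape[0])),
                max(0, min(box[1], volume_shape[0])),
                max(0, min(box[2], volume_shape[1])),
                max(0, min(box[3], volume_shape[1])),
                max(0, min(box[4], volume_shape[2])),
                max(0, min(box[5], volume_shape[2])),
            ]
            if clipped != box:
                warnings.warn(f"{side} VOI exceeded volume bounds and was clipped",
                              stacklevel=2)
            box = clipped
        vois.append(VOI(side=side, box=tuple(box)))
    return vois[0], vois[1]


def preprocess(volume: DensityVolume, sigma: float = 0.8, support: float = 1.0) -> DensityVolume:
    """Gaussian filtration (default sigma 0.8 voxels, 1-voxel support)."""
    if sigma <= 0:
        return DensityVolume(voxels=volume.voxels.copy(), voxel_size=volume.voxel_size)
    smoothed = ndi.gaussian_filter(volume.voxels, sigma=sigma, truncate=support / sigma)
    return DensityVolume(voxels=smoothed, voxel_size=volume.voxel_size)


def _keep_largest(labels: np.ndarray, n_labels: int, keep: int) -> np.ndarray:
    """Boolean mask of the ``keep`` largest labelled components."""
    if n_labels == 0:
        return np.zeros(labels.shape, dtype=bool)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    order = np.argsort(sizes)[::-1][:keep]
    kept = np.zeros(sizes.size, dtype=bool)
    kept[order[sizes[order] > 0]] = True
    return kept[labels]


def _closing(mask: np.ndarray, radius: int) -> np.ndarray:
    """Morphological closing with a discrete ball, padded to avoid edge loss."""
    if radius <= 0 or not mask.any():
        return mask
    selem = ball(radius)
    padded = np.pad(mask, radius)
    closed = ndi.binary_erosion(ndi.binary_dilation(padded, structure=selem),
                                structure=selem)
    sl = (slice(radius, -radius),) * 3
    return closed[sl]


def segment_cartilage(
    volume: DensityVolume,
    voi: VOI,
    upper: float = CARTILAGE_THRESHOLD,
    keep_largest: int = 5,
    closing_radius: int = 5,
    surface_connected: bool = True,
    surface_margin: Optional[int] = None,
) -> np.ndarray:
    """Articular-cartilage mask within the VOI (full-volume boolean array).

    Voxels below ``upper`` are thresholded, the ``keep_largest`` largest
    26-connected components retained, and a ``closing_radius``-voxel
    morphological closing applied.  With ``surface_connected``, retained
    components must reach within ``surface_margin`` voxels of the
    shallowest low-density voxel in the VOI: the articular cartilage is the
    topmost soft structure, while deeper low-density pockets (marrow
    spaces, growth-plate cartilage) are rejected.
    """
    sl = voi.slices()
    sub = volume.voxels[sl]
    low = sub < upper
    mask = np.zeros(volume.voxels.shape, dtype=bool)
    if not low.any():
        warnings.warn("no voxels below the cartilage threshold in the VOI",
                      stacklevel=2)
        return mask
    labels, n = ndi.label(low, structure=_CONN26)
    if surface_connected and n:
        margin = closing_radius + 1 if surface_margin is None else surface_margin
        z_any = low.any(axis=(1, 2))
        z_surface = int(np.flatnonzero(z_any)[0])
        reach = np.zeros(n + 1, dtype=bool)
        near_surface = labels[: z_surface + margin + 1]
        reach[np.unique(near_surface[near_surface > 0])] = True
        low = reach[labels]
        labels, n = ndi.label(low, structure=_CONN26)
    kept = _keep_largest(labels, n, keep_largest)
    kept = _closing(kept, closing_radius)
    if not kept.any():
        warnings.warn("cartilage segmentation is empty", stacklevel=2)
    mask[sl] = kept
    return mask


def segment_subchondral_bone(
    volume: DensityVolume,
    voi: VOI,
    cartilage_mask: np.ndarray,
    growth_plate_z: Optional[int] = None,
    lower: float = BONE_THRESHOLD,
    keep_largest: int = 20,
    closing_radius: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Subchondral-bone mask and its tissue-volume region (both full-volume).

    Bone is thresholded above ``lower`` in the slab between the cartilage
    base and the growth plate, the ``keep_largest`` largest 26-connected
    components retained, and a ``closing_radius``-voxel closing applied.
    The returned region mask (the TV of BV/TV) is that slab intersected
    with the VOI.
    """
    z0, z1, y0, y1, x0, x1 = voi.box
    if growth_plate_z is None:
        growth_plate_z = z1
    cart_sub = np.asarray(cartilage_mask, dtype=bool)[voi.slices()]
    if cart_sub.any():
        cart_base = int(np.flatnonzero(cart_sub.any(axis=(1, 2)))[-1]) + 1
    else:
        cart_base = 0
    slab_lo = z0 + cart_base
    slab_hi = min(growth_plate_z, z1)
    region = np.zeros(volume.voxels.shape, dtype=bool)
    mask = np.zeros(volume.voxels.shape, dtype=bool)
    if slab_lo >= slab_hi:
        warnings.warn("no tissue between the cartilage base and the growth plate",
                      stacklevel=2)
        return mask, region
    region[slab_lo:slab_hi, y0:y1, x0:x1] = True

    sub = volume.voxels[slab_lo:slab_hi, y0:y1, x0:x1]
    bone = sub > lower
    labels, n = ndi.label(bone, structure=_CONN26)
    kept = _keep_largest(labels, n, keep_largest)
    kept = _closing(kept, closing_radius)
    mask[slab_lo:slab_hi, y0:y1, x0:x1] = kept
    mask &= ~np.asarray(cartilage_mask, dtype=bool)
    mask &= region
    if not mask.any():
        warnings.warn("subchondral bone segmentation is empty", stacklevel=2)
    return mask, region


def local_thickness(mask: np.ndarray, step: Optional[float] = None) -> np.ndarray:
    """Maximal-inscribed-sphere thickness field, in voxels.

    For every foreground voxel, the diameter of the largest sphere that
    contains it and fits inside the structure: th(x) = 2 max over centers
    c with |x - c| <= dt(c) of dt(c), where dt is the Euclidean distance
    transform to the nearest background voxel center.  Sphere radii are
    processed in descending bins of width ``step`` voxels (default: 0.25,
    coarsened to rmax/40 for thick structures), so values are exact to
    about one ``step``.
    """
    mask = np.asarray(mask, dtype=bool)
    th = np.zeros(mask.shape, dtype=float)
    if not mask.any():
        return th
    # Work on the bounding box (plus 1-voxel pad) for speed.
    bbox = ndi.find_objects(mask.astype(np.int8), max_label=1)[0]
    pad = tuple(
        (1 if s.start > 0 else 0, 1 if s.stop < dim else 0)
        for s, dim in zip(bbox, mask.shape)
    )
    sub = mask[bbox]
    dt = ndi.distance_transform_edt(np.pad(sub, pad))
    dt = dt[tuple(slice(p0, dt.shape[i] - p1 or None) for i, (p0, p1) in enumerate(pad))]
    rmax = float(dt.max())
    if step is None:
        step = max(0.25, rmax / 40.0)
    if step > 0:
        # floor-quantize so painted radii never exceed the true dt
        q = np.floor(dt / step) * step
    else:
        q = dt  # exact unique radii (small volumes)
    radii = np.unique(q[sub])[::-1]
    th_sub = np.zeros(sub.shape, dtype=float)
    for r in radii:
        if r <= 0:
            continue
        centers = q == r
        cover = ndi.distance_transform_edt(~centers) <= r
        np.maximum(th_sub, np.where(cover & sub, 2.0 * r, 0.0), out=th_sub)
    th[bbox] = th_sub
    return th


def cartilage_metrics(
    mask: np.ndarray, voxel_size: float
) -> tuple[float, float, float]:
    """(Cg.V mm^3, Median Cg.Th mm, Max Cg.Th mm) of a cartilage mask."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        warnings.warn("empty cartilage mask; metrics are zero", stacklevel=2)
        return 0.0, 0.0, 0.0
    vox_mm = voxel_size / 1000.0
    cg_v = n * vox_mm**3
    th = local_thickness(mask)[mask] * vox_mm
    return float(cg_v), float(np.median(th)), float(th.max())


def trabecular_metrics(
    mask: np.ndarray,
    densities: np.ndarray,
    voxel_size: float,
    region_mask: Optional[np.ndarray] = None,
    method: str = "direct",
) -> tuple[float, float, float, float]:
    """(SC BV/TV, SC Tb.Th mm, SC Tb.N 1/mm, SC TMD mg HA/cm^3).

    BV/TV is the bone-voxel fraction of the tissue region.  Tb.Th is the
    mean maximal-sphere thickness of the bone phase.  Tb.N by the direct
    (model-independent) method is the reciprocal of the mean mid-axis
    spacing, Tb.Th + Tb.Sp, with Tb.Sp the mean maximal-sphere thickness
    of the background phase within the region; ``method="plate"`` gives
    the plate-model alternative (BV/TV)/Tb.Th.  TMD is the mean density
    over bone voxels.
    """
    mask = np.asarray(mask, dtype=bool)
    region = (
        np.ones(mask.shape, dtype=bool)
        if region_mask is None
        else np.asarray(region_mask, dtype=bool)
    )
    n_bone = int(mask.sum())
    n_region = int(region.sum())
    if n_bone == 0 or n_region == 0:
        warnings.warn("empty bone mask or region; metrics are zero", stacklevel=2)
        return 0.0, 0.0, 0.0, 0.0
    vox_mm = voxel_size / 1000.0
    bv_tv = n_bone / n_region
    tb_th = float(local_thickness(mask)[mask].mean()) * vox_mm
    tmd = float(np.asarray(densities, dtype=float)[mask].mean())
    if bv_tv >= 1.0:
        return 1.0, tb_th, 1.0 / tb_th if tb_th > 0 else 0.0, tmd
    background = region & ~mask
    if method == "plate":
        tb_n = bv_tv / tb_th if tb_th > 0 else 0.0
    elif method == "direct":
        tb_sp = float(local_thickness(background)[background].mean()) * vox_mm
        spacing = tb_th + tb_sp
        tb_n = 1.0 / spacing if spacing > 0 else 0.0
    else:
        raise ValueError(f"unknown Tb.N method {method!r}")
    return float(bv_tv), tb_th, float(tb_n), tmd


def run_morphometry(
    volume: DensityVolume,
    landmarks: TibiaLandmarks,
    side: str = "medial",
    config: Optional[CTConfig] = None,
) -> MorphometryResult:
    """Full morphometry of one plateau side: VOI placement through metrics."""
    cfg = config or CTConfig()
    medial, lateral = place_vois(landmarks, volume.voxels.shape)
    voi = {"medial": medial, "lateral": lateral}[side]

    filtered = preprocess(volume, sigma=cfg.gaussian_sigma, support=cfg.gaussian_support)
    cart = segment_cartilage(
        filtered,
        voi,
        upper=cfg.cartilage_threshold,
        keep_largest=cfg.cartilage_keep_largest,
        closing_radius=cfg.cartilage_closing_radius,
    )
    bone, region = segment_subchondral_bone(
        filtered,
        voi,
        cart,
        growth_plate_z=landmarks.growth_plate_z,
        lower=cfg.bone_threshold,
        keep_largest=cfg.bone_keep_largest,
        closing_radius=cfg.bone_closing_radius,
    )
    # Metrics are computed on the VOI crop: a structure clipped by a VOI
    # face physically continues beyond it, and the distance transform on
    # the crop treats its edges accordingly (no spurious lateral thinning).
    sl = voi.slices()
    cg_v, med_th, max_th = cartilage_metrics(cart[sl], volume.voxel_size)
    # TMD from the unfiltered densities: smoothing drags boundary-voxel
    # densities toward the marrow and would bias the mean downward.
    bv_tv, tb_th, tb_n, tmd = trabecular_metrics(
        bone[sl], volume.voxels[sl], volume.voxel_size, region[sl],
        method=cfg.tb_n_method,
    )
    return MorphometryResult(
        cg_v_mm3=cg_v,
        median_cg_th_mm=med_th,
        max_cg_th_mm=max_th,
        sc_bv_tv=bv_tv,
        sc_tb_th_mm=tb_th,
        sc_tb_n_per_mm=tb_n,
        sc_tmd=tmd,
        provenance={
            "side": side,
            "voi_box": list(voi.box),
            "cartilage_threshold": cfg.cartilage_threshold,
            "bone_threshold": cfg.bone_threshold,
            "closing_radii": [cfg.cartilage_closing_radius, cfg.bone_closing_radius],
            "keep_largest": [cfg.cartilage_keep_largest, cfg.bone_keep_largest],
            "gaussian": [cfg.gaussian_sigma, cfg.gaussian_support],
            "tb_n_method": cfg.tb_n_method,
        },
    )
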