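"""Synthetic contrast-enhanced density volumes with analytic ground truth.

Emulates the epiphysis geometry the morphometry pipeline consumes: a
high-density contrast bath above, an articular-cartilage slab of known
thickness (low density), a subchondral compartment of a solid bone
plate over crossing trabecular walls on a square lattice (lattice fill
fraction 1 - (1 - t/s)^2) embedded in soft marrow, and a low-density
growth-plate layer at the bottom.  The plate is as thick as the walls, so
the whole bone phase has one analytic trabecular thickness.  Every
returned ground truth is the analytic value of the constructed geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._util import substream
from ..ct import DensityVolume, TibiaLandmarks

__all__ = ["VolumeSpec", "generate_volume"]


@dataclass
class VolumeSpec:
    volume_shape: tuple[int, int, int] = (160, 132, 132)  # (z, y, x)
    voxel_size: float = 2.0  # um, matching the scan protocol
    cartilage_thickness: float = 100.0  # um
    cartilage_density: float = 120.0  # mg HA/cm^3, must be < 200
    bath_density: float = 600.0  # mg HA/cm^3, bone-like contrast, > 300
    trabecular_rod_spacing: float = 132.0  # um, lattice period
    trabecular_rod_thickness: float = 44.0  # um, wall (and plate) thickness
    bone_density: float = 700.0  # mg HA/cm^3, > 300
    marrow_density: float = 100.0  # mg HA/cm^3, unperfused soft tissue
    lattice_kind: str = "grid"  # "grid": crossing walls; "plates": parallel plates
    bath_depth: int = 20  # voxels of bath above the cartilage surface
    growth_plate_depth: int = 6  # voxels of low-density growth plate at bottom
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.cartilage_density < 200.0 < 300.0 <= self.bone_density):
            raise ValueError("need cartilage_density < 200 < 300 <= bone_density")
        if self.bath_density <= 300.0:
            raise ValueError("bath_density must be bone-like (> 300)")
        if self.marrow_density >= 200.0:
            raise ValueError("marrow_density must stay below the cartilage threshold")
        if self.trabecular_rod_thickness >= self.trabecular_rod_spacing:
            raise ValueError("rod thickness must be below the lattice spacing")
        if self.lattice_kind not in ("grid", "plates"):
            raise ValueError("lattice_kind must be 'grid' or 'plates'")

    @property
    def cartilage_voxels(self) -> int:
        return int(round(self.cartilage_thickness / self.voxel_size))


def generate_volume(spec: VolumeSpec):
    """Construct one density volume.

    Returns
    -------
    volume : DensityVolume
    truths : dict
        Analytic ground truths of the constructed geometry: ``cg_th_um``,
        ``cg_v_mm3`` (full-cross-section slab volume), ``bv_tv``,
        ``tb_th_um``, ``tb_sp_um``, ``tb_n_per_mm``, ``tmd`` plus the
        exact ``cartilage_mask`` and ``bone_mask`` and a ``landmarks``
        object spanning the full cross-section.

    Raises
    ------
    ValueError
        If the cartilage slab would be thinner than 2 voxels (unresolvable).
    """
    nz, ny, nx = spec.volume_shape
    n_cart = spec.cartilage_voxels
    if n_cart < 2:
        raise ValueError(
            f"cartilage_thickness {spec.cartilage_thickness} um is below 2 voxels "
            f"at {spec.voxel_size} um voxel size"
        )
    s = int(round(spec.trabecular_rod_spacing / spec.voxel_size))
    t = int(round(spec.trabecular_rod_thickness / spec.voxel_size))
    if t < 1 or s <= t:
        raise ValueError("trabecular lattice unresolvable at this voxel size")

    z_cart0 = spec.bath_depth
    z_cart1 = z_cart0 + n_cart
    z_gp = nz - spec.growth_plate_depth
    if z_cart1 >= z_gp:
        raise ValueError("volume too shallow for bath + cartilage + bone + growth plate")

    rng = substream(spec.seed, 20)
    phase_y = int(rng.integers(0, s))
    phase_x = int(rng.integers(0, s))

    vol = np.full(spec.volume_shape, spec.bath_density, dtype=float)

    cartilage_mask = np.zeros(spec.volume_shape, dtype=bool)
    cartilage_mask[z_cart0:z_cart1] = True
    vol[cartilage_mask] = spec.cartilage_density

    # Subchondral bone plate (solid, thickness t) directly under the
    # cartilage, then the trabecular wall lattice down to the growth plate.
    z_plate1 = z_cart1 + t
    if z_plate1 >= z_gp:
        raise ValueError("volume too shallow for the subchondral plate + lattice")
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    if spec.lattice_kind == "grid":
        lattice2d = ((yy + phase_y) % s < t) | ((xx + phase_x) % s < t)
    else:  # parallel plates: analytically exact thickness metrics
        lattice2d = (xx + phase_x) % s < t
    bone_mask = np.zeros(spec.volume_shape, dtype=bool)
    bone_mask[z_cart1:z_plate1] = True
    bone_mask[z_plate1:z_gp] = lattice2d
    vol[z_cart1:z_plate1] = spec.bone_density
    vol[z_plate1:z_gp] = np.where(lattice2d, spec.bone_density, spec.marrow_density)

    vol[z_gp:] = spec.cartilage_density  # growth-plate cartilage layer

    volume = DensityVolume(voxels=vol, voxel_size=spec.voxel_size)

    vox_mm = spec.voxel_size / 1000.0
    if spec.lattice_kind == "grid":
        lattice_fill = 1.0 - (1.0 - t / s) ** 2
    else:
        lattice_fill = t / s
    height = z_gp - z_cart1  # subchondral compartment height, voxels
    bv_tv = (t + lattice_fill * (height - t)) / height
    # Mean maximal-sphere thickness is t for parallel plates; wall crossings
    # of the grid geometry host larger inscribed spheres, so thickness-based
    # truths are only stated for the plate geometry.
    analytic_thickness = spec.lattice_kind == "plates"
    landmarks = TibiaLandmarks(
        ml_extent=(0, nx),
        ap_extent=(0, ny),
        plateau_edges={"medial": (0, nx // 2), "lateral": (nx // 2, nx)},
        growth_plate_z=z_gp,
    )
    truths = {
        "cg_th_um": n_cart * spec.voxel_size,
        "cg_v_mm3": n_cart * ny * nx * vox_mm**3,
        "bv_tv": bv_tv,
        "lattice_bv_tv": lattice_fill,
        "tb_th_um": t * spec.voxel_size if analytic_thickness else None,
        "tb_sp_um": (s - t) * spec.voxel_size if analytic_thickness else None,
        "tb_n_per_mm": 1.0 / (s * vox_mm) if analytic_thickness else None,
        "tmd": spec.bone_density,
        "cartilage_mask": cartilage_mask,
        "bone_mask": bone_mask,
        "z_cartilage": (z_cart0, z_cart1),
        "z_lattice": (z_plate1, z_gp),
        "growth_plate_z": z_gp,
        "landmarks": landmarks,
    }
    return volume, truths
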