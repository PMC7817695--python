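"""uCT morphometry: VOI scaling, segmentation, thickness, trabecular metrics."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from helpers import local_thickness_bruteforce
from jointphen.ct import (
    VOI,
    DensityVolume,
    TibiaLandmarks,
    cartilage_metrics,
    local_thickness,
    place_vois,
    preprocess,
    run_morphometry,
    segment_cartilage,
    segment_subchondral_bone,
    trabecular_metrics,
)


def _landmarks(ml=(0, 1000), ap=(0, 600), gp=100):
    return TibiaLandmarks(
        ml_extent=ml,
        ap_extent=ap,
        plateau_edges={"medial": (ml[0], (ml[0] + ml[1]) // 2),
                       "lateral": ((ml[0] + ml[1]) // 2, ml[1])},
        growth_plate_z=gp,
    )


class TestPlaceVOIs:
    def test_dimensions_are_percentages_of_axes(self):
        medial, lateral = place_vois(_landmarks())
        for voi in (medial, lateral):
            z0, z1, y0, y1, x0, x1 = voi.box
            assert x1 - x0 == 140  # 14% of 1000
            assert y1 - y0 == 198  # 33% of 600

    def test_ap_midpoints_at_stated_fractions(self):
        medial, lateral = place_vois(_landmarks())
        _, _, y0m, y1m, _, _ = medial.box
        _, _, y0l, y1l, _, _ = lateral.box
        assert (y0m + y1m) / 2 == pytest.approx(0.615 * 600, abs=1)
        assert (y0l + y1l) / 2 == pytest.approx(0.685 * 600, abs=1)

    def test_lateral_box_shifted_medially_by_7_percent(self):
        medial, lateral = place_vois(_landmarks())
        _, _, _, _, x0m, x1m = medial.box
        _, _, _, _, x0l, x1l = lateral.box
        medial_center = (x0m + x1m) / 2
        lateral_center = (x0l + x1l) / 2
        # plateau midpoints are 250 and 750; lateral shifts 70 voxels medially
        assert medial_center == pytest.approx(250, abs=1)
        assert lateral_center == pytest.approx(750 - 70, abs=1)

    def test_scaling_landmarks_scales_boxes(self):
        a, _ = place_vois(_landmarks())
        b, _ = place_vois(_landmarks(ml=(0, 2000), ap=(0, 1200), gp=200))
        za = np.array(a.box)
        zb = np.array(b.box)
        assert np.allclose(zb, 2 * za, atol=2)

    def test_out_of_bounds_box_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            medial, _ = place_vois(_landmarks(), volume_shape=(50, 100, 100))
        assert medial.box[1] <= 50
        assert medial.box[3] <= 100


class TestPreprocess:
    def test_constant_volume_unchanged(self):
        vol = DensityVolume(np.full((8, 8, 8), 42.0), voxel_size=2.0)
        assert np.allclose(preprocess(vol).voxels, 42.0)

    def test_impulse_mass_preserved(self):
        v = np.zeros((9, 9, 9))
        v[4, 4, 4] = 1.0
        out = preprocess(DensityVolume(v, 2.0))
        assert out.voxels.sum() == pytest.approx(1.0)
        assert out.voxels[4, 4, 4] < 1.0

    def test_zero_sigma_is_identity(self):
        rng = np.random.default_rng(1)
        v = rng.random((6, 6, 6))
        out = preprocess(DensityVolume(v, 2.0), sigma=0.0)
        assert np.array_equal(out.voxels, v)


class TestSegmentation:
    def test_slab_segmented_with_high_dice(self, grid_volume):
        spec, volume, truths = grid_volume
        nz, ny, nx = volume.voxels.shape
        voi = VOI("medial", (0, truths["growth_plate_z"], 0, ny, 0, nx))
        cart = segment_cartilage(preprocess(volume), voi)
        gt = truths["cartilage_mask"]
        dice = 2 * (cart & gt).sum() / (cart.sum() + gt.sum())
        assert dice > 0.95

    def test_all_bath_voi_gives_empty_mask(self):
        vol = DensityVolume(np.full((20, 20, 20), 600.0), voxel_size=2.0)
        voi = VOI("medial", (0, 20, 0, 20, 0, 20))
        with pytest.warns(UserWarning):
            mask = segment_cartilage(vol, voi)
        assert not mask.any()

    def test_only_five_largest_components_kept(self):
        v = np.full((30, 60, 60), 600.0)
        sizes = [14, 12, 10, 8, 6, 4, 2]  # 7 blobs at the top surface
        for i, w in enumerate(sizes):
            v[0:3, 2 + 4 * i : 2 + 4 * i + 1, :w] = 100.0  # thin rods at z=0
        voi = VOI("medial", (0, 30, 0, 60, 0, 60))
        mask = segment_cartilage(DensityVolume(v, 2.0), voi, closing_radius=0)
        labels, n = ndi.label(mask, structure=np.ones((3, 3, 3)))
        assert n == 5
        kept_sizes = sorted(np.bincount(labels.ravel())[1:], reverse=True)
        assert kept_sizes == [3 * w for w in sizes[:5]]

    def test_lattice_segmented_with_high_dice(self, grid_volume):
        spec, volume, truths = grid_volume
        nz, ny, nx = volume.voxels.shape
        voi = VOI("medial", (0, truths["growth_plate_z"], 0, ny, 0, nx))
        filt = preprocess(volume)
        cart = segment_cartilage(filt, voi)
        bone, region = segment_subchondral_bone(
            filt, voi, cart, growth_plate_z=truths["growth_plate_z"]
        )
        gt = truths["bone_mask"]
        dice = 2 * (bone & gt).sum() / (bone.sum() + gt.sum())
        assert dice > 0.98
        assert not (bone & cart).any()  # masks disjoint

    def test_soft_compartment_gives_empty_bone_mask(self):
        v = np.full((30, 20, 20), 600.0)
        v[5:10] = 100.0  # cartilage slab; nothing mineralized below
        v[10:] = 150.0
        voi = VOI("medial", (0, 28, 0, 20, 0, 20))
        vol = DensityVolume(v, 2.0)
        cart = segment_cartilage(vol, voi, closing_radius=0)
        with pytest.warns(UserWarning, match="empty|no tissue"):
            bone, region = segment_subchondral_bone(vol, voi, cart, growth_plate_z=28)
        assert not bone.any()

    def test_bath_above_cartilage_excluded_from_bone(self, grid_volume):
        spec, volume, truths = grid_volume
        nz, ny, nx = volume.voxels.shape
        voi = VOI("medial", (0, truths["growth_plate_z"], 0, ny, 0, nx))
        filt = preprocess(volume)
        cart = segment_cartilage(filt, voi)
        bone, _ = segment_subchondral_bone(
            filt, voi, cart, growth_plate_z=truths["growth_plate_z"]
        )
        z0, _ = truths["z_cartilage"]
        assert not bone[: z0 + 1].any()  # bath region has no "bone" despite >300


class TestLocalThickness:
    @pytest.mark.parametrize("shape", [(14, 10, 6), (8, 8, 8)])
    def test_matches_bruteforce_sphere_search(self, shape, rng):
        mask = np.zeros(shape, dtype=bool)
        mask[2:-2, 2:-2, 1:-1] = True
        mask &= rng.random(shape) > 0.1
        ours = local_thickness(mask, step=0)
        oracle = local_thickness_bruteforce(mask)
        assert np.abs(ours[mask] - oracle[mask]).max() <= 0.75

    def test_slab_thickness_is_slab_width(self):
        mask = np.zeros((30, 20, 20), dtype=bool)
        mask[5:25] = True  # 20-voxel slab
        th = local_thickness(mask)
        assert np.median(th[mask]) == pytest.approx(20, abs=1)


class TestMetrics:
    def test_cartilage_volume_is_count_times_voxel_volume(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[2:6, :, :] = True
        cg_v, med, mx = cartilage_metrics(mask, voxel_size=2.0)
        assert cg_v == pytest.approx(mask.sum() * 8e-9)  # 8 um^3 in mm^3
        assert med == pytest.approx(0.008, abs=0.002)  # 4 voxels = 8 um

    def test_wedge_max_and_median_thickness(self):
        # thickness ramps gently 10 -> 30 voxels across 100 columns
        mask = np.zeros((40, 100, 20), dtype=bool)
        for y in range(100):
            depth = 10 + (y * 20) // 99
            mask[2 : 2 + depth, y, :] = True
        _, med, mx = cartilage_metrics(mask, voxel_size=1000.0)  # 1 voxel = 1 mm
        assert mx == pytest.approx(30, abs=2)
        assert 15 <= med <= 28

    def test_empty_mask_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="empty"):
            assert cartilage_metrics(np.zeros((4, 4, 4), bool), 2.0) == (0, 0, 0)

    def test_solid_region_has_unit_bvtv(self):
        mask = np.ones((10, 10, 10), dtype=bool)
        dens = np.full((10, 10, 10), 700.0)
        bvtv, tbth, tbn, tmd = trabecular_metrics(mask, dens, 2.0)
        assert bvtv == 1.0
        assert tmd == 700.0

    def test_lattice_bvtv_and_thickness_recovery(self, plates_volume):
        spec, volume, truths = plates_volume
        z0, z1 = truths["z_lattice"]
        region = np.zeros(volume.voxels.shape, dtype=bool)
        region[z0:z1] = True
        mask = truths["bone_mask"] & region
        bvtv, tbth, tbn, tmd = trabecular_metrics(mask, volume.voxels, spec.voxel_size,
                                                  region)
        assert bvtv == pytest.approx(truths["lattice_bv_tv"], abs=0.02)
        assert tbth * 1000 == pytest.approx(truths["tb_th_um"], rel=0.05)
        assert tbn == pytest.approx(truths["tb_n_per_mm"], rel=0.05)
        assert tmd == pytest.approx(700.0, rel=0.01)

    def test_tmd_invariant_under_density_permutation_within_bone(self, rng):
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[3:9, 3:9, 3:9] = True
        dens = np.full((12, 12, 12), 100.0)
        vals = rng.uniform(600, 800, size=int(mask.sum()))
        dens[mask] = vals
        _, _, _, tmd1 = trabecular_metrics(mask, dens, 2.0)
        rng.shuffle(vals)
        dens[mask] = vals
        _, _, _, tmd2 = trabecular_metrics(mask, dens, 2.0)
        assert tmd1 == pytest.approx(tmd2)

    def test_bvtv_invariant_under_rigid_rotation(self, plates_volume):
        spec, volume, truths = plates_volume
        z0, z1 = truths["z_lattice"]
        region = np.zeros(volume.voxels.shape, dtype=bool)
        region[z0:z1] = True
        mask = truths["bone_mask"] & region
        b1, *_ = trabecular_metrics(mask, volume.voxels, 2.0, region)
        rot = lambda a: np.rot90(a, k=1, axes=(1, 2))
        b2, *_ = trabecular_metrics(rot(mask), rot(volume.voxels), 2.0, rot(region))
        assert b1 == pytest.approx(b2)


class TestEndToEnd:
    def test_full_morphometry_recovers_constructed_parameters(self, grid_volume):
        spec, volume, truths = grid_volume
        result = run_morphometry(volume, truths["landmarks"], side="medial")
        # the VOI covers a fraction of the cross-section; volume scales with it
        z0, z1, y0, y1, x0, x1 = result.provenance["voi_box"]
        expected_cg_v = (
            (truths["cg_th_um"] / spec.voxel_size) * (y1 - y0) * (x1 - x0)
            * (spec.voxel_size / 1000.0) ** 3
        )
        assert result.cg_v_mm3 == pytest.approx(expected_cg_v, rel=0.05)
        assert result.median_cg_th_mm * 1000 == pytest.approx(truths["cg_th_um"], rel=0.05)
        assert result.max_cg_th_mm * 1000 == pytest.approx(truths["cg_th_um"], rel=0.05)
        assert result.sc_tmd == pytest.approx(truths["tmd"], rel=0.01)
        assert result.median_cg_th_mm <= result.max_cg_th_mm
        assert 0 <= result.sc_bv_tv <= 1
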