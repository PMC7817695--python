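"""Damage quantitation: macro chain, particle filters, pipeline invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import disk as draw_disk

from helpers import flood_fill_components, otsu_scan
from jointphen.jsr import (
    JSRConfig,
    PlateauImage,
    analyze_particles,
    apply_debris_mask,
    find_edges,
    measure_plateau_area,
    remove_bright_outliers,
    run_jsr_pipeline,
    select_plateau,
    threshold_damage,
)


def _flat_image(shape=(64, 64), level=1000, dtype=np.uint16):
    return PlateauImage(pixels=np.full(shape, level, dtype=dtype), pixel_area=1.3733)


class TestSelectPlateau:
    def test_full_frame_polygon_is_identity(self):
        img = _flat_image()
        poly = [(-0.5, -0.5), (-0.5, 63.5), (63.5, 63.5), (63.5, -0.5)]
        out = select_plateau(img, poly)
        assert np.array_equal(out.pixels, img.pixels)
        assert out.mask.all()

    def test_half_frame_polygon_halves_plateau_area(self):
        img = _flat_image((64, 64))
        poly = [(-0.5, -0.5), (-0.5, 63.5), (31.5, 63.5), (31.5, -0.5)]
        out = select_plateau(img, poly)
        assert out.mask.sum() == 32 * 64  # pixel-count oracle
        assert (out.pixels[32:] == 0).all()

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError, match="zero area"):
            select_plateau(_flat_image(), [(1, 1), (1, 1), (1, 1)])

    def test_self_intersecting_polygon_rejected(self):
        bowtie = [(0, 0), (10, 10), (0, 10), (5, 0)]
        with pytest.raises(ValueError, match="self-intersecting|invalid"):
            select_plateau(_flat_image(), bowtie)


class TestRemoveBrightOutliers:
    def test_constant_image_unchanged(self):
        img = _flat_image()
        out = remove_bright_outliers(img)
        assert np.array_equal(out.pixels, img.pixels)

    def test_three_pixel_speckle_removed_four_pixel_retained(self):
        px = np.full((64, 64), 1000, dtype=np.uint16)
        px[10, 10:13] = 5000  # 3-px speckle
        px[40, 40:44] = 5000  # 4-px speckle
        out = remove_bright_outliers(px, max_area_px=4, brightness_delta=500)
        assert (out[10, 10:13] == 1000).all()
        assert (out[40, 40:44] == 5000).all()
        # no other pixel changed
        changed = out != px
        assert changed.sum() == 3

    def test_synthetic_speckles_never_reach_damage_mask(self, small_surface):
        spec, image, damage, _ = small_surface
        speckle = image.pixels > 40000
        res = run_jsr_pipeline(image)
        assert res.n_damage_particles == spec.n_cracks
        despeckled = remove_bright_outliers(image)
        assert not (despeckled.pixels > 40000).any()

    def test_invalid_max_area_rejected(self):
        with pytest.raises(ValueError):
            remove_bright_outliers(_flat_image(), max_area_px=0)


class TestFindEdges:
    def test_constant_image_gives_zero_response(self):
        assert (find_edges(_flat_image()) == 0).all()

    def test_ideal_step_interior_response_is_4h(self):
        h = 100
        px = np.zeros((16, 16), dtype=float)
        px[:, 8:] = h
        mag = find_edges(px)
        # pixels adjoining the vertical step respond with 4h (hand-convolved)
        assert mag[8, 7] == pytest.approx(4 * h)
        assert mag[8, 8] == pytest.approx(4 * h)
        assert mag[8, 3] == 0

    def test_rotating_input_rotates_output(self, rng):
        px = rng.integers(0, 1000, size=(32, 32)).astype(float)
        assert np.allclose(np.rot90(find_edges(px)), find_edges(np.rot90(px)))


class TestDebrisMask:
    def test_empty_mask_is_identity(self):
        img = _flat_image()
        out = apply_debris_mask(img, np.zeros((64, 64), dtype=bool))
        assert np.array_equal(out.pixels, img.pixels)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            apply_debris_mask(_flat_image(), np.zeros((32, 32), dtype=bool))

    def test_masking_a_blob_removes_it_from_particles(self):
        px = np.full((128, 128), 1000, dtype=np.uint16)
        rr, cc = draw_disk((64, 64), 15)
        px[rr, cc] = 5000
        img = PlateauImage(pixels=px, pixel_area=1.0)
        edges = find_edges(img)
        binary = threshold_damage(edges, method="manual", value=1000.0)
        with_blob = analyze_particles(binary, min_area_px=20, circularity_range=(0, 1))
        mask = np.zeros((128, 128), dtype=bool)
        mask[rr, cc] = True
        mask = np.pad(mask[2:-2, 2:-2], 2)  # keep it tight
        edges2 = apply_debris_mask(edges, binary)  # erase everything detected
        binary2 = threshold_damage(edges2, method="manual", value=1000.0)
        without = analyze_particles(binary2, min_area_px=20, circularity_range=(0, 1))
        assert len(with_blob) == 1
        assert len(without) == 0

    def test_full_mask_gives_zero_damage_with_warning(self, small_surface):
        _, image, _, _ = small_surface
        full = np.ones(image.pixels.shape, dtype=bool)
        with pytest.warns(UserWarning, match="entire image"):
            res = run_jsr_pipeline(image, debris_mask=full)
        assert res.damage_percent == 0.0


class TestThreshold:
    def test_zero_threshold_selects_all_plateau_pixels(self):
        edges = np.abs(np.random.default_rng(0).normal(10, 3, (32, 32)))
        out = threshold_damage(edges, method="manual", value=0.0)
        assert out.all()

    def test_threshold_above_max_gives_empty_foreground(self):
        edges = np.full((16, 16), 5.0)
        assert not threshold_damage(edges, method="manual", value=6.0).any()

    def test_manual_without_value_rejected(self):
        with pytest.raises(ValueError, match="value"):
            threshold_damage(np.zeros((8, 8)), method="manual")

    def test_otsu_lands_between_bimodal_modes(self, rng):
        edges = np.concatenate(
            [rng.normal(10, 2, 600), rng.normal(200, 10, 400)]
        ).reshape(40, 25)
        binary = threshold_damage(edges, method="otsu")
        # foreground is exactly the upper mode
        assert binary.sum() == (edges >= 100).sum()
        oracle = otsu_scan(edges.ravel()[::5])
        assert 20 < oracle < 180

    def test_lowering_manual_threshold_never_decreases_damage_area(self, small_surface):
        _, image, _, _ = small_surface
        edges = find_edges(remove_bright_outliers(image))
        areas = []
        for value in (40000, 20000, 10000, 5000, 1000):
            binary = threshold_damage(edges, method="manual", value=value)
            ps = analyze_particles(binary, min_area_px=20, circularity_range=(0, 1))
            areas.append(ps.total_area_px)
        assert all(a <= b for a, b in zip(areas, areas[1:]))


class TestAnalyzeParticles:
    def test_elongated_rectangle_kept_with_low_circularity(self):
        binary = np.zeros((40, 130), dtype=bool)
        binary[10:20, 10:110] = True  # 10 x 100 rectangle
        ps = analyze_particles(binary, min_area_px=20, circularity_range=(0, 0.5))
        assert len(ps) == 1
        p = ps.particles[0]
        assert p.area_px == 1000
        # ideal contour perimeter 2 (10 + 100) = 220
        assert p.perimeter == pytest.approx(220, rel=0.05)
        assert p.circularity < 0.5

    def test_filled_disk_excluded_by_circularity(self):
        binary = np.zeros((64, 64), dtype=bool)
        rr, cc = draw_disk((32, 32), 20)
        binary[rr, cc] = True
        kept = analyze_particles(binary, min_area_px=20, circularity_range=(0, 0.5))
        assert len(kept) == 0
        measured = analyze_particles(binary, min_area_px=20, circularity_range=(0, 1))
        assert measured.particles[0].circularity > 0.9

    def test_small_fragment_excluded_by_size(self):
        binary = np.zeros((32, 32), dtype=bool)
        binary[5, 5:20] = True  # 15-px crack fragment
        assert len(analyze_particles(binary, min_area_px=20,
                                     circularity_range=(0, 1))) == 0

    def test_invalid_circularity_range_rejected(self):
        with pytest.raises(ValueError):
            analyze_particles(np.zeros((8, 8), dtype=bool), circularity_range=(0.7, 0.2))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_counts_and_areas_match_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        binary = rng.random((48, 48)) > 0.82
        ps = analyze_particles(binary, min_area_px=0, circularity_range=(0, 1),
                               fill_holes=False)
        comps = flood_fill_components(binary)
        assert len(ps) == len(comps)
        assert sorted(p.area_px for p in ps) == sorted(len(c) for c in comps)


class TestPlateauArea:
    def test_full_frame_area(self):
        sel = np.ones((1536, 1536), dtype=bool)
        area = measure_plateau_area(sel, pixel_area=1.3733)
        assert area == pytest.approx(1536**2 * 1.3733)

    def test_area_is_pixel_count_times_pixel_area(self):
        sel = np.zeros((300, 300), dtype=bool)
        sel[:250, :200] = True  # 50,000 px
        assert measure_plateau_area(sel, pixel_area=1.3733) == pytest.approx(68665.0)

    def test_fragmented_selection_warns_and_returns_zero(self):
        sel = np.zeros((64, 64), dtype=bool)
        sel[0:8, 0:8] = True  # 64 px <= 100
        with pytest.warns(UserWarning, match="fragmented"):
            assert measure_plateau_area(sel) == 0.0

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            measure_plateau_area(np.zeros((8, 8), dtype=bool))


class TestPipeline:
    def test_crack_free_surface_yields_zero_damage(self):
        from jointphen.synthetic import SurfaceSpec, generate_surface

        spec = SurfaceSpec(image_shape=(512, 512), n_cracks=0, n_debris_blobs=0,
                           n_speckles=0, seed=3)
        image, _, _ = generate_surface(spec)
        res = run_jsr_pipeline(image)
        assert res.damage_percent == 0.0

    def test_recovery_within_15_percent_of_truth(self, small_surface):
        spec, image, damage, _ = small_surface
        res = run_jsr_pipeline(image)
        truth_um2 = damage.sum() * spec.pixel_area
        assert res.damage_area_um2 == pytest.approx(truth_um2, rel=0.20)
        assert res.n_damage_particles == spec.n_cracks

    def test_damage_bounded_by_plateau(self, small_surface):
        _, image, _, _ = small_surface
        res = run_jsr_pipeline(image)
        assert 0 <= res.damage_percent <= 100
        assert res.damage_area_um2 <= res.plateau_area_um2

    def test_provenance_records_configuration(self, small_surface):
        _, image, _, _ = small_surface
        res = run_jsr_pipeline(image)
        assert res.provenance["threshold_method"] == "otsu"
        assert res.provenance["plateau_selection"] == "full_frame"
        assert res.provenance["circularity_range"] == [0.0, 0.5]
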