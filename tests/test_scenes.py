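"""Generator contracts: geometry, intensity model, determinism, ground truth."""

import math

import numpy as np
import pytest

from beadmetrics import (ArcSpec, BeadSpec, SceneSpec, SpheroidSpec,
                         render_brightfield_scene, render_fluorescence_scene,
                         sample_bead_population)


class TestRenderBrightfield:
    def test_empty_scene_is_uniform_background(self):
        spec = SceneSpec(256, 256, 2.0, "brightfield", noise_sd=0.01,
                         background_level=0.85, seed=3)
        scene, truth = render_brightfield_scene(spec, [])
        n_pix = scene.image.size
        assert abs(scene.image.mean() - 0.85) < 3 * 0.01 / math.sqrt(n_pix)
        assert truth.beads == []

    def test_bead_geometry_and_rim_level(self):
        # 700 um at 2 um/px: radius 175 px; rim darker by rim_contrast
        spec = SceneSpec(512, 512, 2.0, "brightfield", noise_sd=0.0, seed=0)
        bead = BeadSpec(256, 256, 700, rim_contrast=0.4)
        scene, truth = render_brightfield_scene(spec, [bead])
        assert truth.beads[0].diameter_um == 700
        assert truth.beads[0].diameter_um / spec.pixel_size_um == 350  # px
        rim_sample = scene.image[256, 256 + 170]  # inside rim annulus
        assert rim_sample == pytest.approx(0.85 * (1 - 0.4), abs=1e-12)
        assert scene.image[256, 256] > rim_sample          # interior lighter
        assert scene.image[10, 10] == pytest.approx(0.85)  # background

    def test_identical_spec_and_seed_bit_identical(self):
        spec = SceneSpec(256, 256, 4.0, "brightfield", noise_sd=0.02, seed=11)
        beads = [BeadSpec(128, 128, 560,
                          overgrowth_arcs=(ArcSpec(0, 120),))]
        img1 = render_brightfield_scene(spec, beads)[0].image
        img2 = render_brightfield_scene(spec, beads)[0].image
        assert np.array_equal(img1, img2)

    def test_different_seed_differs(self):
        beads = [BeadSpec(128, 128, 560)]
        a = render_brightfield_scene(
            SceneSpec(256, 256, 4.0, "brightfield", seed=1), beads)[0].image
        b = render_brightfield_scene(
            SceneSpec(256, 256, 4.0, "brightfield", seed=2), beads)[0].image
        assert not np.array_equal(a, b)

    def test_out_of_bounds_bead_names_index(self):
        spec = SceneSpec(256, 256, 4.0, "brightfield", seed=0)
        beads = [BeadSpec(128, 128, 500), BeadSpec(250, 128, 500)]
        with pytest.raises(ValueError, match="bead 1"):
            render_brightfield_scene(spec, beads)

    def test_overlapping_beads_rejected(self):
        spec = SceneSpec(512, 512, 4.0, "brightfield", seed=0)
        beads = [BeadSpec(200, 200, 600), BeadSpec(280, 200, 600)]
        with pytest.raises(ValueError, match="overlap"):
            render_brightfield_scene(spec, beads)

    @pytest.mark.parametrize("rim_contrast,arc_contrast",
                             [(0.35, 0.5), (0.1, 0.1), (0.6, 0.9)])
    def test_intensity_ordering(self, rim_contrast, arc_contrast):
        # band mean < rim mean < interior mean < background, any contrasts > 0
        spec = SceneSpec(320, 320, 4.0, "brightfield", noise_sd=0.0, seed=0)
        bead = BeadSpec(160, 160, 600, rim_contrast=rim_contrast,
                        overgrowth_arcs=(ArcSpec(0, 360, 40, arc_contrast),))
        scene, _ = render_brightfield_scene(spec, [bead])
        yy, xx = np.mgrid[0:320, 0:320]
        dist = np.hypot(xx - 160, yy - 160)
        r = 600 / 2 / 4.0
        rim_w = 32 / 4.0
        interior = scene.image[dist <= r - rim_w - 2].mean()
        rim = scene.image[(dist > r - rim_w + 1) & (dist <= r - 1)].mean()
        band = scene.image[(dist > r + 1) & (dist <= r + 0.5 * 10)].mean()
        background = scene.image[dist > r + 1.4 * 10 + 2].mean()
        assert band < rim < interior < background

    def test_inversion_flag_flips_polarity(self):
        beads = [BeadSpec(128, 128, 560)]
        spec = SceneSpec(256, 256, 4.0, "brightfield", noise_sd=0.0, seed=0)
        inv = SceneSpec(256, 256, 4.0, "brightfield", noise_sd=0.0, seed=0,
                        invert=True)
        a = render_brightfield_scene(spec, beads)[0].image
        b = render_brightfield_scene(inv, beads)[0].image
        assert np.allclose(a + b, 1.0)


class TestRenderFluorescence:
    def _one_bead(self, f, noise_sd=0.01, seed=5):
        spec = SceneSpec(320, 320, 4.0, "fluorescence", noise_sd=noise_sd,
                         background_level=0.9, seed=seed)
        bead = BeadSpec(160, 160, 624, permeation_fraction=f)
        return render_fluorescence_scene(spec, [bead])

    def test_fully_permeable_interior_matches_background(self):
        scene, _ = self._one_bead(1.0)
        yy, xx = np.mgrid[0:320, 0:320]
        dist = np.hypot(xx - 160, yy - 160)
        interior = scene.image[dist < 40]
        exterior = scene.image[dist > 100]
        pooled_se = 0.01 * math.sqrt(1 / interior.size + 1 / exterior.size)
        assert abs(interior.mean() - exterior.mean()) < 3 * pooled_se

    def test_impermeable_interior_at_dark_floor(self):
        scene, _ = self._one_bead(0.0)
        yy, xx = np.mgrid[0:320, 0:320]
        dist = np.hypot(xx - 160, yy - 160)
        interior = scene.image[dist < 40]
        assert interior.mean() == pytest.approx(0.02, abs=3 * 0.01 / 40)

    def test_half_permeation_center_exact(self, fluorescence_half_permeable):
        _, _, scene, _ = fluorescence_half_permeable
        # noiseless: center intensity exactly (dark_floor + background)/2
        assert scene.image[160, 160] == pytest.approx((0.02 + 0.9) / 2,
                                                      abs=1e-12)

    def test_missing_permeation_fraction_rejected(self):
        spec = SceneSpec(320, 320, 4.0, "fluorescence", seed=0)
        with pytest.raises(ValueError, match="permeation_fraction"):
            render_fluorescence_scene(spec, [BeadSpec(160, 160, 600)])


class TestGroundTruth:
    def test_coverage_fraction_matches_arc_sum(self):
        arcs = (ArcSpec(10, 100), ArcSpec(180, 271.5))
        bead = BeadSpec(160, 160, 600, overgrowth_arcs=arcs)
        expected = (90 + 91.5) / 360
        assert bead.coverage_fraction == pytest.approx(expected, abs=1e-9)
        spec = SceneSpec(320, 320, 4.0, "brightfield", seed=0)
        _, truth = render_brightfield_scene(spec, [bead])
        assert truth.beads[0].coverage_fraction == pytest.approx(expected,
                                                                 abs=1e-9)

    def test_record_count_matches_beads(self):
        spec = SceneSpec(640, 320, 4.0, "brightfield", seed=0)
        beads = [BeadSpec(160, 160, 560), BeadSpec(470, 160, 560)]
        _, truth = render_brightfield_scene(spec, beads)
        assert len(truth.beads) == 2

    def test_roundtrip_through_dict(self):
        spec = SceneSpec(320, 320, 4.0, "brightfield", seed=9)
        _, truth = render_brightfield_scene(spec, [BeadSpec(160, 160, 560)])
        from beadmetrics.scenes import GroundTruth
        again = GroundTruth.from_dict(truth.to_dict())
        assert again == truth


class TestBeadSpecValidation:
    def test_spheroid_outside_disk_rejected(self):
        with pytest.raises(ValueError, match="spheroid"):
            BeadSpec(0, 0, 300, spheroid_specs=(SpheroidSpec(120, 0, 150),))

    def test_overlapping_arcs_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            BeadSpec(0, 0, 600,
                     overgrowth_arcs=(ArcSpec(0, 100), ArcSpec(50, 150)))

    def test_diameter_range_enforced(self):
        with pytest.raises(ValueError):
            BeadSpec(0, 0, 60)
        with pytest.raises(ValueError):
            BeadSpec(0, 0, 1200)


class TestSampleBeadPopulation:
    def test_degenerate_draw_exact_mean(self):
        beads = sample_bead_population(1, 650, 0.0, 0.0, seed=1)
        assert len(beads) == 1
        assert beads[0].diameter_um == 650

    def test_sample_mean_near_population_mean(self):
        # 699 +/- 17 um batch: sample mean within 3 sigma/sqrt(n)
        beads = sample_bead_population(
            200, 699, 17, 0.0, seed=42,
            image_width_px=4608, image_height_px=4608, max_attempts=100000)
        d = np.array([b.diameter_um for b in beads])
        assert abs(d.mean() - 699) < 3 * 17 / math.sqrt(200)

    def test_zero_spheroid_rate(self):
        beads = sample_bead_population(5, 600, 30, 0.0, seed=3)
        assert all(len(b.spheroid_specs) == 0 for b in beads)

    def test_spheroids_inside_and_counted(self):
        beads = sample_bead_population(5, 700, 20, 2.0, seed=4)
        assert any(len(b.spheroid_specs) > 0 for b in beads)
        # validity enforced by BeadSpec __post_init__ already ran

    def test_placement_failure_names_achieved_count(self):
        with pytest.raises(RuntimeError, match=r"placed only \d+ of 50"):
            sample_bead_population(50, 700, 10, 0.0, seed=5,
                                   image_width_px=1024, image_height_px=1024,
                                   max_attempts=300)

    def test_deterministic_per_seed(self):
        a = sample_bead_population(6, 620, 40, 1.0, seed=8)
        b = sample_bead_population(6, 620, 40, 1.0, seed=8)
        assert a == b
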