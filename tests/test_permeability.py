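"""Permeability readout: ROI means, background, two-anchor normalization."""

import numpy as np
import pytest

from beadmetrics import (BeadSpec, DetectedBead, SceneSpec, Scene,
                         background_intensity, center_intensity,
                         compare_groups_permeability, detect_beads,
                         normalize_permeation, render_fluorescence_scene)
from beadmetrics.permeability import measure_scene_permeability
from conftest import make_detected

PS = 4.0

LADDER = (("4 kDa", 1.0), ("70 kDa", 0.75), ("150 kDa", 0.45),
          ("500 kDa", 0.2), ("2 MDa", 0.0))


def render_ladder(seed, noise_sd=0.01, use_detection=True):
    """One scene per probe; returns probe -> mean raw ratio."""
    ratios = {}
    for i, (probe, frac) in enumerate(LADDER):
        spec = SceneSpec(320, 320, PS, "fluorescence", noise_sd=noise_sd,
                         background_level=0.9, seed=seed * 10 + i)
        bead = BeadSpec(160, 160, 624, permeation_fraction=frac)
        scene, _ = render_fluorescence_scene(spec, [bead])
        beads = detect_beads(scene) if use_detection else [make_detected(bead)]
        assert beads, f"probe {probe} bead not detected"
        recs = measure_scene_permeability(scene, beads[:1], probe)
        ratios[probe] = recs[0].raw_ratio
    return ratios


class TestCenterIntensity:
    def test_half_permeation_linear_construction(self,
                                                 fluorescence_half_permeable):
        _, bead, scene, _ = fluorescence_half_permeable
        val = center_intensity(scene, make_detected(bead))
        assert val == pytest.approx(0.46, abs=1e-9)

    def test_roi_size_irrelevant_on_uniform_interior(
            self, fluorescence_half_permeable):
        _, bead, scene, _ = fluorescence_half_permeable
        d = make_detected(bead)
        assert center_intensity(scene, d, 0.5) == pytest.approx(
            center_intensity(scene, d, 0.1), abs=1e-6)

    def test_full_permeation_matches_background(self):
        spec = SceneSpec(320, 320, PS, "fluorescence", noise_sd=0.01,
                         background_level=0.9, seed=3)
        bead = BeadSpec(160, 160, 624, permeation_fraction=1.0)
        scene, _ = render_fluorescence_scene(spec, [bead])
        d = make_detected(bead)
        center = center_intensity(scene, d)
        bg = background_intensity(scene, [d])
        assert abs(center - bg) < 0.01

    def test_invalid_roi_fraction(self, fluorescence_half_permeable):
        _, bead, scene, _ = fluorescence_half_permeable
        with pytest.raises(ValueError):
            center_intensity(scene, make_detected(bead), 0.9)


class TestBackgroundIntensity:
    def test_no_beads_global_mean(self):
        img = np.random.default_rng(0).uniform(0.5, 0.9, (128, 128))
        scene = Scene(img, PS, "fluorescence")
        assert background_intensity(scene, []) == pytest.approx(img.mean())

    def test_single_bead_background_recovered(self):
        spec = SceneSpec(512, 512, PS, "fluorescence", noise_sd=0.01,
                         background_level=0.9, seed=4)
        bead = BeadSpec(256, 256, 700, permeation_fraction=0.3)
        scene, _ = render_fluorescence_scene(spec, [bead])
        bg = background_intensity(scene, [make_detected(bead)])
        n_bg = 512 * 512 * 0.5  # conservative pixel count after exclusion
        assert abs(bg - 0.9) < 3 * 0.01 / np.sqrt(n_bg) + 1e-4

    def test_insufficient_background_errors(self):
        scene = Scene(np.full((128, 128), 0.9), PS, "fluorescence")
        big = DetectedBead(64, 64, 200, 200 * 2 * PS, 1.0)
        with pytest.raises(ValueError, match="background"):
            background_intensity(scene, [big])


class TestNormalizePermeation:
    def test_linear_interpolation_example(self):
        out = normalize_permeation(
            {"4 kDa": 0.95, "150 kDa": 0.50, "2 MDa": 0.05})
        assert out["4 kDa"] == 100.0
        assert out["2 MDa"] == 0.0
        assert out["150 kDa"] == pytest.approx(50.0)

    def test_anchor_exactness_and_clamping(self):
        out = normalize_permeation(
            {"4 kDa": 0.91, "x": 0.91, "below": 0.01, "2 MDa": 0.03})
        assert out["4 kDa"] == 100.0 and out["x"] == 100.0
        assert out["below"] == 0.0  # clamped below the low anchor

    def test_inverted_anchors_error(self):
        with pytest.raises(ValueError, match="inverted"):
            normalize_permeation({"4 kDa": 0.1, "2 MDa": 0.9})

    def test_missing_anchor_error(self):
        with pytest.raises(ValueError, match="anchor"):
            normalize_permeation({"4 kDa": 0.9, "70 kDa": 0.5})


class TestCompareGroups:
    def test_identical_groups_null(self):
        res = compare_groups_permeability([50.0, 60.0, 70.0],
                                          [50.0, 60.0, 70.0])
        assert res.t_statistic == 0.0
        assert res.p_two_sided == pytest.approx(1.0)

    def test_single_sample_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups_permeability([50.0], [40.0, 60.0])

    def test_three_sd_separation_detected_reliably(self):
        # groups 3 pooled SDs apart at n = 11: significant in >= 95% of reps
        rng = np.random.default_rng(99)
        hits = 0
        n_reps = 500
        for _ in range(n_reps):
            a = rng.normal(50, 5, 11)
            b = rng.normal(65, 5, 11)
            if compare_groups_permeability(b, a).p_two_sided < 0.05:
                hits += 1
        assert hits / n_reps >= 0.95


class TestEndToEndLadder:
    def test_recovery_within_five_points(self):
        ratios = render_ladder(seed=21)
        out = normalize_permeation(ratios)
        for probe, frac in LADDER:
            assert abs(out[probe] - 100 * frac) <= 5.0

    def test_monotone_in_probe_size(self):
        # strictly decreasing true fractions -> non-increasing estimates
        violations = 0
        for seed in range(8):
            out = normalize_permeation(render_ladder(seed=50 + seed))
            vals = [out[p] for p, _ in LADDER]
            violations += sum(1 for a, b in zip(vals, vals[1:]) if b > a + 1e-9)
        assert violations <= 1

    def test_global_rescale_invariance(self):
        # multiplying every scene in a ladder by a gain leaves the normalized
        # percentages unchanged
        out1, out2 = {}, {}
        for gain, out in ((1.0, out1), (0.4, out2)):
            ratios = {}
            for i, (probe, frac) in enumerate(LADDER):
                spec = SceneSpec(320, 320, PS, "fluorescence", noise_sd=0.005,
                                 background_level=0.9, seed=770 + i)
                bead = BeadSpec(160, 160, 624, permeation_fraction=frac)
                scene, _ = render_fluorescence_scene(spec, [bead])
                scene = Scene(gain * scene.image, PS, "fluorescence")
                rec = measure_scene_permeability(scene, [make_detected(bead)],
                                                 probe)[0]
                ratios[probe] = rec.raw_ratio
            out.update(normalize_permeation(ratios))
        for p, _ in LADDER:
            assert out1[p] == pytest.approx(out2[p], abs=1e-9)
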