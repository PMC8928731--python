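"""Seeded study-condition drivers: reference synthetic experiments.

Each function renders a full synthetic experiment under the study conditions
the package targets (bead geometry, group sizes, imaging noise), runs the
relevant pipeline stages end-to-end — rendering, detection, measurement,
summarization — and returns both the measured quantities and the ground
truth.  They are the single source of the reference experiments used by the
test suite and the reproduction script.

Problem sizes: benchmark fields are 1024 x 1024 px at 4 um/px (a ~4.1 mm
square field, comfortably holding eight ~600-um beads), and imaging noise is
1-2% of dynamic range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .detection import DetectionConfig, detect_beads
from .morphometry import population_stats
from .permeability import (background_mean_sd, measure_scene_permeability,
                           normalize_permeation)
from .pfo import PFORecord, bin_coverage, perimeter_coverage, summarize_cohort
from .pipeline import evaluate_against_truth, match_detections
from .scenes import (ArcSpec, BeadSpec, SceneSpec, render_brightfield_scene,
                     render_fluorescence_scene, sample_bead_population)

__all__ = [
    "LADDER_FRACTIONS",
    "place_centers",
    "render_pfo_cohort",
    "score_pfo_cohort",
    "run_permeability_ladder",
    "detection_benchmark",
    "population_recovery",
]

FIELD_PX = 1024
PIXEL_SIZE_UM = 4.0

# Probe ladder: FITC-dextran sizes with the true permeation fraction each
# condition renders (anchors fully open / fully excluded).
LADDER_FRACTIONS = {
    "4 kDa": 1.0,
    "70 kDa": 0.75,
    "150 kDa": 0.45,
    "500 kDa": 0.2,
    "2 MDa": 0.0,
}


def place_centers(radii_px: list[float], width_px: int, height_px: int,
                  rng: np.random.Generator, margin_px: float = 10.0,
                  max_attempts: int = 50000) -> list[tuple[float, float]]:
    """Rejection-sample non-overlapping centers for the given radii."""
    centers: list[tuple[float, float]] = []
    attempts = 0
    for r in radii_px:
        edge = r + margin_px
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"placed only {len(centers)} of {len(radii_px)} beads")
            cx = rng.uniform(edge, width_px - 1 - edge)
            cy = rng.uniform(edge, height_px - 1 - edge)
            if all(math.hypot(cx - x, cy - y) > r + rr + margin_px
                   for (x, y), rr in zip(centers, radii_px)):
                break
        centers.append((cx, cy))
    return centers


def _chunk(seq, size):
    for i in range(0, len(seq), size):
        yield seq[i:i + size]


def render_pfo_cohort(coverages: list[float], seed: int,
                      diameter_um: float = 560.0, noise_sd: float = 0.01,
                      beads_per_scene: int = 7):
    """Brightfield scenes for one explant cohort with given true coverages.

    Each bead carries a single contiguous overgrowth arc spanning the
    requested perimeter fraction at a random start angle.  Returns a list of
    (scene, truth) pairs.
    """
    rng = np.random.default_rng(seed)
    out = []
    for k, chunk in enumerate(_chunk(list(coverages), beads_per_scene)):
        arc_extent = 40.0 * 1.3  # band width x max fringe jitter, um
        radii_px = [(diameter_um / 2 + arc_extent) / PIXEL_SIZE_UM] * len(chunk)
        centers = place_centers(radii_px, FIELD_PX, FIELD_PX, rng,
                                margin_px=12.0)
        beads = []
        for cov, (cx, cy) in zip(chunk, centers):
            arcs = ()
            if cov > 0:
                span = 360.0 * min(cov, 1.0)
                start = rng.uniform(0.0, 360.0 - span) if span < 360 else 0.0
                arcs = (ArcSpec(start, start + span),)
            beads.append(BeadSpec(cx, cy, diameter_um, overgrowth_arcs=arcs))
        spec = SceneSpec(FIELD_PX, FIELD_PX, PIXEL_SIZE_UM, "brightfield",
                         noise_sd=noise_sd, seed=int(seed + 1000 * k + 1))
        out.append(render_brightfield_scene(spec, beads,
                                            scene_id=f"pfo_{seed}_{k}"))
    return out


def score_pfo_cohort(scene_truth_pairs, group_label: str,
                     config: DetectionConfig = DetectionConfig()):
    """Detect, score and bin every bead of a rendered cohort.

    Returns (CohortSummary, records, coverage_errors) where coverage_errors
    are |estimated - true| for detections matched to ground truth.
    """
    records: list[PFORecord] = []
    errors: list[float] = []
    bead_id = 0
    for scene, truth in scene_truth_pairs:
        detections = detect_beads(scene, config)
        # background statistics must exclude every bead in the field, not
        # just the one being scored
        bg_stats = background_mean_sd(scene, detections)
        pairs, _, _ = match_detections(detections, truth.beads)
        for det_i, truth_j, _ in pairs:
            cov = perimeter_coverage(scene, detections[det_i],
                                     background_stats=bg_stats)
            records.append(PFORecord(bead_id, cov, bin_coverage(cov)))
            errors.append(abs(cov - truth.beads[truth_j].coverage_fraction))
            bead_id += 1
    summary = summarize_cohort(records, group_label)
    return summary, records, errors


def run_permeability_ladder(seed: int, n_beads_per_probe: int = 11,
                            noise_sd: float = 0.01,
                            fractions: dict[str, float] | None = None,
                            diameter_um: float = 624.0):
    """Render one fluorescence scene per probe and normalize the ladder.

    Returns (normalized percentages by probe, mean raw ratios by probe,
    per-probe bead counts actually measured).
    """
    fractions = dict(LADDER_FRACTIONS if fractions is None else fractions)
    rng = np.random.default_rng(seed)
    mean_ratios: dict[str, float] = {}
    n_measured: dict[str, int] = {}
    for i, (probe, frac) in enumerate(fractions.items()):
        radii_px = [diameter_um / 2 / PIXEL_SIZE_UM] * n_beads_per_probe
        centers = place_centers(radii_px, FIELD_PX, FIELD_PX, rng,
                                margin_px=12.0)
        beads = [BeadSpec(cx, cy, diameter_um, permeation_fraction=frac)
                 for cx, cy in centers]
        spec = SceneSpec(FIELD_PX, FIELD_PX, PIXEL_SIZE_UM, "fluorescence",
                         noise_sd=noise_sd, background_level=0.9,
                         seed=int(seed + 131 * i + 7))
        scene, _ = render_fluorescence_scene(spec, beads,
                                             scene_id=f"perm_{probe}")
        detections = detect_beads(scene)
        recs = measure_scene_permeability(scene, detections, probe)
        if not recs:
            raise RuntimeError(f"no beads measured for probe {probe}")
        mean_ratios[probe] = float(np.mean([r.raw_ratio for r in recs]))
        n_measured[probe] = len(recs)
    normalized = normalize_permeation(mean_ratios)
    return normalized, mean_ratios, n_measured


def detection_benchmark(n_scenes: int = 50, seed: int = 0,
                        noise_sd: float = 0.02,
                        diameter_mean_um: float = 600.0,
                        diameter_sd_um: float = 60.0) -> dict:
    """Precision/recall/diameter-error suite over seeded multi-bead scenes.

    Scenes hold 1-8 non-overlapping beads each; matching radius is 5 px.
    """
    rng = np.random.default_rng(seed)
    n_det = n_truth = n_match = 0
    diam_errors: list[float] = []
    for k in range(n_scenes):
        n_beads = int(rng.integers(1, 9))
        beads = sample_bead_population(
            n_beads, diameter_mean_um, diameter_sd_um, 0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
            image_width_px=FIELD_PX, image_height_px=FIELD_PX,
            pixel_size_um=PIXEL_SIZE_UM)
        spec = SceneSpec(FIELD_PX, FIELD_PX, PIXEL_SIZE_UM, "brightfield",
                         noise_sd=noise_sd, seed=int(rng.integers(0, 2**31 - 1)))
        scene, truth = render_brightfield_scene(spec, beads)
        detections = detect_beads(scene)
        pairs, _, _ = match_detections(detections, truth.beads)
        n_det += len(detections)
        n_truth += len(truth.beads)
        n_match += len(pairs)
        diam_errors += [abs(detections[i].diameter_um
                            - truth.beads[j].diameter_um)
                        for i, j, _ in pairs]
    return {
        "n_scenes": n_scenes,
        "n_truth": n_truth,
        "n_detections": n_det,
        "precision": n_match / n_det if n_det else 0.0,
        "recall": n_match / n_truth if n_truth else 0.0,
        "diameter_mae_um": float(np.mean(diam_errors)) if diam_errors else float("nan"),
        "diameter_max_error_um": float(np.max(diam_errors)) if diam_errors else float("nan"),
    }


def population_recovery(n_beads: int = 200, diameter_mean_um: float = 699.0,
                        diameter_sd_um: float = 17.0, seed: int = 0,
                        noise_sd: float = 0.01, beads_per_scene: int = 8) -> dict:
    """Recover a batch's size distribution end-to-end from rendered scenes.

    Draws the full population, renders it across multi-bead fields, detects
    and measures every bead, and compares the detected population mean with
    the sample ground truth.
    """
    rng = np.random.default_rng(seed)
    detected = []
    truth_diams: list[float] = []
    remaining = n_beads
    while remaining > 0:
        k = min(beads_per_scene, remaining)
        beads = sample_bead_population(
            k, diameter_mean_um, diameter_sd_um, 0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
            image_width_px=FIELD_PX, image_height_px=FIELD_PX,
            pixel_size_um=PIXEL_SIZE_UM)
        spec = SceneSpec(FIELD_PX, FIELD_PX, PIXEL_SIZE_UM, "brightfield",
                         noise_sd=noise_sd, seed=int(rng.integers(0, 2**31 - 1)))
        scene, truth = render_brightfield_scene(spec, beads)
        detections = detect_beads(scene)
        pairs, _, _ = match_detections(detections, truth.beads)
        detected += [detections[i] for i, _, _ in pairs]
        truth_diams += [b.diameter_um for b in truth.beads]
        remaining -= k
    stats = population_stats(detected, include_satellites=True)
    sample_mean = float(np.mean(truth_diams))
    return {
        "n_rendered": n_beads,
        "n_detected": stats.n_beads,
        "sample_truth_mean_um": sample_mean,
        "detected_mean_um": stats.mean_diameter_um,
        "detected_sd_um": stats.sd_diameter_um,
        "mean_abs_error_um": abs(stats.mean_diameter_um - sample_mean),
    }
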