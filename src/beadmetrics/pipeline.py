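"""End-to-end orchestration: simulate -> detect -> measure -> summarize.

A run is driven by a single JSON-serializable configuration document with
per-stage blocks, executed in dependency order, and recorded in a manifest
(seed, config hash, per-stage outputs).  Re-running an identical config and
seed reproduces all CSV/JSON outputs bit-identically.

The module also provides the ground-truth evaluation harness used to score
synthetic runs: greedy nearest-first matching of detections to true beads
within a fixed pixel radius, then precision/recall and per-quantity error
summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .detection import DetectionConfig, detect_beads, flag_malformed, flag_satellites
from .io import save_ground_truth, save_scene
from .morphometry import SpheroidCountConfig, count_spheroids, population_stats
from .permeability import (background_mean_sd, measure_scene_permeability,
                           normalize_permeation)
from .pfo import PFORecord, bin_coverage, perimeter_coverage, summarize_cohort
from .scenes import (ArcSpec, BeadSpec, GroundTruth, Scene, SceneSpec,
                     render_brightfield_scene, render_fluorescence_scene,
                     sample_bead_population)
from .stats import sample_size_two_sample_t, welch_from_summary

__all__ = [
    "ConfigError",
    "StageError",
    "run_pipeline",
    "evaluate_against_truth",
    "match_detections",
    "simulate_scene_from_config",
]

logger = logging.getLogger("beadmetrics")

_STAGE_ORDER = ("simulate", "detect", "morphometry", "permeability", "pfo", "stats")


class ConfigError(ValueError):
    """Raised before any stage runs when the configuration is invalid."""


class StageError(RuntimeError):
    """Raised when a pipeline stage fails after the run has started."""


def _config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()


def validate_config(config: dict) -> None:
    """Schema-level validation; raises ConfigError before any stage runs."""
    if not isinstance(config, dict):
        raise ConfigError("config must be a JSON object")
    if "seed" not in config or not isinstance(config["seed"], int):
        raise ConfigError("config requires an integer 'seed'")
    stages = config.get("stages")
    if not isinstance(stages, dict) or not stages:
        raise ConfigError("config requires a non-empty 'stages' object")
    unknown = set(stages) - set(_STAGE_ORDER)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    if not isinstance(config.get("pixel_size_um", 4.0), (int, float)):
        raise ConfigError("pixel_size_um must be a number")
    if stages.get("simulate") and not isinstance(config.get("simulate"), dict):
        raise ConfigError("'simulate' stage enabled but no 'simulate' block")
    for name in _STAGE_ORDER[1:]:
        if stages.get(name) and name in config and not isinstance(config[name], dict):
            raise ConfigError(f"'{name}' block must be an object")


def simulate_scene_from_config(block: dict, pixel_size_um: float,
                               seed: int) -> tuple[Scene, GroundTruth]:
    """Render one scene from its JSON description.

    The block carries the scene geometry plus either an explicit ``beads``
    list (BeadSpec fields; spheroids as [offset_x_um, offset_y_um,
    diameter_um] triples, arcs as [start_deg, end_deg, band_width_um,
    contrast]) or a ``population`` block for
    :func:`~beadmetrics.scenes.sample_bead_population`.
    """
    modality = block.get("modality", "brightfield")
    spec = SceneSpec(
        image_width_px=int(block.get("image_width_px", 1024)),
        image_height_px=int(block.get("image_height_px", 1024)),
        pixel_size_um=pixel_size_um,
        modality=modality,
        noise_sd=float(block.get("noise_sd", 0.01)),
        background_level=float(block.get("background_level", 0.85)),
        seed=int(block.get("seed", seed)),
        dark_floor=float(block.get("dark_floor", 0.02)),
        invert=bool(block.get("invert", False)),
    )
    if "beads" in block:
        beads = []
        for b in block["beads"]:
            spheroids = tuple(
                _spheroid_from_json(s) for s in b.get("spheroid_specs", []))
            arcs = tuple(ArcSpec(*a) for a in b.get("overgrowth_arcs", []))
            beads.append(BeadSpec(
                center_x_px=float(b["center_x_px"]),
                center_y_px=float(b["center_y_px"]),
                diameter_um=float(b["diameter_um"]),
                rim_width_um=float(b.get("rim_width_um", 32.0)),
                rim_contrast=float(b.get("rim_contrast", 0.35)),
                spheroid_specs=spheroids,
                permeation_fraction=b.get("permeation_fraction"),
                overgrowth_arcs=arcs,
                rim_gap_arcs=tuple(tuple(g) for g in b.get("rim_gap_arcs", [])),
            ))
    elif "population" in block:
        p = block["population"]
        beads = sample_bead_population(
            n=int(p["n"]),
            diameter_mean_um=float(p["diameter_mean_um"]),
            diameter_sd_um=float(p["diameter_sd_um"]),
            spheroid_rate=float(p.get("spheroid_rate", 0.0)),
            seed=int(p.get("seed", seed)),
            image_width_px=spec.image_width_px,
            image_height_px=spec.image_height_px,
            pixel_size_um=pixel_size_um,
        )
        if "permeation_fraction" in p:
            from dataclasses import replace as _replace
            beads = [_replace(b, permeation_fraction=float(p["permeation_fraction"]))
                     for b in beads]
    else:
        beads = []
    renderer = (render_brightfield_scene if modality == "brightfield"
                else render_fluorescence_scene)
    return renderer(spec, beads, scene_id=str(block.get("scene_id", "")))


def _spheroid_from_json(s):
    from .scenes import SpheroidSpec
    if isinstance(s, dict):
        return SpheroidSpec(**s)
    return SpheroidSpec(*s)


def _beads_to_frame(scene_id: str, beads) -> pd.DataFrame:
    return pd.DataFrame([
        {"scene_id": scene_id, "bead_id": i,
         "cx_px": b.center_x_px, "cy_px": b.center_y_px,
         "diameter_um": b.diameter_um, "score": b.accumulator_score,
         "malformed": b.malformed_flag, "satellite": b.satellite_flag}
        for i, b in enumerate(beads)
    ], columns=["scene_id", "bead_id", "cx_px", "cy_px", "diameter_um",
                "score", "malformed", "satellite"])


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config["seed"]
    ps = float(config.get("pixel_size_um", 4.0))
    stages = config["stages"]
    manifest: dict[str, Any] = {
        "beadmetrics_version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "pixel_size_um": ps,
        "stages": {},
        "status": "running",
    }

    scenes: dict[str, Scene] = {}
    truths: dict[str, GroundTruth] = {}
    detections: dict[str, list] = {}

    try:
        if stages.get("simulate"):
            paths = []
            scene_blocks = config["simulate"]["scenes"]
            for i, block in enumerate(scene_blocks):
                block = dict(block)
                block.setdefault("scene_id", f"scene_{i:03d}")
                block.setdefault("seed", seed + i)
                scene, truth = simulate_scene_from_config(block, ps, seed + i)
                sid = scene.scene_id
                scenes[sid], truths[sid] = scene, truth
                img_path = save_scene(scene, out / f"{sid}.tif")
                gt_path = save_ground_truth(truth, out / f"{sid}.json")
                paths += [img_path.name, gt_path.name]
                logger.info("simulate[seed=%d]: rendered %s", seed, sid)
            manifest["stages"]["simulate"] = {"outputs": paths,
                                              "n_scenes": len(scene_blocks)}

        if stages.get("detect"):
            det_cfg = DetectionConfig(**config.get("detect", {}).get("config", {}))
            sat_um = config.get("detect", {}).get("satellite_max_diameter_um", 200.0)
            support = config.get("detect", {}).get("min_edge_support", 0.8)
            frames = []
            for sid, scene in scenes.items():
                beads = detect_beads(scene, det_cfg)
                flag_satellites(beads, sat_um)
                flag_malformed(scene, beads, support, det_cfg)
                detections[sid] = beads
                frames.append(_beads_to_frame(sid, beads))
                logger.info("detect[seed=%d]: %s -> %d beads", seed, sid, len(beads))
            beads_csv = out / "beads.csv"
            pd.concat(frames, ignore_index=True).to_csv(
                beads_csv, index=False, float_format="%.6f")
            manifest["stages"]["detect"] = {"outputs": [beads_csv.name]}

        if stages.get("morphometry"):
            blk = config.get("morphometry", {})
            all_beads = [b for sid in sorted(detections) for b in detections[sid]]
            stats = population_stats(
                all_beads, bin_width_um=blk.get("bin_width_um", 10.0),
                include_satellites=blk.get("include_satellites", False))
            sph_cfg = SpheroidCountConfig(**blk.get("spheroid_config", {}))
            rows = []
            for sid in sorted(detections):
                if scenes[sid].modality != "brightfield":
                    continue
                for i, b in enumerate(detections[sid]):
                    rows.append({"scene_id": sid, "bead_id": i,
                                 "spheroid_count": count_spheroids(
                                     scenes[sid], b, sph_cfg)})
            stats_path = out / "stats.json"
            stats_path.write_text(json.dumps(asdict(stats), indent=1))
            sph_path = out / "spheroids.csv"
            pd.DataFrame(rows, columns=["scene_id", "bead_id", "spheroid_count"]
                         ).to_csv(sph_path, index=False)
            manifest["stages"]["morphometry"] = {
                "outputs": [stats_path.name, sph_path.name]}

        if stages.get("permeability"):
            blk = config.get("permeability", {})
            ladder = blk.get("ladder", {})  # scene_id -> {probe, timepoint_h}
            records = []
            for sid, meta in ladder.items():
                if sid not in scenes:
                    raise StageError(f"permeability: unknown scene {sid!r}")
                records += measure_scene_permeability(
                    scenes[sid], detections.get(sid, []),
                    probe_label=meta["probe"],
                    timepoint_h=float(meta.get("timepoint_h", 1.0)),
                    roi_fraction=blk.get("roi_fraction", 0.2))
            ratios = {}
            for rec in records:
                ratios.setdefault(rec.probe_label, []).append(rec.raw_ratio)
            mean_ratios = {p: float(np.mean(v)) for p, v in ratios.items()}
            normalized = normalize_permeation(
                mean_ratios, blk.get("anchor_low", "4 kDa"),
                blk.get("anchor_high", "2 MDa"))
            for rec in records:
                rec.normalized_permeation_pct = normalized[rec.probe_label]
            perm_csv = out / "permeability.csv"
            pd.DataFrame([asdict(r) for r in records]).to_csv(
                perm_csv, index=False, float_format="%.6f")
            norm_json = out / "permeation_normalized.json"
            norm_json.write_text(json.dumps(normalized, indent=1, sort_keys=True))
            manifest["stages"]["permeability"] = {
                "outputs": [perm_csv.name, norm_json.name]}

        if stages.get("pfo"):
            blk = config.get("pfo", {})
            group_map = blk.get("group_map", {})  # scene_id -> group label
            per_group: dict[str, list[PFORecord]] = {}
            rows = []
            for sid, group in group_map.items():
                if sid not in scenes:
                    raise StageError(f"pfo: unknown scene {sid!r}")
                scene_beads = detections.get(sid, [])
                bg_stats = background_mean_sd(scenes[sid], scene_beads)
                for i, bead in enumerate(scene_beads):
                    cov = perimeter_coverage(
                        scenes[sid], bead,
                        band_width_fraction=blk.get("band_width_fraction", 0.15),
                        n_rays=blk.get("n_rays", 360),
                        dark_threshold_k=blk.get("dark_threshold_k", 3.0),
                        background_stats=bg_stats)
                    rec = PFORecord(i, cov, bin_coverage(cov))
                    per_group.setdefault(group, []).append(rec)
                    rows.append({"scene_id": sid, "bead_id": i, "group": group,
                                 "coverage_fraction": cov,
                                 "coverage_category": rec.coverage_category})
            pfo_csv = out / "pfo.csv"
            pd.DataFrame(rows).to_csv(pfo_csv, index=False, float_format="%.6f")
            summaries = {g: asdict(summarize_cohort(recs, g))
                         for g, recs in sorted(per_group.items())}
            summary_json = out / "pfo_summary.json"
            summary_json.write_text(json.dumps(summaries, indent=1, sort_keys=True))
            manifest["stages"]["pfo"] = {
                "outputs": [pfo_csv.name, summary_json.name]}

        if stages.get("stats"):
            blk = config.get("stats", {})
            results = {}
            for name, w in blk.get("welch_from_summary", {}).items():
                res = welch_from_summary(w["mean1"], w["sd1"], int(w["n1"]),
                                         w["mean2"], w["sd2"], int(w["n2"]))
                results[name] = asdict(res)
            for name, p in blk.get("sample_size", {}).items():
                results[name] = {"n_per_group": sample_size_two_sample_t(
                    p["effect_size_d"], p.get("alpha", 0.05),
                    p.get("power", 0.8), p.get("two_sided", True))}
            stats_json = out / "stat_tests.json"
            stats_json.write_text(json.dumps(results, indent=1, sort_keys=True))
            manifest["stages"]["stats"] = {"outputs": [stats_json.name]}

    except ConfigError:
        raise
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise StageError(str(exc)) from exc

    manifest["status"] = "complete"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def match_detections(detections, truth_beads, match_radius_px: float = 5.0):
    """Greedy nearest-first one-to-one matching of detections to true beads.

    Returns (pairs, unmatched_detection_idx, unmatched_truth_idx) where pairs
    is a list of (detection_idx, truth_idx, distance_px).
    """
    candidates = []
    for i, d in enumerate(detections):
        for j, t in enumerate(truth_beads):
            dist = float(np.hypot(d.center_x_px - t.center_x_px,
                                  d.center_y_px - t.center_y_px))
            if dist <= match_radius_px:
                candidates.append((dist, i, j))
    candidates.sort()
    used_d, used_t, pairs = set(), set(), []
    for dist, i, j in candidates:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        pairs.append((i, j, dist))
    unmatched_d = [i for i in range(len(detections)) if i not in used_d]
    unmatched_t = [j for j in range(len(truth_beads)) if j not in used_t]
    return pairs, unmatched_d, unmatched_t


def evaluate_against_truth(detections, ground_truth: GroundTruth,
                           spheroid_counts=None, permeation_pcts=None,
                           coverage_fractions=None,
                           match_radius_px: float = 5.0) -> dict:
    """Score pipeline outputs against the generator's ground truth.

    ``spheroid_counts``, ``permeation_pcts`` and ``coverage_fractions`` are
    optional per-detection sequences aligned with ``detections``; metrics for
    absent components are omitted from the report.
    """
    if ground_truth is None or not ground_truth.beads:
        raise ValueError("ground truth is required for evaluation")
    truth_beads = ground_truth.beads
    pairs, unmatched_d, unmatched_t = match_detections(
        detections, truth_beads, match_radius_px)
    n_det, n_truth, n_match = len(detections), len(truth_beads), len(pairs)
    report = {
        "n_detections": n_det,
        "n_truth": n_truth,
        "n_matched": n_match,
        "precision": n_match / n_det if n_det else 0.0,
        "recall": n_match / n_truth if n_truth else 0.0,
    }
    if pairs:
        diam_err = [abs(detections[i].diameter_um - truth_beads[j].diameter_um)
                    for i, j, _ in pairs]
        report["diameter_mae_um"] = float(np.mean(diam_err))
        if spheroid_counts is not None:
            hits = [spheroid_counts[i] == truth_beads[j].spheroid_count
                    for i, j, _ in pairs]
            report["spheroid_exact_match_rate"] = float(np.mean(hits))
        if permeation_pcts is not None:
            errs = [abs(permeation_pcts[i] - 100.0 * truth_beads[j].permeation_fraction)
                    for i, j, _ in pairs
                    if permeation_pcts[i] is not None
                    and truth_beads[j].permeation_fraction is not None]
            if errs:
                report["permeation_mae_pct"] = float(np.mean(errs))
        if coverage_fractions is not None:
            errs = [abs(coverage_fractions[i] - truth_beads[j].coverage_fraction)
                    for i, j, _ in pairs if coverage_fractions[i] is not None]
            if errs:
                report["coverage_mae"] = float(np.mean(errs))
    return report
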