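"""FITC-dextran permeability readout for alginate microbeads.

A bead's permeability to a fluorescent probe of a given molecular weight is
read semi-quantitatively as the ratio of the mean fluorescence in a central
disk ROI of the bead to the mean fluorescence of the bead-free background
(the probe solution).  Per-probe mean ratios are then placed on a 0–100%
permeation scale by two-anchor normalization: the smallest probe of the
ladder (4 kDa dextran, which fully equilibrates) defines 100% and the largest
(2 MDa, fully excluded) defines 0%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import DetectedBead
from .scenes import Scene
from .stats import WelchResult, welch_from_samples

__all__ = [
    "PermeabilityRecord",
    "center_intensity",
    "background_intensity",
    "background_mean_sd",
    "measure_scene_permeability",
    "normalize_permeation",
    "compare_groups_permeability",
]


@dataclass
class PermeabilityRecord:
    """Per-bead raw intensities and the normalized permeation percentage."""

    bead_id: int
    probe_label: str
    timepoint_h: float
    center_mean_intensity: float
    background_mean_intensity: float
    raw_ratio: float
    normalized_permeation_pct: float | None = None


def center_intensity(scene: Scene, bead: DetectedBead,
                     roi_fraction: float = 0.2) -> float:
    """Mean intensity over a central disk ROI of radius roi_fraction * r."""
    if not 0 < roi_fraction <= 0.5:
        raise ValueError("roi_fraction must be in (0, 0.5]")
    h, w = scene.image.shape
    r_roi = roi_fraction * bead.radius_px
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.hypot(xx - bead.center_x_px, yy - bead.center_y_px) <= r_roi
    if not mask.any():
        raise ValueError("central ROI contains no pixels")
    return float(scene.image[mask].mean())


def _background_mask(scene: Scene, beads: list[DetectedBead],
                     exclusion_factor: float) -> np.ndarray:
    h, w = scene.image.shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.ones((h, w), dtype=bool)
    for b in beads:
        mask &= np.hypot(xx - b.center_x_px, yy - b.center_y_px) > exclusion_factor * b.radius_px
    return mask


def background_intensity(scene: Scene, beads: list[DetectedBead],
                         exclusion_factor: float = 1.5) -> float:
    """Mean intensity of the bead-free area.

    Pixels closer than ``exclusion_factor`` bead radii to any bead center are
    excluded; at least 5% of the field must remain.
    """
    mask = _background_mask(scene, beads, exclusion_factor)
    if mask.mean() < 0.05:
        raise ValueError("insufficient bead-free background area (<5% of field)")
    return float(scene.image[mask].mean())


def background_mean_sd(scene: Scene, beads: list[DetectedBead],
                       exclusion_factor: float = 1.5) -> tuple[float, float]:
    """Mean and SD of the bead-free background (used by darkness criteria)."""
    mask = _background_mask(scene, beads, exclusion_factor)
    if mask.mean() < 0.05:
        raise ValueError("insufficient bead-free background area (<5% of field)")
    vals = scene.image[mask]
    return float(vals.mean()), float(vals.std())


def measure_scene_permeability(scene: Scene, beads: list[DetectedBead],
                               probe_label: str, timepoint_h: float = 1.0,
                               roi_fraction: float = 0.2,
                               exclusion_factor: float = 1.5,
                               first_bead_id: int = 0) -> list[PermeabilityRecord]:
    """Raw center/background ratio for every detected bead in one scene."""
    bg = background_intensity(scene, beads, exclusion_factor)
    if bg <= 0:
        raise ValueError("background intensity must be positive")
    records = []
    for i, bead in enumerate(beads):
        center = center_intensity(scene, bead, roi_fraction)
        records.append(PermeabilityRecord(
            bead_id=first_bead_id + i, probe_label=probe_label,
            timepoint_h=timepoint_h, center_mean_intensity=center,
            background_mean_intensity=bg, raw_ratio=center / bg,
        ))
    return records


def normalize_permeation(raw_ratios_by_probe: dict[str, float],
                         anchor_low: str = "4 kDa",
                         anchor_high: str = "2 MDa") -> dict[str, float]:
    """Two-anchor normalization of per-probe mean ratios to a 0–100% scale.

    ``anchor_low``/``anchor_high`` name the low- and high-molecular-weight
    reference probes; the low-MW anchor (full permeation) maps to exactly 100
    and the high-MW anchor (full exclusion) to exactly 0, with all values
    clamped to [0, 100].
    """
    if anchor_low not in raw_ratios_by_probe or anchor_high not in raw_ratios_by_probe:
        raise ValueError("both anchor probes must be present in the ladder")
    r_full = raw_ratios_by_probe[anchor_low]
    r_blocked = raw_ratios_by_probe[anchor_high]
    if r_blocked >= r_full:
        raise ValueError(
            "anchor ratios are equal or inverted: the high-MW anchor must "
            "have a smaller center/background ratio than the low-MW anchor")
    span = r_full - r_blocked
    return {
        probe: float(np.clip(100.0 * (r - r_blocked) / span, 0.0, 100.0))
        for probe, r in raw_ratios_by_probe.items()
    }


def compare_groups_permeability(group_a: list[float],
                                group_b: list[float]) -> WelchResult:
    """Welch's t-test between two groups of normalized permeation values."""
    return welch_from_samples(group_a, group_b)
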