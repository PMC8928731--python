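"""Pericapsular fibrotic overgrowth (PFO) scoring.

The fraction of a bead's perimeter covered by fibrotic tissue is estimated by
casting equally spaced rays from the bead center and testing, for each ray,
whether the mean intensity over an annular segment just outside the bead
boundary falls significantly below the bead-free background (a k-sigma
darkness criterion).  Coverage fractions are binned into the grading
categories used for encapsulated-device explants (0%, 1–25%, 26–50%, 51–75%,
76–100%) and cohorts are summarized as whole-percent category prevalences.

The scored annulus starts an ``inner_offset_um`` beyond the detected radius
rather than at the radius itself: under heavy overgrowth the detector
legitimately locks onto the rim's inner edge (the outer boundary carries no
contrast there), and the offset keeps the bead's own dark rim from being
scored as overgrowth in that case.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import ndimage as ndi

from .detection import DetectedBead
from .permeability import background_mean_sd
from .scenes import Scene

__all__ = [
    "COVERAGE_CATEGORIES",
    "PFORecord",
    "CohortSummary",
    "perimeter_coverage",
    "bin_coverage",
    "summarize_cohort",
]

COVERAGE_CATEGORIES = ("0%", "1–25%", "26–50%", "51–75%", "76–100%")


@dataclass
class PFORecord:
    """Per-bead perimeter coverage and its grading category."""

    bead_id: int
    coverage_fraction: float
    coverage_category: str


@dataclass
class CohortSummary:
    """Per-category bead percentages for one experimental group."""

    group_label: str
    n_beads: int
    pct_per_category: dict[str, int]


def perimeter_coverage(scene: Scene, bead: DetectedBead,
                       band_width_fraction: float = 0.15,
                       n_rays: int = 360,
                       dark_threshold_k: float = 3.0,
                       *,
                       inner_offset_um: float = 8.0,
                       background_stats: tuple[float, float] | None = None,
                       sample_step_px: float = 0.5) -> float:
    """Fraction of perimeter rays whose outer annular segment is dark.

    A ray is covered when its mean intensity over the radial window
    [r + offset, r + offset + band_width_fraction * r] is below
    (background mean - k * background SD).  ``background_stats`` may supply a
    precomputed (mean, sd) of the bead-free area; otherwise it is measured
    from this scene excluding this bead.
    """
    if not 0 < band_width_fraction <= 1:
        raise ValueError("band_width_fraction must be in (0, 1]")
    if n_rays < 8:
        raise ValueError("n_rays must be >= 8")
    img = scene.image
    h, w = img.shape
    r = bead.radius_px
    r0 = r + inner_offset_um / scene.pixel_size_um
    r1 = r0 + band_width_fraction * r
    cx, cy = bead.center_x_px, bead.center_y_px
    if cx - r1 < 0 or cy - r1 < 0 or cx + r1 > w - 1 or cy + r1 > h - 1:
        raise ValueError("scoring annulus exceeds the image bounds")
    if background_stats is None:
        bg_mean, bg_sd = background_mean_sd(scene, [bead])
    else:
        bg_mean, bg_sd = background_stats
    threshold = bg_mean - dark_threshold_k * bg_sd

    theta = np.linspace(0.0, 2 * np.pi, n_rays, endpoint=False)
    n_samples = max(2, int(np.ceil((r1 - r0) / sample_step_px)))
    radii = np.linspace(r0, r1, n_samples)
    xs = cx + np.outer(np.cos(theta), radii)
    ys = cy + np.outer(np.sin(theta), radii)
    vals = ndi.map_coordinates(img, [ys.ravel(), xs.ravel()], order=1,
                               mode="nearest").reshape(n_rays, n_samples)
    covered = vals.mean(axis=1) < threshold
    return float(covered.mean())


def bin_coverage(coverage_fraction: float) -> str:
    """Grading category for a coverage fraction (right-closed quartile bins,
    with exact zero its own class; the 75% boundary grades downward)."""
    if not 0 <= coverage_fraction <= 1:
        raise ValueError("coverage_fraction must be in [0, 1]")
    c = 100.0 * coverage_fraction
    if c == 0:
        return COVERAGE_CATEGORIES[0]
    if c <= 25:
        return COVERAGE_CATEGORIES[1]
    if c <= 50:
        return COVERAGE_CATEGORIES[2]
    if c <= 75:
        return COVERAGE_CATEGORIES[3]
    return COVERAGE_CATEGORIES[4]


def _pct_half_up(count: int, total: int) -> int:
    return int(Decimal(100 * count) / Decimal(total)
               if total and (100 * count) % total == 0
               else (Decimal(100 * count) / Decimal(total)).quantize(
                   Decimal("1"), rounding=ROUND_HALF_UP))


def summarize_cohort(records: list[PFORecord], group_label: str) -> CohortSummary:
    """Whole-percent (half-up) category prevalences for one cohort."""
    if not records:
        raise ValueError("cannot summarize an empty cohort")
    n = len(records)
    counts = {cat: 0 for cat in COVERAGE_CATEGORIES}
    for rec in records:
        if rec.coverage_category not in counts:
            raise ValueError(f"unknown category {rec.coverage_category!r}")
        counts[rec.coverage_category] += 1
    pct = {cat: _pct_half_up(c, n) for cat, c in counts.items()}
    return CohortSummary(group_label=group_label, n_beads=n, pct_per_category=pct)
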