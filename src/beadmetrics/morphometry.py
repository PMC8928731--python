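"""Batch size-distribution statistics and per-bead spheroid counting."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .detection import DetectedBead
from .scenes import Scene

__all__ = [
    "PopulationStats",
    "SpheroidCountConfig",
    "population_stats",
    "count_spheroids",
    "cells_per_ml",
]


@dataclass
class PopulationStats:
    """Size-distribution summary of one encapsulation batch.

    ``sd_diameter_um`` uses the n-1 denominator; for a single bead it is
    reported as 0 with ``single_bead_warning`` set.  Satellite and malformed
    fractions always refer to the full input list, regardless of whether
    satellites were excluded from the size statistics.
    """

    n_beads: int
    mean_diameter_um: float
    sd_diameter_um: float
    median_diameter_um: float
    histogram: list[tuple[float, float, int]]
    satellite_fraction: float
    malformed_fraction: float
    single_bead_warning: bool = False


@dataclass(frozen=True)
class SpheroidCountConfig:
    """Spheroid segmentation parameters.

    The size gate defaults to 80–220 um equivalent diameter, bracketing the
    100–200 um scale of 800-cell hepatocyte spheroids with margin.
    ``rim_allowance_um`` shrinks the analyzed interior disk so the dark rim
    annulus cannot masquerade as cell material.
    """

    spheroid_min_um: float = 80.0
    spheroid_max_um: float = 220.0
    rim_allowance_um: float = 48.0
    # minimum Otsu class separation, in units of the larger within-class SD,
    # below which the interior is declared spheroid-free
    min_class_separation: float = 4.0


def population_stats(beads: list[DetectedBead], bin_width_um: float = 10.0,
                     include_satellites: bool = False) -> PopulationStats:
    """Mean/SD/median diameter and a fixed-width histogram for a bead batch."""
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be positive")
    n_total = len(beads)
    kept = beads if include_satellites else [b for b in beads if not b.satellite_flag]
    if not kept:
        raise ValueError("no beads remain after satellite exclusion")
    d = np.array([b.diameter_um for b in kept], dtype=np.float64)
    single = d.size == 1
    lo = math.floor(d.min())
    n_bins = max(1, int(math.ceil((d.max() - lo) / bin_width_um)))
    if d.max() == lo:  # all diameters on the lower edge
        n_bins = 1
    edges = lo + bin_width_um * np.arange(n_bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    return PopulationStats(
        n_beads=int(d.size),
        mean_diameter_um=float(d.mean()),
        sd_diameter_um=0.0 if single else float(d.std(ddof=1)),
        median_diameter_um=float(np.median(d)),
        histogram=[(float(edges[i]), float(edges[i + 1]), int(counts[i]))
                   for i in range(n_bins)],
        satellite_fraction=(sum(b.satellite_flag for b in beads) / n_total
                            if n_total else 0.0),
        malformed_fraction=(sum(b.malformed_flag for b in beads) / n_total
                            if n_total else 0.0),
        single_bead_warning=single,
    )


def count_spheroids(scene: Scene, bead: DetectedBead,
                    config: SpheroidCountConfig = SpheroidCountConfig()) -> int:
    """Count encapsulated spheroids inside one bead's interior disk.

    Dark objects are segmented by Otsu thresholding restricted to the interior
    disk (radius shrunk by ``rim_allowance_um``), touching objects are split
    by one watershed round on the distance transform, and connected components
    with equivalent diameter inside the configured size gate are counted.  An
    interior whose Otsu split does not separate two genuinely distinct
    intensity classes (noise-only interiors) counts zero.
    """
    img = scene.image
    ps = scene.pixel_size_um
    h, w = img.shape
    r = bead.radius_px
    cx, cy = bead.center_x_px, bead.center_y_px
    if cx - r < -0.5 or cy - r < -0.5 or cx + r > w - 0.5 or cy + r > h - 0.5:
        raise ValueError("bead lies partially outside the image")
    r_in = r - config.rim_allowance_um / ps
    if r_in <= 0:
        return 0
    y0, y1 = max(0, int(cy - r_in) - 1), min(h, int(cy + r_in) + 2)
    x0, x1 = max(0, int(cx - r_in) - 1), min(w, int(cx + r_in) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    disk = np.hypot(xx - cx, yy - cy) <= r_in
    vals = img[y0:y1, x0:x1][disk]
    if vals.size == 0 or np.ptp(vals) < 1e-9:
        return 0
    thresh = threshold_otsu(vals)
    dark_vals = vals[vals < thresh]
    light_vals = vals[vals >= thresh]
    if dark_vals.size == 0 or light_vals.size == 0:
        return 0
    spread = max(dark_vals.std(), light_vals.std(), 1e-12)
    if (light_vals.mean() - dark_vals.mean()) < config.min_class_separation * spread:
        return 0

    mask = (img[y0:y1, x0:x1] < thresh) & disk
    distance = ndi.distance_transform_edt(mask)
    min_sep_px = max(1, int(config.spheroid_min_um / ps / 2))
    coords = peak_local_max(distance, min_distance=min_sep_px, labels=mask)
    if coords.shape[0] == 0:
        return 0
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, coords.shape[0] + 1)
    labels = watershed(-distance, markers, mask=mask)
    count = 0
    for region in regionprops(labels):
        eq_d_um = region.equivalent_diameter_area * ps
        if config.spheroid_min_um <= eq_d_um <= config.spheroid_max_um:
            count += 1
    return count


def cells_per_ml(clusters_per_ml: float, cells_per_cluster: float) -> float:
    """Cell concentration implied by a spheroid (cluster) suspension density.

    E.g. 6.25e4 clusters/mL of 800-cell spheroids corresponds to 5e7 cells/mL.
    """
    if clusters_per_ml < 0 or cells_per_cluster < 0:
        raise ValueError("concentrations must be non-negative")
    return clusters_per_ml * cells_per_cluster
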