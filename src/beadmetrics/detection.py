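"""Edge-based circular Hough detection of microbeads in calibrated scenes.

The detector follows the classic pipeline: Gaussian smoothing, Sobel gradient
magnitude, hysteresis edge linking with thresholds expressed as fractions of
the 99th-percentile gradient (making detection invariant to global affine
intensity rescaling), then a 3-parameter circular Hough accumulator over
(cx, cy, r).  Accumulator peaks are screened by a normalized perimeter-support
score, duplicate concentric hypotheses are suppressed by a minimum
center-to-center separation, and the surviving circles are refined to
sub-pixel geometry by an algebraic circle fit to the edge pixels in a narrow
annular window.

A microbead images as two concentric near-perfect circles: its outer boundary
and the inner edge of its rim annulus, typically 3–8 px apart and both with
near-unit perimeter support.  Since float accumulator scores virtually never
tie exactly, "equal score" for the larger-radius-first tie-break is defined as
equality after quantizing scores into bins of ``score_tiebreak_quantum``; this
is what makes the detector report the bead's true outer boundary rather than
its rim's inner edge, while still preferring the fully supported rim circle
when overgrowth erases most of the outer boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import canny
from skimage.transform import hough_circle

from .scenes import Scene

__all__ = [
    "DetectedBead",
    "DetectionConfig",
    "edge_map",
    "hough_detect",
    "detect_beads",
    "flag_satellites",
    "flag_malformed",
    "perimeter_edge_support",
]


@dataclass
class DetectedBead:
    """One circle hypothesis promoted to a measured bead.

    ``accumulator_score`` is the fraction of the circle perimeter supported by
    edge pixels (in [0, 1]); flags are set by :func:`flag_satellites` and
    :func:`flag_malformed`.
    """

    center_x_px: float
    center_y_px: float
    radius_px: float
    diameter_um: float
    accumulator_score: float
    malformed_flag: bool = False
    satellite_flag: bool = False


@dataclass(frozen=True)
class DetectionConfig:
    """Detector tuning; all defaults target ~450–750 um beads.

    ``edge_low``/``edge_high`` are fractions of the 99th-percentile gradient
    magnitude.  The radius search band defaults to 150–400 um, bracketing the
    ~620–700 um bead diameters of electrostatically generated alginate
    capsules with margin.
    """

    gaussian_sigma_px: float = 2.0
    edge_low: float = 0.1
    edge_high: float = 0.2
    radius_min_um: float = 150.0
    radius_max_um: float = 400.0
    radius_step_px: float = 2.0
    peak_threshold: float = 0.5
    min_center_separation_um: float = 300.0
    score_tiebreak_quantum: float = 0.1
    support_n_angles: int = 360
    support_tol_px: float = 1.5
    max_candidates: int = 50000
    outer_ring_search_um: float = 64.0

    def __post_init__(self) -> None:
        if self.radius_min_um >= self.radius_max_um:
            raise ValueError("radius_min_um must be < radius_max_um")
        if not 0 < self.peak_threshold <= 1:
            raise ValueError("peak_threshold must be in (0, 1]")
        if self.radius_step_px <= 0:
            raise ValueError("radius_step_px must be positive")


def edge_map(scene: Scene, config: DetectionConfig = DetectionConfig()) -> np.ndarray:
    """Binary edge image: Gaussian smoothing, Sobel gradient magnitude,
    non-maximum suppression and hysteresis linking.

    Thresholds are fractions of a normalized gradient reference — the larger
    of the 99th-percentile gradient magnitude and half the maximum gradient —
    so the output is invariant to any global affine rescale of the input
    intensities.  (The max term keeps sparse fields honest: with a single
    bead in a large field the 99th percentile sits in the noise floor.)
    """
    img = np.asarray(scene.image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("edge_map requires a single-channel 2D image")
    smoothed = ndi.gaussian_filter(img, config.gaussian_sigma_px)
    gx = ndi.sobel(smoothed, axis=1)
    gy = ndi.sobel(smoothed, axis=0)
    mag = np.hypot(gx, gy)
    ref = max(np.percentile(mag, 99), 0.5 * mag.max())
    scale = img.max() - img.min()
    if ref <= 1e-12 * max(scale, 1e-300):
        return np.zeros_like(img, dtype=bool)
    return canny(img, sigma=config.gaussian_sigma_px,
                 low_threshold=config.edge_low * ref,
                 high_threshold=config.edge_high * ref)


def perimeter_edge_support(edges: np.ndarray, cx: float, cy: float, r: float,
                           n_angles: int = 360, tol_px: float = 1.5,
                           edge_dist: np.ndarray | None = None) -> float:
    """Fraction of perimeter sample points within ``tol_px`` of an edge pixel.

    ``edge_dist`` may carry a precomputed Euclidean distance transform of the
    background of ``edges`` to amortize repeated queries on one scene.
    """
    if edge_dist is None:
        if not edges.any():
            return 0.0
        edge_dist = ndi.distance_transform_edt(~edges)
    theta = np.linspace(0.0, 2 * math.pi, n_angles, endpoint=False)
    xs = cx + r * np.cos(theta)
    ys = cy + r * np.sin(theta)
    h, w = edge_dist.shape
    inside = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
    d = np.full(n_angles, np.inf)
    if inside.any():
        d[inside] = ndi.map_coordinates(edge_dist, [ys[inside], xs[inside]],
                                        order=1, mode="nearest")
    return float(np.mean(d <= tol_px))


def _kasa_refine(edges: np.ndarray, cx: float, cy: float, r: float,
                 window_px: float) -> tuple[float, float, float]:
    """Sub-pixel circle refinement: algebraic least-squares fit to the edge
    pixels inside an annular window around the accumulator peak.

    Falls back to the input geometry when the fit is degenerate or drifts
    outside the window (e.g. heavily gapped boundaries).
    """
    h, w = edges.shape
    pad = int(math.ceil(r + window_px)) + 2
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    ys, xs = np.nonzero(edges[y0:y1, x0:x1])
    if ys.size < 8:
        return cx, cy, r
    px = xs + x0
    py = ys + y0
    dist = np.hypot(px - cx, py - cy)
    sel = np.abs(dist - r) <= window_px
    if sel.sum() < 8:
        return cx, cy, r
    for _ in range(2):
        x = px[sel].astype(np.float64)
        y = py[sel].astype(np.float64)
        a_mat = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
        b_vec = x * x + y * y
        try:
            sol, *_ = np.linalg.lstsq(a_mat, b_vec, rcond=None)
        except np.linalg.LinAlgError:
            return cx, cy, r
        fx, fy = sol[0], sol[1]
        fr2 = sol[2] + fx * fx + fy * fy
        if fr2 <= 0:
            return cx, cy, r
        fr = math.sqrt(fr2)
        if math.hypot(fx - cx, fy - cy) > 3.0 or abs(fr - r) > window_px + 1:
            return cx, cy, r
        sel = np.abs(np.hypot(px - fx, py - fy) - fr) <= window_px
        if sel.sum() < 8:
            return fx, fy, fr
    return fx, fy, fr


def _prefer_outer_ring(edges: np.ndarray, cx: float, cy: float, r: float,
                       config: DetectionConfig, edge_dist: np.ndarray,
                       pixel_size_um: float) -> float:
    """Climb from a rim's inner ring to the bead's outer boundary.

    A bead images as two concentric near-fully-supported rings (rim inner
    edge and outer boundary).  Accumulator vote-splitting can rank the inner
    ring marginally above the outer one, so after suppression we take the
    outermost concentric radius whose perimeter support is still
    near-complete and not materially below the accepted peak's.
    """
    base = perimeter_edge_support(edges, cx, cy, r, config.support_n_angles,
                                  config.support_tol_px, edge_dist)
    search_px = config.outer_ring_search_um / pixel_size_um
    best = r
    for rr in np.arange(r + 2.0, r + search_px + 0.5):
        s = perimeter_edge_support(edges, cx, cy, rr, config.support_n_angles,
                                   config.support_tol_px, edge_dist)
        if s < max(0.9, base - 0.05):
            continue
        # a genuine boundary ring has empty space beyond it; dense texture
        # (e.g. fibrotic-overgrowth speckle and its ragged fringe) supports
        # a whole range of radii and must not be climbed into
        outside = max(
            perimeter_edge_support(edges, cx, cy, rr + gap,
                                   config.support_n_angles,
                                   config.support_tol_px, edge_dist)
            for gap in (3.0, 5.0, 7.0))
        if outside <= 0.3:
            best = rr
    return best


def hough_detect(edges: np.ndarray, config: DetectionConfig,
                 pixel_size_um: float) -> list[DetectedBead]:
    """Detect circles in a binary edge image and report beads in um.

    Peaks with normalized accumulator score >= ``peak_threshold`` are taken in
    quantized-score, larger-radius-first, row-major order; accepted centers
    are kept at least ``min_center_separation_um`` apart.  The returned list
    is sorted by descending perimeter-support score.
    """
    edges = np.asarray(edges, dtype=bool)
    if edges.ndim != 2:
        raise ValueError("edge image must be 2D")
    r_lo = config.radius_min_um / pixel_size_um
    r_hi = config.radius_max_um / pixel_size_um
    step = max(1, int(round(config.radius_step_px)))
    radii = np.arange(int(math.ceil(r_lo)), int(math.floor(r_hi)) + 1, step)
    if radii.size < 2:
        raise ValueError("radius search band spans fewer than 2 steps")
    if not edges.any():
        return []

    acc = hough_circle(edges, radii, normalize=True, full_output=False)
    # A ring whose radius falls between two grid steps splits its votes over
    # the neighboring planes and can drop below threshold in both; the sums
    # of adjacent planes (near-disjoint vote sets) recover full support at
    # the midpoint radii.
    if radii.size >= 2 and step > 1:
        acc = np.concatenate([acc, acc[:-1] + acc[1:]], axis=0)
        radii = np.concatenate([radii, radii[:-1] + step // 2])
    acc = np.minimum(acc, 1.0)
    cand = np.argwhere(acc >= config.peak_threshold)
    if cand.size == 0:
        return []
    scores = acc[cand[:, 0], cand[:, 1], cand[:, 2]]
    if cand.shape[0] > config.max_candidates:
        keep = np.argpartition(scores, -config.max_candidates)[-config.max_candidates:]
        cand, scores = cand[keep], scores[keep]

    q = np.floor(scores / config.score_tiebreak_quantum).astype(int)
    cand_r = radii[cand[:, 0]]
    # order: higher quantized score, then larger radius, then row-major center
    order = np.lexsort((cand[:, 2], cand[:, 1], -cand_r, -q))
    min_sep_px = config.min_center_separation_um / pixel_size_um

    accepted: list[tuple[float, float, float]] = []
    for idx in order:
        ri, cy, cx = cand[idx]
        if any(math.hypot(cx - ax, cy - ay) < min_sep_px for ax, ay, _ in accepted):
            continue
        accepted.append((float(cx), float(cy), float(radii[ri])))

    edge_dist = ndi.distance_transform_edt(~edges)
    beads: list[DetectedBead] = []
    for cx, cy, r in accepted:
        # center first (the accumulator peak can sit 1-2 px off), then climb
        # to the outermost concentric ring, then re-fit there
        fx, fy, fr = _kasa_refine(edges, cx, cy, r, window_px=step + 1.0)
        rr = _prefer_outer_ring(edges, fx, fy, fr, config, edge_dist,
                                pixel_size_um)
        if rr != fr:
            fx, fy, fr = _kasa_refine(edges, fx, fy, rr, window_px=step + 1.0)
        score = perimeter_edge_support(edges, fx, fy, fr,
                                       config.support_n_angles,
                                       config.support_tol_px, edge_dist)
        beads.append(DetectedBead(
            center_x_px=fx, center_y_px=fy, radius_px=fr,
            diameter_um=2 * fr * pixel_size_um,
            accumulator_score=min(score, 1.0),
        ))
    beads.sort(key=lambda b: (-b.accumulator_score, -b.radius_px,
                              b.center_y_px, b.center_x_px))
    return beads


def detect_beads(scene: Scene,
                 config: DetectionConfig = DetectionConfig()) -> list[DetectedBead]:
    """Convenience wrapper: edge map then Hough detection on one scene."""
    return hough_detect(edge_map(scene, config), config, scene.pixel_size_um)


def flag_satellites(beads: list[DetectedBead],
                    satellite_max_diameter_um: float = 200.0) -> list[DetectedBead]:
    """Mark residual droplet-fission 'satellite' beads by a diameter cutoff."""
    for b in beads:
        b.satellite_flag = b.diameter_um < satellite_max_diameter_um
    return beads


def flag_malformed(scene: Scene, beads: list[DetectedBead],
                   min_edge_support: float = 0.8,
                   config: DetectionConfig = DetectionConfig()) -> list[DetectedBead]:
    """Mark beads whose boundary lacks circular edge support.

    A well-formed bead's boundary supports nearly the full perimeter; gaps
    from malformation lower the stored accumulator score below
    ``min_edge_support``.  Scores are recomputed from the scene when absent.
    """
    if not 0 < min_edge_support < 1:
        raise ValueError("min_edge_support must be in (0, 1)")
    needs = [b for b in beads if b.accumulator_score is None or math.isnan(b.accumulator_score)]
    if needs:
        edges = edge_map(scene, config)
        edge_dist = ndi.distance_transform_edt(~edges) if edges.any() else None
        for b in needs:
            b.accumulator_score = perimeter_edge_support(
                edges, b.center_x_px, b.center_y_px, b.radius_px,
                config.support_n_angles, config.support_tol_px, edge_dist)
    for b in beads:
        b.malformed_flag = b.accumulator_score < min_edge_support
    return beads
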