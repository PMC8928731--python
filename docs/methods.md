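# Methods

`beadmetrics` quantifies four readouts of alginate-microencapsulated cell
therapy products from calibrated single-channel microscopy: batch morphometry
(bead diameters, size distribution, satellite/malformed fractions, spheroid
occupancy), semi-quantitative permeability against a FITC-dextran
molecular-weight ladder, pericapsular fibrotic overgrowth (PFO) grading of
explanted beads, and the associated two-group statistics (Welch's t-test,
a priori power). Because no raw imaging data are distributed with the studies
this pipeline serves, every stage is validated against a seeded synthetic
scene generator with machine-readable ground truth.

## Synthetic scenes

Images are scalar arrays in [0, 1], written as 16-bit TIFF/PNG. The generator
emulates two modalities.

**Brightfield.** Bright solution background (default 0.85) with beads as
slightly darker disks bounded by a darker rim annulus — the transmitted-light
appearance of an alginate capsule wall. With rim contrast `c_r` (default
0.35) the rim level is `bg·(1 − c_r)` and the interior `bg·(1 − 0.3·c_r)`;
the 0.3 factor fixes the ordering band < rim < interior < background for any
positive contrasts. Encapsulated cell spheroids are darker disks wholly
inside the bead (diameters 100–200 μm, the scale of ~800-cell hepatocyte
spheroids). Fibrotic overgrowth is drawn as an annular band outside the bead
boundary: a per-pixel Bernoulli speckle (density 0.7) mixing two darkness
levels strictly below the rim, with the band's outer fringe jittered per
degree by ±30% of the band width so the tissue boundary is ragged rather
than a clean circle. Keeping the band strictly darker than the rim preserves
edge contrast at the bead boundary even under 100% coverage, which is what
real fibrotic capsules show (tissue is optically denser than the alginate
wall) and what lets one detector serve clean and overgrown beads alike.

**Fluorescence.** Bead-free probe solution at `bg` (default 0.9); a bead
interior carries `floor + f·(bg − floor)` where `f` is the rendered
permeation fraction and `floor` (default 0.02) models autofluorescence. The
capsule wall is drawn as a faint dark rim annulus. The rim is not part of
the interior-intensity contract; it exists so that a fully permeable bead
(`f = 1`, interior = background) remains optically localizable, without
which a ladder's 4 kDa anchor condition could not be processed by the same
detect-then-measure route as every other probe.

Defaults mirror the imaging conditions the pipeline targets: 4 μm/px
(high-content screening at ~5×), Gaussian noise at 1–2% of dynamic range,
bead diameters 450–750 μm (electrostatic encapsulation sized "below
700 μm"), rim width 32 μm. Sub-pixel centers are allowed and rasterized by a
pixel-center-in-disk test. All stochastic elements derive from one seeded
generator: identical (spec, beads, seed) gives bit-identical scenes.

What the generator does *not* model: optical blur/PSF, illumination
gradients, debris, z-structure, bead deformation, overlapping beads.
Passing tests therefore demonstrate correctness of the measurement
operations under idealized optics, not robustness to every real-world
artifact; the detector's exposure invariance and noise tolerance are tested
explicitly, field non-uniformity is not.

## Bead detection

Classic edge-based circular Hough transform:

1. Gaussian smoothing (σ = 2 px), Sobel gradient magnitude, non-maximum
   suppression, hysteresis linking. Thresholds are fractions (0.1/0.2) of a
   normalized gradient reference, making detection invariant to global
   affine intensity rescaling. The reference is `max(p99, 0.5·max)` of the
   gradient magnitude rather than the 99th percentile alone: with a single
   bead in a megapixel field the 99th percentile sits in the noise floor,
   and anchoring to the strongest edge keeps sparse fields from flooding.
2. A 3-parameter accumulator over (cx, cy, r), radius discretized at 2 px
   over a 150–400 μm radius search band (bracketing ~620–700 μm beads with
   margin). Accumulator planes are normalized by circumference, so peak
   values approximate the fraction of perimeter supported by edges. Because
   a ring whose radius falls midway between grid steps splits its votes
   across the two neighboring planes (and can drop below threshold in
   both), sums of adjacent planes are added as candidates at the midpoint
   radii.
3. Peaks at normalized score ≥ 0.5 are taken in quantized-score
   (bins of 0.1), larger-radius-first, row-major order, with accepted
   centers kept ≥ 300 μm apart. A bead images as *two* concentric
   near-perfect circles — its outer boundary and the rim's inner edge —
   and float scores never tie exactly, so "equal score" for the
   larger-radius-first rule is defined after quantization; this makes the
   detector report the outer boundary rather than the rim's inner edge.
4. Each accepted circle is refined to sub-pixel geometry by an algebraic
   (Kåsa) least-squares circle fit to edge pixels in a ±3 px annular
   window, then climbed to the outermost concentric radius whose perimeter
   support remains near-complete (≥ max(0.9, peak − 0.05)) and re-fitted.
   The climb is what makes ring choice robust when vote-splitting ranks
   the inner ring marginally higher.

The reported `accumulator_score` is the fraction of 360 perimeter sample
points within 1.5 px of an edge pixel. Satellites (residual droplet-fission
beads) are flagged by an absolute diameter cutoff, default 200 μm — the
studies this serves report satellites qualitatively, so the cutoff is this
package's choice. Malformation is flagged as perimeter edge support below
0.8: a well-formed bead supports ≈ 100% of its perimeter, while a rendered
120° boundary gap drops support to ≈ 2/3.

Measured accuracy under the benchmark conditions (50 seeded 1024² scenes,
1–8 beads, 2% noise): precision = recall = 1.0, diameter MAE ≈ 0.3 μm
(≤ 0.1 px), centers within ~0.5 px.

## Morphometry

Population statistics are plain closed-form quantities: mean, SD (n−1
denominator; a single bead reports SD 0 with an explicit warning flag),
median, and a fixed-width histogram (default 10 μm bins) from
⌊min⌋. Satellites are excluded from the size statistics by default but both
modes are available; satellite and malformed *fractions* always refer to the
full detected list. Spheroid counting restricts to the bead interior disk
(radius minus a 48 μm rim allowance), thresholds dark pixels by Otsu's
method computed on interior pixels only (exposure-invariant), splits
touching objects with one watershed round on the distance transform, and
counts components with equivalent diameter in 80–220 μm (the 100–200 μm
spheroid scale with margin). A guard declines to count when Otsu's two
classes are not genuinely separated (class-mean separation < 4× the larger
within-class SD), which is what a noise-only interior produces.

## Permeability

Per bead, the raw statistic is the ratio of the mean intensity in a central
disk ROI to the mean intensity of the bead-free background. The "central
point" is read as a disk of radius 0.2·r rather than one pixel — a
single-pixel readout is noise-dominated, and the interior is flat by
construction. Background excludes pixels within 1.5 bead radii of any
detected center and requires ≥ 5% of the field to survive. Per-bead ratios
are averaged within a probe condition (group-level readout, n = 11 beads
per probe in the reference design) and the ladder is normalized linearly so
that the 4 kDa probe (full equilibration) maps to exactly 100% and the
2 MDa probe (full exclusion) to exactly 0%, clamping to [0, 100]. The
anchors map exactly by construction — the normalization is anchored
interpolation, not a fit. Incubation timepoints are carried as metadata
only; no kinetic model is fitted. Group comparisons delegate to Welch's
t-test; no multiplicity adjustment is applied by default (a Holm adjustment
is available for repeated per-probe testing).

## PFO scoring

For each detected bead, 360 equally spaced rays sample an annular segment
outside the boundary; a ray is "covered" when its mean intensity over the
radial window [r + δ, r + δ + 0.15·r] falls below the bead-free background
mean minus 3 background SDs. Coverage is the covered-ray fraction. The
inner offset δ (default 8 μm, ≈ 2 px) skips the blurred boundary gradient
so a clean bead's rays are not scored dark; this is a deliberate refinement
of the nominal [r, r·(1 + w)] annulus. With zero noise the background SD is
0 and the criterion degenerates to "strictly darker than background", which
is exact on rendered scenes.

Coverage fractions are graded into 0% / 1–25% / 26–50% / 51–75% / 76–100%
categories: exact zero is its own class, bins are right-closed, and the 75%
boundary grades downward. Only the top category's existence is fixed by the
explant-grading convention this reproduces; the full quartile scheme is
this package's choice, matching common encapsulation-device grading.
Cohort summaries are per-category percentages of beads, rounded half-up to
integers to match whole-percent reporting.

Measured accuracy: |estimated − true| ≤ 0.05 noiseless and ≤ 0.10 at 2%
noise across a 0–100% coverage sweep, with Spearman ρ ≥ 0.95 against true
arc length.

## Statistics

Welch's t statistic, the Welch–Satterthwaite degrees of freedom (kept
unrounded) and the two-sided p-value are computed from their defining
formulas, with the central-t tail evaluated through the regularized
incomplete beta function, P(|T| > t) = I_{ν/(ν+t²)}(ν/2, ½). Degenerate
inputs are defined explicitly: both SDs zero with equal means gives
t = 0, p = 1; both zero with distinct means is an error. A priori sample
size inverts the exact noncentral-t power of the equal-n two-sample t-test
(noncentrality d·√(n/2)) by bisection; d = 0.3, α = 0.05, power = 0.80
(two-sided) yields n = 176 per group. The reference design's stated small
groups (n = 3–11) cannot follow from that calculation under a two-sample
t-test — the effect-size family behind the original power analysis is not
recoverable — so the package implements the standard calculation and leaves
the discrepancy documented here rather than reverse-engineering it.
Summary-statistic Welch tests on published group means/SDs reproduce the
significance band (e.g. t ≈ 4.13, p < 0.01 for the albumin comparison) but
not raw-data p-values, which depend on unpublished samples.

## Reproduction script problem sizes

`scripts/acceptance.py` renders its experiments at the benchmark field size
(1024² px at 4 μm/px): a five-probe ladder at 11 beads per probe, and a
26-bead low-coverage explant cohort (true coverage uniform in [0, 0.5])
packed 7 beads per scene. These sizes are the package's reference
conditions; all quantities are recomputed end-to-end at run time from the
given seed.

## Known limitations

* The detector assumes discrete, non-overlapping, circular beads; touching
  or elliptical beads are out of scope.
* Coverage scoring assumes overgrowth is optically darker than background
  immediately outside the boundary; translucent overgrowth would be missed.
* Satellite beads below the radius search band are not detected (they can
  only be flagged in externally supplied bead tables).
* The Otsu separation guard trades a small risk of missing very
  low-contrast spheroids for robustness against counting noise.
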