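# Methods

`spheroidquant` quantifies 3D spheroid invasion cultures from
single-channel nuclear-reporter (H2B-GFP-like) confocal z-stacks: how many
cells sit in the residual core, the compact rim, and the invasion zone;
how far cells have disseminated; how often they divide or die; and how
deep into the specimen nuclei remain segmentable with and without optical
clearing. Because such cultures are living specimens, the package ships a
synthetic spheroid generator with exported ground truth, so every stage is
testable by parameter recovery.

## Segmentation chain

Nuclei are segmented per slice (2D, no 3D linking — slice-level counts are
the readout unit):

1. **Gaussian blur**, σ = 1.5 µm. σ is physical ("scaled") and converted
   to pixels through the mandatory calibration.
2. **Phansalkar local adaptive threshold.** The slice is rescaled to
   [0, 1] by its global min/max; with m, s the mean and standard deviation
   over a disc window (radius 15 px), the per-pixel threshold is
   t = m·(1 + p·e^(−q·m) + k·(s/r − 1)) with the Fiji defaults k = 0.25,
   r = 0.5, p = 2, q = 10. Local adaptivity is what makes nuclei at
   variable z-position and contrast segmentable at all; the price is that
   the method has **no absolute contrast floor** — a frame containing
   nothing but noise will be stretched to full range and segments speckle.
   A constant frame is guarded (all-background with a warning); frames
   with real signal anchor the rescale and background stays off.
3. **Binary median filter**, disc radius 3 px, implemented as an exact
   integer majority vote (foreground iff more than half the window is
   foreground), so it equals a per-pixel oracle bit for bit.
4. **Watershed separation** of touching nuclei: Euclidean distance
   transform, seeds at its regional maxima (maxima closer than 2 px are
   merged), watershed on the negated distance map restricted to the mask;
   separation lines go to background, labels are 8-connected — the ImageJ
   binary-watershed convention.
5. **Area band filter**: labels with calibrated area (pixel count ×
   xy_size²) in 45–700 µm² become nuclei ("size 45–700" is read as area;
   a 700 µm *length* would exceed any nucleus). Sub-floor labels are kept
   as **fragment candidates** for apoptosis detection; super-ceiling
   labels are discarded as unresolvable clumps. Centroids are
   intensity-weighted.

All windows are discs with mirrored border padding.

## Zonal geometry

Zone boundaries (core→rim, rim→invasion) are closed polygons — drawn by
the user (ImageJ `.roi`/`.zip` or a JSON dialect) or estimated from the
radial intensity profile — straightened to ellipses with ImageJ
Fit-Ellipse semantics: orientation and axis ratio from the polygon
interior's second central moments (computed exactly by Green's-theorem
integrals), axes scaled so the areas match exactly. Pixels inside the
core_rim ellipse are core, between the two ellipses rim, outside
invasion. A record's zone is the zone label at its centroid pixel — the
cheapest rule consistent with counting nuclei. The spheroid centroid is
the core_rim ellipse center; radial (migration) distance is the in-plane
Euclidean distance to it, in µm.

For representative single-cell analysis the invasion zone can be
restricted to one **random quadrant**: axis-aligned, anchored at the
centroid, drawn uniformly with a seeded RNG. The restriction applies
uniformly to nuclei and events (whether death/mitosis events were
quadrant-restricted is not specified anywhere; uniformity is the logged
choice). Core and rim counts always use the full regions.

The automatic boundary estimator takes the radial mean-intensity profile
about the intensity centroid; the rim→invasion radius is the outermost
half-maximum crossing of the falling outer edge, the core→rim radius the
inward half-rise toward the densest ring. It assumes the rim is denser
than the core (true of the generator's defaults and of compact-rim
specimens) and is a convenience only — user ROIs always win.

## Event readouts

**Apoptosis** is read out as nuclear fragmentation: fragment candidates
with area 3–25 µm² are single-linkage clustered per slice with a 20 µm
linking distance; clusters of ≥ 2 fragments are events, centered on the
mean member centroid. The clustering reading of "fragments within 20 µm"
is fixed here because the original detector is proprietary. One event
stands for one dead cell, so
death_frequency = events / (events + intact nuclei) per zone — the
denominator is a documented choice, recorded in run metadata.

**Mitoses** are annotation-driven (bright condensed figures are counted
by eye in this assay; no heuristic detector is shipped): a CSV of
(slice, row, col) rows is zone-assigned per pixel, duplicates within 5 µm
on a slice collapse with a warning, and
mitosis_frequency = mitoses / (mitoses + nuclei) per zone, symmetric with
the death frequency.

**Two-group comparison** uses a two-sided Mann–Whitney U test: for
n₁+n₂ ≤ 12 the p-value is exact by full enumeration of rank assignments
(mid-ranks for ties); larger samples use the normal approximation with
tie and continuity correction. Time-course ANOVA is out of scope — the
per-zone tables are exported as plain CSV for any external stats package.

## SNR-depth profile

Per slice, SNR = (I_mean − B_mean)/SD_mean with I_mean the mean of the
brightest ⌈5%⌉ of all slice pixels, and B_mean, SD_mean the mean and
population (divisor N) standard deviation of a user-chosen dark region
(default: the top-left corner window covering 10% of each dimension).
Taking the top 5% over the whole slice (rather than a signal ROI) is the
implemented reading and is flagged here. The statistic is invariant to
additive offsets and positive gain. The segmentable depth is the greatest
depth whose SNR meets a configurable threshold (default 5; the assay
itself only marks the threshold as a dashed line, not a number).

## Synthetic spheroid generator

The generator emulates a day-7-like invasion culture:

- **Geometry** (defaults): core ball radius 100 µm holding 400 cells,
  rim shell 30 µm thick with 900 cells (the rim is ~2× denser than the
  core, matching the compact-ring phenotype and making the boundary
  estimable), 300 invading cells whose radial distance beyond the rim is
  exponential with 100 µm decay, truncated at 400 µm. With these counts
  the nuclear volume packing fraction stays ≤ 0.25 everywhere; > 0.9 in
  any zone is rejected as unphysical.
- **Nuclei** are Gaussian blobs whose half-maximum contour has the drawn
  diameter (12 ± 1.5 µm), peak intensity 150 on a background of 10.
  Invading cells are radially polarized (1.4× elongated in-plane along
  the radius). Mitotic cells (2% by default) are condensed (0.75×
  diameter) and 2.5× brighter.
- **Apoptotic cells** (1% per zone in control conditions, 8% in the
  invasion zone for the irradiated condition) are rendered as their
  fragment cloud instead of one nucleus: 4–7 fragments of diameter
  2.2–3.6 µm, scattered uniformly in an 18 µm disc with ≥ 10 µm spacing
  (so the fragments stay optically resolvable after PSF + protocol blur),
  at 0.95× nuclear brightness. In z the cloud keeps an envelope 1.2× the
  parent nucleus: apoptotic bodies disperse through (and slightly beyond)
  the rounded cell's depth. These distributions are modeling choices —
  the assay specifies only the detector's limits (3–25 µm², 20 µm) — and
  were calibrated on single-event scenes so that the
  *rendered-then-segmented* fragment areas fall inside the detector band
  and events share the nuclei's z-visibility window. Without that axial
  envelope, small fragments vanish a few µm off-plane while 12 µm nuclei
  stay segmentable out to ~2σ_z ≈ 10 µm, and any slice-based death
  frequency would systematically undercount.
- **Optics**: per-slice Beer–Lambert attenuation exp(−depth/λ) with the
  attenuation length λ the single clearing parameter (25 µm ≈ uncleared,
  500 µm ≈ cleared; scattering blur growth with depth is not modeled —
  single-exponential attenuation is the simplest model producing the
  observed SNR-depth phenomenology), then an in-plane Gaussian PSF
  (σ = 1 µm), a constant background, Poisson shot noise on
  signal + background, and additive Gaussian read noise (σ = 2).
- **Acquisition modes**: `central` places n slices 10 µm apart about the
  spheroid center (the 3-central-slices quantification protocol);
  `full` scans from the upper spheroid border downward at 6 µm steps.
  Imaging depth for attenuation is measured from the upper spheroid
  border.
- **Treatment model**: the treated sibling of a control scene removes
  each invading cell independently with the kill fraction (default 0.5),
  truncates the invasion front (default by 100 µm), and converts extra
  surviving invading cells to apoptotic; core and rim are untouched.

**Reproducibility.** One RNG stream (PCG64, mandatory seed) drives
specimen sampling in a documented draw order (state uniforms first, then
positions, diameters, fragment layouts), so counts like "how many
invading cells became apoptotic" are reproducible by replaying the
documented draws. Optics noise and treatment edits use seeds derived from
the scene seed by fixed documented offsets; the pipeline derives its
quadrant seed the same way. Identical config + seed ⇒ byte-identical CSV
outputs (up to the metadata timestamp).

**What the generator does not emulate** — and hence what passing recovery
tests do *not* show about real data: textured chromatin (blob-scale
features only), depth-dependent blur and refractive-index mismatch
artifacts, collagen autofluorescence and fibers, cell motion/time-lapse
blur, mitotic morphology beyond "small and bright" (mitoses are counted
from manual annotations in any case), and real apoptotic morphology
beyond the calibrated fragment statistics.

## Evaluation protocol for recovery tests

Truth lives in 3D but segmentation is 2D per slice, so scoring uses a
visibility convention: a truth cell is *expected* to be found when its
center is within 3.5 µm of its nearest slice plane (recall denominator);
a detection is *correct* when some truth cell lies within 10 µm in-plane
and within 10 µm of that slice's plane (precision) — a nucleus at 2σ_z
still presents ~15% of its peak cross-section, enough for a local
adaptive threshold, so cells between the strict and loose cuts may
legitimately be detected but are not demanded. On the cleared control
preset this yields precision ≈ 0.99 and recall ≈ 0.98 per seed.

## Canonical experiment sizes

The recovery experiments (in `spheroidquant.experiments`, reused by the
analysis drivers, the acceptance tests and `scripts/acceptance.py`) use:
10 seeds of the control preset for segmentation recovery; 25 seeds pooled
for death-frequency recovery (≈ 900 invasion-zone objects, comfortably
above the n ≥ 500 the recovery claim is stated at); 10 control/treated pairs for
the treatment contrast; one matched scene pair for the clearing depth
gain; and one full-depth 880 × 880 px scan at 2 µm/px with a 350 µm decay
length and 2000 invading cells for the maximum-dissemination readout
(the denser, longer-tailed front guarantees cells near the 850 µm cap are
actually present in the imaged slab). These sizes keep each experiment in
the minutes range on one CPU while leaving the statistical tolerances
comfortable.

## Numerical / degenerate-input choices

- Constant slice → all-background mask with a warning (rescale undefined).
- Identical zone boundaries → zero-pixel rim, accepted with a warning;
  a core boundary leaving the rim boundary → error with the overlap
  fraction.
- SD_mean = 0 in the background region → explicit undefined-SNR error.
- Watershed on an empty mask → empty labeling; plateau maxima merge into
  one seed (no spurious splitting of rectangles or single discs).
- Mann–Whitney with a zero-variance normal approximation → p = 1.
- Pixel convention everywhere: 0-based (row, col), pixel centers at
  integer coordinates, slice 0 shallowest; calibration is explicit user
  input and file metadata is never trusted beyond a mismatch warning.

## Known limitations

- 2D per-slice counting means one cell spanning two analyzed slices is
  counted twice; the per-slice averages inherit this, exactly as in the
  manual protocol the chain reproduces.
- Phansalkar on signal-free noise frames segments speckle (see above).
- The fragment/event detector's recovered death frequency is calibrated
  at the canonical scene density; at substantially higher invasion-zone
  packing, fragment–nucleus merging biases it low by roughly one to two
  percentage points.
- `estimate_boundaries` assumes a roughly concentric, rim-dense specimen;
  fragmented or hollow specimens need manual ROIs.
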