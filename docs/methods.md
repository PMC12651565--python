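# Methods

## Pipeline model and assumptions

`ctcscan` operationalizes image-based rare-cell enumeration as a fixed
chain: nuclear segmentation on DAPI, cell/debris sorting, per-cell
background-corrected marker luminance, control-percentile threshold
calibration, strict-exceedance counting per 5 mL blood, and cohort
diagnostics. The chain assumes:

- nuclei are the detection anchor — every candidate must have a DAPI
  nucleus; marker staining is a surface halo around it;
- marker intensity is additive on the 8-bit gray ("lumen") scale, and
  slide-to-slide staining differences are predominantly additive and
  smooth, so a local background subtraction makes luminances comparable
  across samples;
- healthy-control cells define the null luminance population; a CTC is
  operationally a cell whose corrected luminance exceeds a stated
  percentile of pooled control cells.

## Stage conventions and defaults

**Grayscale / binarization.** Channels are converted to an
8-bit-equivalent scale ([0, 255], dtype full range; BT.601 luma for
RGB). The Otsu threshold is the level `t ∈ [0,255]` maximizing
between-class variance of `{≤t}` vs `{>t}` over the 256 integer levels;
foreground is *strictly above* `t` (ties to background), lowest level on
ties. Implemented by cumulative histogram; tests compare against an
explicit per-level enumeration.

**Closing.** "Three expansions and three contractions": 3 binary
dilations then 3 erosions with the same structuring element, default a
3×3 cross (4-connectivity), config-exposed. Erosion treats out-of-image
as foreground so closing remains extensive at borders.

**Watershed.** Markers are local maxima of the Euclidean distance
transform with minimum separation 10 px (at the 0.377 µm/px, 20×
scanner class; config-exposed); flooding on the negated distance map
restricted to the mask. Labels are relabelled contiguously from 1.

**Size filter.** Regions outside 20–2000 µm² are dropped — below
nucleus scale is optical noise, above is aggregates. The filter is not
part of the original detection description but is required to suppress
single-pixel noise; it is logged and config-exposed.

**Cell vs debris.** Ten shape/texture features (area, eccentricity,
solidity, circularity 4πA/P², perimeter, DAPI mean/std/entropy,
boundary gradient, bbox aspect). Model: standardized, class-weighted L2
logistic regression (auditable coefficients; class weighting because
true cells vastly outnumber debris in some preparations and vice versa
in others), seeded stratified 5-fold CV accuracy reported. Decision
threshold 0.5 by default — lower it to trade reviewer burden for
recall. Human review labels always override machine labels.

**Luminance.** Per-cell cutout with a 10 px margin. Background level =
median of marker pixels outside the nuclear mask dilated by 3 px;
corrected = raw − background clamped at 0 (an *additive* correction —
the stated aim is removing staining-condition offsets and nonspecific
luminescence; a multiplicative model is not supported by that goal).
Stained foreground = Otsu within the corrected cutout, restricted to
the cell's own dilated mask so neighboring cells inside the cutout
frame cannot contaminate the measurement; degenerate Otsu (constant
patch or < 3 px foreground) falls back to the DAPI mask and is flagged;
an all-zero patch scores 0 by convention.

**Calibration.** Threshold at coverage C = nearest-rank upper order
statistic, the m-th smallest of n pooled control values with
m = ⌈C/100·n⌉. Chosen over interpolated percentiles because it
guarantees "include C % of all cells" as an inequality on the training
data; linear interpolation is available behind a switch. Pooling is
across all cells of the training controls, not per-control averages.
The training controls are selected by a seeded uniform draw and
excluded from the diagnostic test set.

**Counting & diagnostics.** Candidate count = cells with corrected
luminance strictly `>` threshold (ties negative); counts are per 5 mL,
other volumes scale linearly with round-half-up. Detection = count ≥ 1;
positivity = count ≥ the Youden cutoff (conventionally 2 cells/5 mL) —
both are reported, they answer different questions. AUC is computed
from midranks (exactly U/(mn), ties ½); SE by DeLong structural
components; the 95 % CI is computed on the logit scale and
back-transformed, giving asymmetric intervals that respect [0, 1].
Youden cutoff = smallest integer cutoff maximizing SN + SP − 1. The
paired DeLong test includes the covariance of components across assays
scored on the same samples; a degenerate zero variance yields p = 1
with a warning. Fisher's exact two-sided p follows the probability-mass
convention (sum of hypergeometric probabilities ≤ the observed table's,
with the customary 1+1e-7 tie slack); chi-square is Pearson df=1
without continuity correction; the choice between them is always
caller-specified. Mann–Whitney uses exact enumeration for
n₁+n₂ ≤ 12 without ties, otherwise the tie-corrected,
continuity-corrected normal approximation.

## The simulator

`ctcscan.simulate` emulates a negative-enrichment slide: anti-aliased
elliptical nuclei (eccentricity ≤ 0.6) with lognormal radius (default
median 10 px ≈ 7.5 µm diameter at 0.377 µm/px — inside the 20–2000 µm²
nucleus filter with margin); per-cell marker expression drawn from a
two-component lognormal on the 8-bit scale (background population for
ordinary blood cells, an elevated population for spiked CTCs; defaults
put the healthy EpCAM distribution's bulk in the low tens of lumens
with a long tail, and CTC EpCAM well above the 95 % control percentile,
while CSV is only weakly elevated in CTCs — an epithelial-vs-
mesenchymal contrast); marker signal rendered as a constant halo on the
nuclear mask dilated 2 px (surface staining, deliberately simplified);
debris as thresholded smoothed-noise blobs with low solidity and
moderate, textureless DAPI; then a degree-2 polynomial additive
background gradient, optional radial vignetting, Gaussian sensor noise,
and clipping to bit depth — in that order. Objects are placed by
dart-throwing with a no-overlap constraint; an impossible packing
raises rather than silently overlapping. One RNG stream per scan,
seeded per sample from the cohort seed, makes any sample regenerable in
isolation.

What it does **not** emulate: optical PSF and defocus blur, spectral
bleed-through, photobleaching, cell clusters/doublets, anucleate
debris that mimics nuclei, or non-additive staining artifacts. Passing
tests therefore demonstrate correctness of the measurement and
statistical machinery under a controlled forward model — not clinical
performance on patient slides.

## Desk-scale experiment defaults

Cohort experiments (`pipeline.run_simulated_cohort`,
`scripts/acceptance.py`) use 224×224 px fields with 25 background cells
per sample, noise σ = 2, gradient amplitude 8, cohorts of 38 cases and
17 controls with thresholds calibrated on 10 random controls, and
Poisson spike-in counts per case. These sizes keep a 20-seed,
multi-level experiment within desktop runtimes while preserving the
cohort's statistical structure; the 224 px field leaves enough free
area to pack the largest plausible spike-in draw without forced
overlap. With 25 cells per control sample, a 10-control calibration
pools ~250 cells, so calibrated thresholds carry visible sampling noise
around the analytic quantile — exactly as small real control sets do.

## Numerical notes and edge cases

- Determinism: identical (config, seed) reproduces scans byte-for-byte;
  classifier training and control selection are seeded.
- Constant images have no Otsu split: `binarize` warns and returns an
  empty mask; within cutouts the measurement falls back to the DAPI
  mask.
- Empty masks watershed to an empty labelling (0 regions), not an
  error; an empty luminance set cannot calibrate a threshold (error).
- Focus stacking picks the lowest Z index on sharpness ties; region
  ordering is (bbox row, col, label); Youden ties break to the smallest
  cutoff — all deterministic tie-breaks.
- The stitcher blends overlaps with linear feather weights; identical
  overlapping content reproduces the original to ≤ 1 gray of rounding.

## Known limitations

- Per-tile (not per-pixel) focus selection; translation-only stitching
  at nominal grid offsets (calibrated-stage assumption).
- Global (not tile-local) binarization per stitched image.
- The debris model is a stand-in: no quantitative description of real
  debris/optical noise was available, so classifier performance numbers
  on synthetic debris do not transfer to real slides without
  re-annotation.
- Thresholds do not transfer across instruments or staining batches; no
  calibration-transfer model is provided.
- No survival/prognostic modelling and no multivariate clinical models.
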