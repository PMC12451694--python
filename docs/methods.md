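# Methods

This note documents what the package computes, the modelling and numerical
choices behind it, and what the synthetic benchmark does and does not show.

## The measurement

Each annotated cell is processed independently within its outline polygon:

1. **Background.** Per channel, the median intensity over all pixels outside
   the union of the cell outlines (`outside_roi_median`); a fixed value can
   be supplied instead.  Subtraction clips at zero.  If no pixel lies outside
   the outlines the global 5th percentile is used (logged); with no outlines
   at all, the whole-image median.
2. **Nuclear mask.** Otsu's threshold (or a fixed value) on the
   background-subtracted DAPI intensities restricted to the outline;
   connected components smaller than `min_nucleus_area` (default 50 px²) are
   removed, holes filled, and the surviving components are united — a
   multinucleated cell yields one combined nuclear mask and a nucleus count.
   Podocytes are frequently binucleated, and the outcome is defined per cell,
   not per nucleus.
3. **F-actin⁺ mask.** Otsu (or fixed) threshold on the background-subtracted
   actin intensities in the outline; all supra-threshold pixels, no size
   filtering.
4. **FAR.** With the default `actin_positive` denominator,
   `FAR% = 100 · Σ I_actin over (nuclear ∩ actin⁺) / Σ I_actin over actin⁺`.
   The `whole_cell` alternative (sums over the full nuclear mask and the full
   outline) is kept as a configuration for sensitivity analysis.  Which
   denominator a given Fiji-style workflow uses is generally ambiguous from
   published figure legends; restricting to the thresholded F-actin⁺ area is
   the default here because the thresholding step visibly defines the
   measured compartment, and because it is robust to the clipped-noise
   inflation that biases whole-outline sums downward at realistic noise
   levels (measured ≈ −5 points at a true nuclear fraction of 0.40).

Degenerate inputs never invent a threshold: a constant in-ROI histogram, an
all-zero DAPI region or a zero denominator flag the cell (`no_nucleus`,
`empty_actin`) and exclude it downstream; cells touching the image border
are flagged `border` by default (partial cells bias intensity sums).  Every
exclusion is counted and logged; flagged cells stay in the output table.

### Coordinates and rasterization

Vertex coordinates are 0-based (row, col) with integers on pixel corners:
pixel (r, c) spans [r, r+1) × [c, c+1) and has its center at
(r+0.5, c+0.5) — the ImageJ polygon convention, so imported `.roi` files
line up without offsets.  A pixel belongs to a polygon iff its center is
covered (interior or boundary; boundary tolerance 1e-6 px).  The test suite
pins this against a brute-force per-pixel ray-casting oracle.  The
point-in-polygon kernel runs in single precision; its worst-case
cancellation error (~1e-11 in squared distance) is six orders of magnitude
below the boundary tolerance.

## Statistics

The experimental unit is the independent replicate, not the pooled cell:
per-cell FAR is first averaged per donor × sample × replicate (flagged cells
excluded), and group comparisons run on those means with N = 3 by default.
Pooling thousands of cells would treat pseudo-replicates as independent and
inflate significance.

* **Pairwise test:** unpaired Student's t-test (equal-variance) by default,
  Welch as an option.  Zero pooled variance with equal means returns p = 1;
  with unequal means it is an error.
* **Dunnett's many-to-one procedure** applies automatically when one control
  faces ≥ 2 samples within a donor family; both the pairwise and the
  adjusted p are always reported, and the significance stars of the primary
  read-out come from the pairwise test (matching how such crossmatch figures
  are usually annotated).  The adjustment uses the multivariate-t
  distribution of the max-|t| statistic over the pooled ANOVA error
  (`scipy.stats.dunnett`, randomized-QMC, seeded).  Each adjusted p is
  floored at its single-comparison pooled-error p: that bound holds exactly
  for the max-|t| distribution, and flooring absorbs the QMC estimator's
  small Monte-Carlo error so the monotonicity guarantee is exact.  Note the
  guarantee is stated against the pooled-error single-comparison p (same
  error, same df); against a two-group-only Student t (fewer df) no such
  inequality holds in general.
* **Significance ladder:** boundary-inclusive, ns / * (p ≤ .05) / **
  (p ≤ .01) / *** (p ≤ .001) / **** (p ≤ .0001).
* **Inter-observer agreement:** cells paired by id across two annotation
  sets; per-cell relative difference (FAR_A − FAR_B)/mean(FAR_A, FAR_B)·100
  (Bland–Altman style denominator), summarized as mean ± SD, with the
  correlation between the relative difference and the pairwise-mean FAR
  reported (not enforced) as the effect-size-independence diagnostic.

## The synthetic generator

Each scene is a field of non-overlapping elliptical cells (semi-axes ~34–46
× 22–30 px, random orientation) with one nucleus (~0.42–0.50 of the cell's
semi-axes, ≈ 20 % of its area) or, in 25 % of cells, two smaller nuclei.
The actin channel is built from anti-aliased random chords across the cell
(20–60 per cell, Gaussian cross profile σ = 1.5 px, amplitude jitter):
cytoplasmic chords are masked out of the nucleus, and the nuclear component
is the same chord texture clipped to the nucleus.  The two components are
scaled analytically so the noiseless nuclear share of total actin equals the
prescribed ρ exactly; ρ is therefore the ground-truth analogue of FAR.  The
DAPI channel is a smooth per-nucleus profile, zero outside nuclei.  Noise:
Poisson on signal + background (gain 1.0), then additive Gaussian read noise
at 2 % of the maximum signal in the field — one detector serves both
channels, so the read noise is a single absolute level (typically set by the
DAPI peak) — then 16-bit quantization.  Identical (spec, seed) pairs are
bit-identical, including the files on disk.

Two intensity choices are deliberate and matter:

* **Per-cell total actin ≈ 1.4–2.2 × 10⁵ counts** puts fiber-pixel SNR
  against the read noise at ~3–6.  In this regime the intensity lost below
  the Otsu threshold is balanced between nucleus and cytoplasm and the
  measured FAR recovers ρ with < 1.5-point bias across ρ ∈ {0.15, 0.25,
  0.40}.  This calibration exists because the generator's purpose is
  parameter-recovery benchmarking; it is a property of the benchmark, not of
  the assay.
* **Limitation:** at much higher actin SNR the `actin_positive` read-out
  over-weights whichever compartment is per-pixel brighter (up to ≈ +18
  points at ρ = 0.40 in a low-read-noise variant), because a single
  threshold then cuts the two compartments' intensity distributions
  asymmetrically.  Measured FAR is a faithful *relative* injury score in any
  regime, but its calibration against a physical nuclear fraction depends on
  the noise model — a caveat that applies to the real assay as well.

What the generator does not emulate: touching or overlapping cells (the
assay analyzes singular annotated cells), fiber curvature and anisotropic
stress-fiber bundling, uneven illumination, z-structure, or chromatic
offsets.  Passing tests therefore demonstrate correctness of the
quantification and statistics pipeline under controlled conditions, not
performance on real microscope data.

The default study design emulates a pre-transplant crossmatch: donors D1–D5
× (PDP control + patient samples P1A–P4A) × 3 replicates (75 image sets),
30 cells per replicate; effect map: baseline ρ = 0.15 everywhere, ρ = 0.40
for the injurious samples P1A/P2A/P4A on susceptible donors D1/D2/D4,
ρ = 0.25 on the intermediate donor D5, with D3 resistant and P3A
non-injurious throughout.  One control and four patient samples keep the
default at the documented 75-set size; the qualitative pattern (a resistant
donor, a null patient sample, graded susceptibility) is the point, not the
patient count.

## Problem sizes and tolerances used in validation

* Oracle equivalence: 24 random/two-level toy rasters plus the 4×4
  hand-checkable example, exact equality (integer intensities make the
  float64 sums exact).
* Ground-truth recovery: the full default study (75 images, 2250 cells),
  group-mean FAR within 3 points of 100·ρ.
* Discrimination: 200 simulated experiments (3 control, 3 injured, 3 null
  replicates each, 30 cells per replicate); detection of ρ 0.15 → 0.40
  required in ≥ 90 %, false flags at ρ = 0.15 in ≤ 10 %.
* t-test calibration: 1000 null simulations at the replicate level,
  rejection rate within [0.03, 0.07] at α = .05.
* Dunnett: k = 1 reduction to the t-test within 1e-9; adjusted ≥
  pooled-error marginal on random inputs; null familywise rate over 1000
  runs ≤ 0.05 + 3 SE.
* Annotation robustness: ±2 px uniform vertex jitter on 30 cells across
  ρ ∈ {0.15, 0.25, 0.40}; |mean relative difference| ≤ 10 % (observed
  ≈ −2.4 % ± 1.5 %).

## Known limitations

* The ImageJ ROI dialect stores vertices at integer precision (the classic
  format); the JSON dialect is lossless.  Round-trips are exact at each
  dialect's declared precision.
* Multi-point and line ROI kinds are rejected rather than coerced.
* No hierarchical model of cells-within-replicates: replicate means are the
  unit, which is conservative for cell-level inference.
* The crossmatch matrix reports group means and significance; it makes no
  clinical recurrence call.
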