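# Methods

## The measurement problem

A stain-free morphometry device must produce, per sperm cell, four head
endpoints — length (µm), width (µm), length-to-width ratio, and
acrosome-area-to-head-area ratio (%) — that agree with the reference
workflow (chemical staining, bright-field imaging, manual measurement per
WHO protocol) well enough that a WHO2021 strict-criteria classification made
from them is trustworthy. `qpmorph` implements both the measurement and the
agreement/repeatability/concordance statistics, and validates the whole
chain against a synthetic study whose ground truth is exact.

## Synthetic study model

**Geometry.** A sperm head is modelled as a solid ellipse with semi-axes
L/2 × W/2 at a random orientation. The acrosome is the anterior cap cut by a
chord perpendicular to the major axis. For a chord at normalized position
t = c/(L/2), the cap area fraction is `(acos t − t·sqrt(1−t²))/π`, which is
inverted numerically (Brent) so the rendered cap fraction equals the
requested `acrosome_pct` exactly up to pixelation. The cap carries 0.6× the
nuclear phase density — the acrosome is the lower-dry-mass compartment —
and an optional thin posterior tail carries 0.3×. Gaussian blur (px) and
additive Gaussian noise (a.u.) model optical softness and detection noise.
Pixel size defaults to 0.05 µm/px so a 3 µm head spans 60 pixels; rendering
refuses pixel sizes coarser than W/4.

**Population.** The generator has no access to a real population, so truth
distributions are fully specified by construction: a-priori-normal cells are
uniform inside every WHO2021 range (length/width resampled until the implied
ratio also complies), a-priori-abnormal cells are uniform over each range
inflated by 30 % of its width on both sides, rejected until at least one
endpoint is outside its range by ≥ 5 % of the range width. Hence normal
truths violate nothing and abnormal truths are unambiguously abnormal —
deliberately cleaner than real biology, where grading is fuzzy.

**Study design.** Defaults emulate the validation design: 73 subjects × (11
a-priori-normal + 11 a-priori-abnormal) = 1606 cells, two modalities, two
replicates per cell per modality ("two intervals of the same recording").
The a-priori-normal share for an arbitrary cohort defaults to 0.61, the
analysed cohort's composition (199 of 326).

**Noise model.** Observed endpoint = truth + modality bias + between-cell
measurement noise (drawn once per cell per modality) + replicate noise. The
ratio receives no direct noise; it is recomputed from the noisy length and
width, so its error structure is emergent. Per-endpoint `repeat_sd` is
parameterised as the SD of the replicate-1 − replicate-2 difference (the
quantity a repeatability analysis reports); each replicate draw therefore
has SD `repeat_sd/√2`. Defaults take the validation study's reported values
as the operating point: stain-free bias (+0.18 µm length, −0.26 µm width,
+5.7 points acrosome; reference unbiased), repeat SDs 0.13/0.10/7.49
(stain-free) vs 0.32/0.29/9.29 (reference), and between-cell SDs solved —
split equally between modalities — so the SD of the between-modality
replicate-mean difference matches the reported agreement SDs (0.32 µm,
0.29 µm, 9.6 points). Negative length/width draws are floored at 0.1 µm and
flagged; acrosome percentages are clipped to [0, 100] likewise.

**Exclusions.** Each cell × modality is excluded with independent
per-reason Bernoulli draws; the first firing reason in the order movement →
focus → borders → flatness wins (movement is judged before imaging in the
acquisition workflow, so it takes precedence). Device-side default rates are
the published tally (38/1451 movement, 593/1451 focus); reference-side rates
keep the published reason proportions and are scaled so the expected
doubly-measurable share of cells is ≈ 22.5 %, the analysable fraction of the
real study, whose own exclusion arithmetic is internally inconsistent and is
not reproduced count-for-count. Excluded records carry only their reason
(endpoints NaN).

## Measurement chain

1. **Focus gate**: variance of the 3×3 Laplacian response normalised by the
   squared mean foreground (Otsu) intensity — scale-invariant and
   monotonically decreasing in blur. The gate threshold is calibrated once
   per pixel size as the score of a canonical noiseless 4.5 × 3.0 µm render
   blurred at σ = 2 px (there is no published criterion; the calibration
   sigma is a config parameter).
2. **Segmentation**: global Otsu threshold on phase values, morphological
   opening (disk, radius 2 px) to remove the thin tail, largest connected
   component with area ≥ 2 µm² (well below any plausible head) as the head
   mask.
3. **Axes**: length = 4·sqrt(λ_major), width = 4·sqrt(λ_minor) of the mask's
   covariance eigenvalues, scaled by pixel size — parameter-free and exact
   for a solid ellipse, which is why it was chosen over contour fitting.
4. **Acrosome**: Otsu split of phase values within the head; the lower-mean
   compartment is the acrosome. This is the no-tail convention for anterior
   disambiguation: the cap is the lower-density compartment by the physics
   of the phantom (and of dry-mass imaging). If the two compartments differ
   by less than a relative contrast floor (default 0.1), the cell is
   signalled as "unclear borders" rather than measured.

Gate failures become exclusion reasons on the record, not exceptions; an
empty/constant image gets the distinct reason `no_cell`. Coordinates are a
0-based row/column grid, origin top-left; lengths are always µm.

On 200 noiseless renders the chain recovers truth with median axis error
≈ 0.1 % and median acrosome error ≈ 0.02 points (the acceptance script
recomputes these); the stated tolerances (2 %, 3 points) leave headroom for
blur and noise at the study defaults.

## Statistics

**Bland–Altman.** Per-cell differences use the replicate-mean convention:
each modality's replicates are averaged first, then differenced (stain-free
minus reference, so a positive length bias means the stain-free modality
reads longer). bias = sample mean, sd = sample SD with n−1, LoA = bias ±
1.96·sd. Cells missing either side are dropped and counted.

**Maximum allowed limits.** The outer tolerance band half-width defaults to
`AL = sqrt(ref_repeat_sd² + 0.1·agreement_sd²)`: the reference method's own
repeatability SD combined with a 0.1 variance down-weight of the agreement
SD, restoring the endpoint's units. The source expression is typographically
ambiguous, so two alternate readings — `sqrt(r² + (0.1·a)²)` and `r + 0.1·a`
— are selectable by config; all three are monotone in both arguments.

**Repeatability.** Same construction on replicate-1 − replicate-2
differences within one modality (first two replicates by index). Modalities
are compared by the ratio of their repeatability SDs with a 95 % bootstrap
percentile interval (default 2000 resamples, each difference vector
resampled independently); "significantly different" iff the interval
excludes 1. A bootstrap was chosen because the underlying significance claim
names no test and the difference vectors are paired within cell but not
across modalities.

**Classification and concordance.** A cell × modality is classified from
its replicate-mean endpoints (ratio recomputed from mean length and width,
consistent with the difference convention). WHO2021 bounds are inclusive:
the cohort characteristic values (4.7 µm, 3.2 µm) sit exactly on upper
bounds and must be classifiable as normal; an exclusive-bounds switch
exists for sensitivity analyses. Concordance uses *abnormal* as the
positive class — sensitivity is the fraction of reference-abnormal cells
the stain-free modality also flags — which inverts the usual diagnostic
convention and is stated on every result object. Conversion rates
(a-priori-normal cells confirmed normal) are reported rounded to integer
percent; exclusion-tally percentages are half-up to one decimal and always
recompute exactly from their counts.

## Numerical and reporting choices

* Every generator and statistic is deterministic under a fixed seed
  (numpy `default_rng`/`SeedSequence`); pipeline outputs are byte-stable,
  embed the seed and a configuration hash, and CSVs round-trip doubles
  exactly (`%.17g` write, round-trip parse).
* Sample SDs use n−1 throughout.
* Degenerate inputs fail loudly and specifically: empty tables, single
  replicates, zero reference-abnormal cells (undefined sensitivity), zero
  denominator SDs (undefined ratio) each raise a dedicated error, and the
  pipeline names the stage that hit it.

## What the synthetic validation does and does not show

Passing tests demonstrate that the measurement chain is unbiased and
precise on phantoms it can model, and that the statistical machinery
recovers the parameters the tables were simulated with — i.e. the pipeline
is internally correct at the study's sample sizes. The phantom omits real
QPM phenomenology (speckle, halo artifacts, debris, overlapping cells,
vacuoles, partial focus across the head), models the acrosome as a perfect
chord cap, and draws truth from boxes rather than a biological population;
agreement or sensitivity numbers on synthetic cohorts therefore
characterise the configured noise model, not any real device. Emergent
quantities (everything involving the length-to-width ratio, the end-to-end
sensitivity/accuracy, the characteristic medians) are consequences of the
configured model, and are reported as such rather than tuned to match any
external figure.

## Problem sizes

The default study (73 × 22 cells, tables only) simulates and analyses in
~2 s. Tests render images at 0.05 µm/px on ~170 px canvases; the deepest
suite member measures 200 rendered cells. The acceptance script runs the
full default pipeline once plus an 824-cell repeatability cohort and the
200-render oracle.
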