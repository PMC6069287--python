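# Methods

## Indices and the ratio mechanism

CI_red-edge = R783/R705 − 1 is approximately linear in canopy chlorophyll
without saturating at high leaf area; PSRI = (R680 − R500)/R750 rises with
the carotenoid:chlorophyll ratio of a senescing canopy. Heavy-metal stress
pushes the two in opposite directions, so their ratio HMSSI = CI/PSRI
multiplies the class contrasts: if adjacent stress classes differ by a
factor g in CI and 1/g in PSRI, they differ by g² in HMSSI, while
independent noise in the two components adds only in quadrature. Both
components are degree-0 homogeneous in the bands, so a multiplicative error
common to all five bands cancels exactly in CI, PSRI *and* HMSSI; an error
common to the two *index values* (e.g. a canopy-level brightness effect
entering both) cancels in HMSSI only. R750 is served by the 740 nm
Sentinel-2 band 6; the symbol keeps the original index definition's
wavelength, the band assignment follows the MSI band set.

Numerical guards: a denominator with magnitude below 1e-6 reflectance units
marks the pixel invalid (nodata) rather than producing infinities. Negative
PSRI — possible over healthy canopy, where PSRI commonly sits between −0.1
and 0.2 — propagates with its sign into HMSSI and is never clipped; the
raster operation logs how many pixels were signed this way. Negative input
reflectance is a domain error.

## Misjudgment rate

For one index on one acquisition, each class's *range* is the closed
[min, max] of its sampled pixel values (a configurable percentile trim is
available but off by default, since the statistic is defined on the full
distribution envelope). The class's *overlap region* is the union of
intersections of its range with the other classes' ranges; its misjudgment
rate is the fraction of its samples inside that region, with boundary
samples counted as misjudged (closed intervals — the conservative choice).
Invalid index samples are excluded from both the ranges and the
denominator and reported separately. Rates are kept at full precision
internally and rounded to whole percents only in the CSV report, which
labels every row with its acquisition date. Because ranges and membership
are order statistics, the rates are invariant under any strictly monotone
transform of all samples — useful both as a property test and because it
makes the statistic insensitive to index rescaling.

## The random-forest monitoring model

Features are per-pixel HMSSI values at the acquisitions of a stage subset
(booting / flowering / mature: two dates each; whole growth: all six),
ordered chronologically. Rows with any invalid feature are dropped at table
build (no imputation), with the count logged. The forest grows 500 trees
with mtry = ⌊√p⌋ (minimum 1, so p=2 → 1 and p=6 → 2) on bootstrap samples.
Labels are encoded in the fixed class order (high, medium, low), which also
breaks probability ties in voting deterministically.

Validation: a stratified random 30% holdout with a fixed seed provides the
headline confusion matrix; the forest's out-of-bag error on the training
split is reported alongside, since the two estimates answer slightly
different questions (independent-sample vs internal). Overall accuracy is
trace/total; kappa is Cohen's with pe = Σᵢ rowᵢ·colᵢ/n² (kappa is defined
as 1.0 when agreement is perfect, and 0.0 in the degenerate pe = 1 case);
user's/producer's accuracies are column-/row-wise and reported as
not-applicable for classes absent from the corresponding margin. Variable
importance defaults to normalised mean impurity decrease (shares summing
to 1), with permutation importance available as an option. Classified maps
are 8-bit GeoTIFFs (0 nodata, 1 high, 2 medium, 3 low); area percentages
are taken over classified rice pixels only.

## Raster model and I/O

Grids are north-up with square cells, cell-centre registered, 0-based
row/col, and half-open cell intervals [left, right) × [top, bottom) for
point sampling, so a point on a shared edge belongs to exactly one cell
(left/top inclusive). GeoTIFF I/O is implemented on tifffile with the
standard georeferencing tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA)
plus a JSON ImageDescription for the CRS string and scene metadata; the
in-memory boolean mask is authoritative for validity, with a float sentinel
(default −9999) on disk. Integer-scaled reflectance is auto-detected
(values beyond 1.5) and divided by a configurable factor, default 10000,
with the decision logged. Resampling to a common grid — all index bands are
natively 20 m except blue and red, and the workflow runs on a 10 m common
grid — is nearest-neighbour by integer factors: it preserves reflectance
statistics (never inventing values outside the source range), and any
contributing nodata cell propagates when aggregating. All stochastic
operations take an explicit integer seed; no global random state is used.

## Synthetic campaigns

The generator emulates the *structure* of a three-area field campaign: three
1 km × 1 km blocks (100 × 100 cells at 10 m) at high/medium/low stress on a
120 × 360 grid, six dates (12/24 July booting, 6/21 August flowering, 17/30
September mature), a rice mask over the blocks, 100 uniformly sampled plots
per area, and a soil-concentration table attached as metadata. Stress
enters in index space rather than through a radiative-transfer canopy
model: per class and stage, target means for CI and PSRI (defaults in
`data/synthetic_defaults.yaml`; CI ordered low > medium > high and PSRI the
reverse within every stage, CI declining and PSRI rising after flowering,
adjacent classes separated by ~1.27× per component ≈ 1.65× in HMSSI). Per
pixel and date,

    CI = target_CI · f · e_ci,   PSRI = target_PSRI · f · e_psri,

with f a shared lognormal "illumination" factor (log-sd `shared_sigma`,
default 0.15) and e_ci, e_psri independent lognormal factors with
coefficients of variation `cv_ci`, `cv_psri` (default 0.10). All factors
are mean-one (μ = −σ²/2) so empirical class means recover the targets.
Bands are then back-solved — r705, r500, r750 fixed at 0.04/0.04/0.42
(thin red-edge shoulder and blue, high NIR-side reflectance, representative
of a closed rice canopy), r783 = (CI+1)·r705, r680 = PSRI·r750 + r500 — so
every downstream computation runs through the real band-level chain. Bands
clip to [0, 1]; a configuration clipping more than 20% of rice pixels is
rejected as infeasible. Target PSRI is kept strictly positive (the
stressed/senescing regime) so the multiplicative model stays well defined.

`calibrate_to_misjudgment` tunes the two noise knobs by bisection, which
works because they separate: the shared factor cancels in HMSSI, so the
independent CV alone sets HMSSI misjudgment (calibrated on the *worst* cell
rate, default target 0.30, so that every class and date stays moderate),
after which the shared sigma alone inflates CI/PSRI overlap (calibrated on
the *best* cell rate, default target 0.80). Rates are averaged over several
generator seeds (default 5) because min/max ranges of 100 samples are
noisy. The default targets sit inside the regimes asserted downstream
(single-index rates ≥ 60%, HMSSI ≤ 35%) by a deliberate margin chosen from
the sampling variability of order statistics at n = 100, so fresh
out-of-sample seeds stay inside the bands.

## What the synthetic data does and does not show

The generator reproduces the statistical mechanism the method relies on —
opposite monotone index responses, a dominant shared multiplicative error,
stage-to-stage independence — and therefore demonstrates *that* the ratio
index and the multitemporal model behave as designed. It does not emulate
spatial autocorrelation, mixed pixels at field edges, cloud/shadow
contamination, phenological mislabelling, within-area contamination
gradients, or other stressors (water, nutrient) that mimic heavy-metal
symptoms; with equal-area blocks the area summary is ~⅓ per class by
construction. Accuracies measured here are accordingly optimistic upper
bounds for real campaigns, and passing tests validate the implementation
and the mechanism, not field-scale accuracy.

## Problem sizes and design choices

Tests and the acceptance script run at desk scale by design: 120 × 360
scenes, 100 plots/area, 100 sampled pixels per class for rates, 10–20
generator seeds for model comparisons, and 500-tree forests (smaller where
the property under test does not depend on forest size). The multitemporal
comparison uses 20 seeds because single-stage accuracies sit close to 1.0
and the mean dominance margin is a fraction of a percent. Open choices
resolved here: index math runs on the 10 m common grid (matching the
resampled product); validation is holdout + OOB (neither is privileged by
the workflow definition); kappa is reported unitless; acquisition dates are
always carried on report rows rather than left implicit.
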