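# Methods

This note documents the models, defaults and design choices behind the
package, and what the synthetic cohort can and cannot demonstrate.

## Vulnerability curves

The sigmoid is parameterised as
`PLC(Ψ) = 100 / (1 + exp((s/25)(Ψ − P50)))` so that `s` is the slope of
the curve at P50 in % MPa⁻¹ — the common convention for this family of
fits. Thresholds invert analytically:
`Ψx = P50 + (25/s)·ln(100/x − 1)`, and the implementation asserts
P12 > P50 > P88 (less to more negative). Fitting is bounded nonlinear
least squares (initial P50 = pressure nearest 50 % PLC, s = 40);
non-convergence returns a diagnostic object rather than raising, so
batch pipelines continue. Curves whose PLC never leaves [0, 5) or
(95, 100] carry no midpoint information and are rejected as degenerate.
Confidence intervals come from a seeded parametric bootstrap (residual
resampling from the fitted curve, percentile 2.5/97.5).

When raw conductances are supplied, Kmax is the mean of all points at
tensions at or above the −0.5 MPa reference. Native embolism defaults
to embolized/total tracheids (directly comparable with PLC); an
embolized/functional option exists because the field phrasing is
ambiguous.

## gmin from desiccation curves

The cuticular phase is selected as the longest terminal window (≥ 5
points) whose quadratic term is non-significant at α = 0.05 in a
`mass ~ t + t²` regression — i.e. the longest stretch at the dry end of
the record statistically indistinguishable from a straight line. A
numerically perfect linear fit (zero residual) counts as
non-significant, so noise-free synthetic series recover their
generating gmin to machine precision. The slope converts to conductance
via `gmin = (−dm/dt / 18.015 g mol⁻¹) / (A · Δw)` with
`Δw = es(T)(1−RH)/P` and es from Tetens
(`0.6108·exp(17.27T/(T+237.3))` kPa) — the same form the climate module
uses. Chamber defaults: 25 °C, RH exactly 0, 101.325 kPa.

Leaf-area basis matters: gmin scales with 1/A. The series carries
whatever area the caller supplies; a helper converts projected needle
area to total surface with the hemicylindrical factor (π+2)/2 ≈ 2.57.
The synthetic generator uses the projected basis throughout, so
generated and refitted values are directly comparable.

## Pit metrics and averaging order

Metrics are computed **per pit**, then averaged per tree, then per
class; class tests run on tree-level means (n = 5 trees of 10 pits
each) to avoid pseudo-replicating pits. The product of class means
(overlap × flexibility) is therefore only a consistency check, not the
reported valve effect — products of means and means of products differ.
The same ordering rule applies to the thickness-to-span ratio
((double wall / lumen)², computed per tracheid before averaging) and to
LMA (per needle). Pits with Da > Dt (no possible torus seal) keep their
negative overlap and are flagged, not clipped: clipping would bias
class means upward. Rows violating Da ≤ Dm or Dt ≤ Dm are rejected at
ingest.

## Growth

BAI is reconstructed outside-in: the last ring's outer radius is
anchored at the measured under-bark radius and earlier radii subtract
ring widths, which makes the total telescope exactly to
π(r_outer² − r_inner²). Because dbh is measured over bark, a helper
derives the under-bark radius as `dbh/2 × (1 − bark_fraction)` with
bark_fraction = 0.15 by default (configurable; whether a given study
used over- or under-bark radii is rarely stated, so both are exposed).
Two cores per tree are averaged before BAI. Zero-width (locally absent)
rings are allowed; no ring-inserting heuristics are applied. BAI is
log(x+1)-transformed only inside parametric tests, never in stored
series. Master chronologies are plain per-year means with sample depth;
cross-dating quality is the 20-yr moving Pearson correlation of each
series against the master.

## Statistics layer

Group comparisons follow one decision rule: Shapiro–Wilk per group; on
rejection (α = 0.05) apply log(x+1) and retest; if still non-normal use
the Wilcoxon rank-sum test; otherwise Welch's t (two groups) or one-way
ANOVA with pairwise Welch tests rendered as compact significance
letters (insert-and-absorb). All choices are logged in the result
object. Per-trait tests are reported unadjusted, matching common
practice in cohort contrast tables; multiple-testing adjustment is left
to the caller. Mann–Kendall uses the tie-corrected variance and
continuity-corrected z; for tie-free series of n ≤ 10 the p-value is
exact (Mahonian inversion-count distribution) because the normal
approximation is visibly off (up to ~0.02) at those sizes. Sen slopes
are median pairwise slopes. Identical constant groups are reported as
t = 0, p = 1 rather than NaN.

## Climate

PET uses the FAO-56 Penman–Monteith reference formulation on the
reduced-data pathway by default (solar radiation from extraterrestrial
radiation and √(Tmax − Tmin) with k_rs = 0.16; wind 2 m s⁻¹; actual
vapour pressure at Tmin; G = 0 at monthly resolution), since
semi-arid station records typically provide only Tmax/Tmin/P. Full
inputs override every estimate. Seasons are DJF/MAM/JJA/SON with
December assigned to the following year's DJF; incomplete seasons are
flagged and excluded from trends. Both Sen and OLS slopes are emitted
per decade.

## iWUE chain

Discrimination `Δ = (δₐ − δ_w)/(1 + δ_w/1000)`, the simple model
`Ci = Ca(Δ − a)/(b − a)` (a = 4.4 ‰, b = 27.0 ‰) and
`iWUE = 0.625·Ca(1 − Ci/Ca)` compose exactly to
`0.625·Ca(b − Δ)/(b − a)`; the suite asserts this identity to 1e-12.
Ci outside [0, Ca] flags a warning rather than raising — real wood
δ¹³C outliers occur, and the clipping policy belongs to the caller.
The packaged atmospheric table (`atmospheric_co2_d13c_synthetic.csv`)
is a synthetic approximation of the public global CO₂ and atmospheric
δ¹³C records, interpolated between era anchors; substitute a measured
table (columns `year, Ca, d13C_atm`) for real analyses.

## Isotope sources

The evaporation line is an OLS fit of δ²H on δ¹⁸O through soil and
recharge (well + river) samples of one date; the regional meteoric
line ships as the constant δ²H = 8.06 + 7.77·δ¹⁸O. Depth inference is
deliberately qualitative — an enrichment ordering annotation — because
biplot position, not a mixing model, is the evidential basis; Bayesian
mixing models are out of scope. The "stale water" diagnosis for
declining trees is implemented as offsets of late-summer xylem against
the spring line. The groundwater reference pools well and river
samples.

## Synthetic cohort

The generator emulates the study conditions of a 30-tree D/ND contrast:
15 trees per class; trait means and standard errors set to the cohort
table values (SE → SD via SE·√n with n = 15 for tree-level traits, 5
for anatomy subsets); ring series 1935–2020 built as tree mean ×
age trend × common lognormal year effect (σ = 0.15, the cross-datable
signal) × drought-year suppression (×0.5 for D, ×0.75 for ND) ×
lognormal noise; vulnerability curves from each tree's true sigmoid
(slope ~N(40, 4), 2 % PLC noise, −0.5…−5 MPa in 0.5 steps);
desiccation series from the inverse gmin formula with a 15 % stomatal
fast phase and 0.5 mg balance noise; climate 1920–2018 with Iberian
interior normals (~12 °C, ~423 mm), a 0.25 °C/decade warming trend and
drought years at 40 % precipitation (2017 among them, which therefore
ranks driest); an iWUE divergence window 2014–2017 in which ND
discrimination drops by 1.2 ‰; and water-isotope structure in which
declining trees use shallower water and, in late summer, stay on the
spring evaporation line. Stem-core pits share pooled class means before
2017 and diverge only in the 2017–2021 window, reproducing the
"contrast emerges late" pattern. Where no published value exists (P50
dispersion, native PLC level, NSC means, within-tree variances) a
single realistic default was chosen and documented in the config; none
are validated against field variance partitions.

Traits are drawn independently within class (a correlation hook ships
as identity — no covariances are published), so the synthetic cohort
cannot demonstrate multivariate trait coordination, nor spatial
structure, stand dynamics, or measurement-protocol artefacts. Passing
tests show the estimators recover known generating parameters and that
the pipeline preserves the designed class contrasts; they are not
evidence about any real forest.

## Problem sizes

Defaults keep the full suite and report fast on one core: 15 trees per
class, 86-year ring series, 5-tree anatomy/carbon subsets, 500-replicate
P50 recovery and 200-replicate gmin bias checks, exhaustive
permutation oracles up to n = 8. The end-to-end report on the default
cohort takes well under a minute.

## Known limitations

- The Pammenter–Vander Willigen sigmoid is the only vulnerability model
  shipped (Weibull-type alternatives are hookable, not provided).
- The gmin phase detector assumes the cuticular phase is terminal; it
  will not find an interior linear segment followed by renewed
  curvature.
- FAO-56 monthly PET neglects soil heat flux; daily PET is not
  computed (daily data are aggregated to monthly first).
- Compact-letter displays can be non-unique when pairwise significance
  is intransitive; the insert-and-absorb construction is deterministic
  but other valid letterings exist.
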