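# Methods

This note documents the models, normalizations, and numerical choices
behind `mapshift`, and what the synthetic-data generator does and does not
emulate.

## Fractionation profiles

Input is a MaxQuant-style `proteinGroups` table: per protein group, per
experiment, a heavy/light SILAC ratio, its quantification-event count and
variability, and an intensity. The heavy channel is a single total-membrane
reference spiked into every light subfraction, so 1/ratio tracks the
protein's abundance in that subfraction.

Filters, in order:

1. identification filters — reverse hits, potential contaminants, and
   site-only identifications are removed (idempotent by construction);
2. SILAC quality — a ratio is *high quality* when it derives from ≥ 3
   quantification events, or exactly 2 events with ratio variability below
   30%;
3. completeness — the MR analysis uses only proteins with high-quality
   ratios in all 30 subfractions (5 fractions × 6 maps). No imputation is
   performed; a map-visualization protein set may instead require
   completeness only within the control maps (both filters are exposed).

A per-map profile inverts the five ratios and divides by their sum, so each
profile is non-negative and sums to 1 (tolerance 1e-9). The classifier
input is the 0–1 rescaled concatenation of both control replicate profiles
(10 values per protein); a constant profile has no dynamic range and maps
to all zeros with a logged warning.

## Organellar map and localization classifier

PCA follows the standard visualization convention: columns centered and
scaled to unit variance (zero-variance columns are dropped with a warning),
components ordered by decreasing explained variance.

The classifier is a one-vs-rest RBF support vector machine with
class-balanced weights; C ∈ {1, 10, 100} and gamma ∈ {scale, 1} are chosen
by grid search inside a stratified 5-fold cross-validation on the marker
proteins only. Reported metrics (per-class recall/F1, overall recall,
median F1) come from cross-validated predictions, so they estimate
generalization to unlabeled proteins. At prediction time a protein is
`unassigned` when the top one-vs-rest decision score beats the runner-up by
less than a margin (default 0.1, configurable) — the margin is on decision
scores, not probabilities, and its default is deliberately permissive.

## MR translocation analysis

The six maps share a single reference, so the normalization must preserve
total-signal information (membrane association changes) while removing
prep-to-prep scale:

1. within each fraction of each map, divide ratios by the column median;
2. invert every ratio;
3. multiply each fraction by its measured protein yield (BCA);
4. sum each map ("prep yield"), set the smallest to 1, and divide each map
   by its relative correction factor — afterwards all six map totals are
   equal (to 1e-9), and multiplying any single raw map by a positive
   constant is absorbed exactly.

Per protein and treatment, the 10 treatment and 10 control values are
divided by their joint sum, and control profiles are subtracted from
treatment profiles within replicates. The delta sign convention is
treatment − control; every statistic downstream is invariant to the
opposite convention. The two replicate deltas concatenate to a 10-vector.

**Outlier test.** An iterated trimmed estimator: initialize with the
classical mean/covariance of all delta vectors; in each of (at most) 101
iterations, retain the ⌈n·0.75⌉ rows with smallest squared Mahalanobis
distance and re-estimate from them, stopping early when the retained set
stabilizes. Ties in the distance ordering are broken by an infinitesimal
seeded jitter — the only use of randomness in the whole pipeline. A
singular covariance receives a small ridge (logged). Distances are then
rescaled so that the retained subset's median matches the χ²₁₀ quantile at
the subset-median's overall level, χ²₁₀.ppf(h/2n) — this consistency
correction makes the upper-tail χ²₁₀ p-values uniform on null data (checked
to ±0.5% at the 1% level on 5000 ten-dimensional Gaussian rows). Matching
the subset median to the χ² *median* instead would inflate all distances by
~15% and destroy that calibration.

**Scores and calls.** p-values are Benjamini–Hochberg adjusted per
treatment (each treatment is its own test family); M = −log₁₀(p_adj), so
M = 4 ⇔ FDR 0.01%. R is the Pearson correlation of the two 5-point
replicate deltas; a constant delta leaves R undefined (NaN) and the protein
is never called. Hits require M > 4 and R > 0.8 strictly; R = 0.8 is the
one-sided critical correlation at p = 0.05 with 3 df (exact value 0.805).
Shared hits are the intersection across treatments.

## Abundance analyses

**Significance A.** With r₀ the median and r±1 the 84.13th/15.87th
percentiles of the log-ratio distribution, the robust z of a value is its
distance from the median over the same-side percentile spread. The
one-sided tail is 0.5·erfc(z/√2); by default the reported p doubles it so
that p is uniform under a symmetric null — this calibrated two-sided p is
what the Benjamini–Hochberg step consumes in hit calling. The one-sided
variant is available (`two_sided=False`).

**Whole-cell hits.** Ratios are median-normalized per experiment and
logged. A protein is a per-drug hit when significant at BH FDR 0.05 in both
replicates *with the same direction*; common hits require significance and
one direction in all four experiments.

**Cytosol shifts.** Mean of four treatment replicates minus mean of four
vehicle replicates on median-normalized log₂ ratios, restricted to proteins
with ≥ 3 quantification events in every replicate compared. Group-level
contrasts (e.g. soluble lysosomal proteins vs all) use the two-sample
Kolmogorov–Smirnov test (asymptotic p). The per-replicate value matrix is
quantification-agnostic: SILAC log-ratios and label-free log-intensities
enter identically.

**Proteomic ruler.** Intensities are scaled to molecular mass and anchored
by equating summed histone MS intensity with the cell's DNA mass:

    copies_i = (I_i / MW_i[Da]) · m_DNA · N_A / Σ_h I_h,
    m_DNA = genome_bp · ploidy · 615.8771 g/mol / N_A.

Defaults: 2.7 Gbp genome, ploidy 2 (mouse), all configurable. Copy numbers
are invariant to global intensity rescaling and linear in I/MW. Replicate
intensities are first linearly normalized to a common summed total.

## Screen analytics

Wells with fewer than 500 cells are excluded (logged per plate). Each
response is divided by its plate's media-well mean, which removes
multiplicative plate effects exactly; plates without media wells are
excluded with an error record. Primary-screen fold change is computed
against the per-plate vehicle (DMSO) mean after media normalization —
"2-fold" is inclusive. Both reference conventions (media, vehicle) are
obtainable; vehicle is the default.

**EC50.** Duplicate normalized responses at six concentrations
(1.25–40 µM, 2-fold spacing) are log₂(x+1) transformed, averaged per
concentration, forced monotone by isotonic regression, interpolated with a
monotone cubic (PCHIP) spline against log-concentration, and mapped back to
the raw response scale. The EC50 is the concentration where the curve
crosses halfway between bottom and top. The bottom defaults to the known
no-drug baseline of 1.0 (plate normalization maps vehicle to 1); the top is
the fitted maximum. Curves still rising at 40 µM are flagged
`not_plateaued` — their maximal effect, and hence EC50, may be
underestimated, which is an inherent property of a within-window spline
method. Series that never reach (or start beyond) the half-effect are
censored `above_max` / `below_min`. EC50s are reported in µM.

**Enrichment and lysosomotropism.** Per primary-target/class annotation a
2×2 Fisher exact test (two-sided), reported raw and BH-adjusted; degenerate
margins give an undefined odds ratio. A compound is flagged lysosomotropic
when 6.5 ≤ pKa ≤ 11 and logP > 2; missing properties give an unknown flag.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, with
ground truth for every planted effect. Defaults mirror the study scale:
2000 mapped proteins, 12 compartments, 559 markers, duplicate maps for a
control and two treatments sharing one reference, a 786-compound screen
with ~4.5% true enhancers, and 100 "leaked" proteins shifted +2 log₂ units
in the cytosol only.

**Map sets.** Compartment mean profiles are drawn from a Dirichlet pool
with a uniform admixture floor (0.10) — the spiked reference keeps every
protein detectable in every fraction, so real per-map profiles have a soft
floor rather than true zeros. The pool is flattened toward a plane in the
per-fraction standardized metric (minor principal axes shrunk to 0.35)
because differential centrifugation orders organelles along a pelleting
continuum, making real cluster centroids near-planar in exactly the metric
the unit-scaled PCA uses; means are then a greedy farthest-point subset
with pairwise L1 separation ≥ 0.45. Each protein carries a fixed offset
from its compartment mean (sd 0.05, identical in all six maps) modelling
multi-localization and gradients: it spreads clusters realistically,
stabilizes the per-fraction medians the normalization relies on, and
cancels exactly in treatment − control deltas. Per-map measurement noise is
Gaussian on profile space (sd 0.02), clipped and renormalized. Movers mix
their baseline profile with a destination compartment mean,
(1−θ)·source + θ·destination, θ = 0.5 by default; 40% of movers are shared
between the two treatments. Measured ratios follow the mixing design:
ratio = scale_m · yield_f · reference_i / amount_{i,f,m}, with reference
abundance proportional to whole-cell abundance (log-normal, σ = 1),
per-map scale factors drawn in [0.5, 2], and fraction yields computed from
the realized amounts — so the full normalization chain is exercised.
Rendered `proteinGroups` tables add flagged decoys and low-quality rows to
exercise the filters.

**What the generator does not emulate:** missing values beyond the
all-present high-quality subset, peptide-level sampling, correlated
(isobaric-style) noise, compartment-size–abundance correlations, or
biological co-regulation. Passing tests therefore demonstrate correctness
of the procedures under the stated statistical assumptions, not performance
on any particular real dataset.

**Known limitation.** The within-fraction median normalization is
re-estimated per map, so its sampling noise creates small (≈1%)
between-map per-fraction scale differences. These produce a shared bias
across all proteins of a compartment whose profile aligns with the
fluctuation; in rare seeds (≈2% of null simulations) this yields a
compartment-clustered burst of false hits. The same mechanism exists in the
real procedure; it is why hit lists should be inspected for implausible
whole-compartment calls.

**Screen and abundance generators.** Hit compounds follow a four-parameter
logistic in concentration (bottom 1, top uniform in [3, 6], EC50
log-uniform in [2, 30] µM, Hill slope 2.5 — lysosomotropic accumulation is
threshold-like, and shallower slopes cannot plateau within the tested
window). Plates carry log-normal multiplicative effects (sd 0.15), wells a
10% response CV, and 2% of wells fall below the 500-cell QC limit. Ratio
experiments use Gaussian log₂ nulls (sd 0.3) with per-replicate global
offsets (sd 0.2) that the median normalization must remove.

## Problem sizes and seeds

Stochastic contracts are evaluated at the study scale: 20 independent
seeds for the null-calibration and mover-recovery suites (2000 proteins,
two treatments each), 5000 rows for the outlier-test calibration, 1e5
draws for Significance A, and 100 simulated compounds for EC50 recovery.
Every generator and the outlier test take explicit seeds; all generators
are bit-reproducible given (config, seed).
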