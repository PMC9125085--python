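# Methods

This note documents the models, rules and numerical choices behind
`microinvade`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Experimental-design model

A dataset is an ASV × sample integer count matrix plus one metadata record
per sample: compartment (snow, soil, flow_through, lab_control), experiment
(melt_rate, soil_ph), arm (treatment, control), condition (average/fast or
acidic/acidoneutral/alkaline), replicate, sampling day, and an optional
qPCR denominator (g of soil or ml filtered). Sampling days form a total
order DS < D-10 < D0 < D5 < D9 < D14 < D20 < D29: DS is the field-sampling
day, D-10 the microcosm set-up day, D0 the first experimental day. Days are
categorical, not integers, so DS and D-10 sort correctly; numeric offsets
for plotting live in a fixed lookup (DS at −110 days, reflecting the
100-day storage between sampling and set-up). D5–D29 are *post-start* days;
soil samples on DS, D-10 and D0 are *pre-treatment*. The standard layout is
two experiments × four arms × triplicate = 12 microcosms per experiment.

The melt-rate→volume conversion assumes a circular column cross-section.
The inner diameter is a design parameter defaulting to 30 mm — the unique
round value reproducing both reference conversions for a 50 ml centrifugal
tube (9 mm we/day → 6.36 ≈ 6.4 ml/day; 35 → 24.74 ≈ 24.7 ml/day). Printed
volumes are reproduced with round-half-up to one decimal, which matches
both figures; Python's default banker's rounding would not.

On-disk formats are tab-delimited; count tables carry ASVs as rows with a
leading `asv_id` column, and a table presenting samples as rows
(`sample_id` leading) is auto-transposed with a logged warning. A minimal
BIOM v1 JSON reader/writer (dense and sparse) is included for
interoperability; BIOM is plain JSON, so no external dependency is needed.

## Cleanup

**Detection rule.** "Identified" means count ≥ τ with τ = 1 by default —
presence in the ASV table. τ is exposed everywhere because taxa can sit
below the detection threshold; raising τ can only remove detections
(monotonicity is tested).

**Prevalence contaminant screen.** For each ASV, a 2×2 table of detection
in negatives (kit and run controls, pooled as a single batch) versus true
samples is scored with the one-sided exact hypergeometric tail probability
for enrichment in negatives. An ASV is flagged when the score falls below
the threshold (default 0.1, the conventional default for prevalence-based
screening) *and* its prevalence is higher in negatives; ASVs detected only
in negatives are flagged regardless of score. The exact tail is used
instead of a chi-square approximation because desk-scale designs have very
few negatives; the two agree asymptotically. Scores are verified against
brute-force enumeration of all 2×2 tables with margins ≤ 12.

**Control-abundance curation.** Any ASV whose *mean relative abundance*
across lab controls strictly exceeds its mean relative abundance across all
other samples is discarded. Mean relative (not raw, not maximum) abundance
makes the rule robust to sequencing-depth differences between controls and
samples. Neither rule can touch an ASV absent from every control sample
(tested as an invariant).

**Rarefaction.** Expected richness at depth d is the hypergeometric
expectation Σᵢ [1 − C(N−Nᵢ, d)/C(N, d)], computed in log-gamma space — no
resampling noise. It is non-decreasing in d and matches the mean of 10,000
Monte-Carlo subsamples within three standard errors on test fixtures.

## Community statistics

Shannon diversity uses natural logarithms (nats), the convention of the
ecology tooling this field uses; H ≤ ln(richness) with equality iff
uniform. Bray–Curtis is Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) on relative abundances; it is a
semimetric (triangle inequality not guaranteed), so this property is
documented, not asserted.

PCoA is classical scaling: eigendecomposition of the Gower-centred matrix
−½·J·D²·J. Negative eigenvalues (possible for semimetric dissimilarities)
are reported but uncorrected — no Cailliez/Lingoes — and their axes are
excluded from coordinates.

PERMANOVA partitions tr(G) over an *ordered* factor list with sequential
(Type I) sums of squares via nested orthonormal projections; the pseudo-F
for each term uses the full-model residual. Significance comes from
permuting sample labels with a seeded generator (bit-reproducible);
permutations are evaluated in vectorised chunks (~32 MB of permuted
matrices at a time). p-values use (1 + #{F\* ≥ F})/(1 + N), so p = 0 is
impossible and the floor is 1/(N+1). An exact mode enumerates all n!
permutations for small n and reports #{F\* ≥ F}/n!. On Euclidean distances
of one-dimensional data the pseudo-F equals the classical one-way ANOVA F
exactly (tested against `scipy.stats.f_oneway`, and against scikit-bio's
PERMANOVA on random distance matrices); under a two-group null the type-I
error at α = 0.05 calibrates to [0.03, 0.07] over 500 runs with 199
permutations.

The dispersion-homogeneity test embeds samples by PCoA keeping all axes;
negative-eigenvalue axes contribute *negatively* to squared distances to
the group centroid (clipped at zero before the square root). Group
centroids — not spatial medians — are used; medians would be a possible
extension. The F statistic is the one-way ANOVA F on centroid distances.
The permutation test reshuffles group labels and *re-fits centroids and
distances* for each permutation (a full re-fit, rather than permuting fixed
residual distances, since the reference procedure is ambiguous on this
point). If every sample coincides, the statistic is reported as the
degenerate no-dispersion case (F = 0, p = 1). Sums of squares at
rounding-noise scale (relative tolerance 1e-8 on the distance scale) are
treated as exactly zero so symmetric toys yield F = 0 rather than a ratio
of floating-point noise.

Factorial ANOVA uses sequential (Type I) sums of squares in the user's term
order, with interaction terms coded as combined-level indicators; rank
increments give the degrees of freedom, and an aliased term raises an error
naming it. Agreement with statsmodels' `anova_lm(typ=1)` is tested. Tukey
HSD uses the studentized-range distribution with the Tukey–Kramer
unequal-n standard error; for two groups it reduces to the pooled-variance
t-test (q = √2·|t|). The optional Bonferroni correction multiplies each p
by the number of test *families* (capped at 1) — the combination used when
several whole HSD families are reported side by side. Zero within-group
variance with unequal means reports the limiting p of 0.

qPCR normalisation is copies/reaction × (eluate volume / template volume) /
denominator, giving copies per g soil or per ml filtered.

## Colonisation classification

The candidate pool is computed dataset-wide: ASVs detected in ≥ 1 snow
sample, minus ASVs detected in any control-microcosm sample (soils and, by
default, control flow-through — "all samples from those microcosms"; a
switch restricts exclusion to control soils since the narrower reading is
also defensible) and minus ASVs detected in any pre-treatment soil (DS,
D-10, D0, both arms — D0 counts as pre-treatment because treatment begins
after the D0 sampling). Exclusion is applied before counting the
snow-unique pool, so pool − invaders = the number of snow-unique ASVs never
seen in treated soil (the bookkeeping identity 541 − 16 = 525 at
full-study scale).

Classification is then per experimental unit (experiment, condition), so
the same ASV can be an invader or colonist in several units; global counts
are union sizes. "Multiple days" means ≥ `min_days` (default 2) distinct
post-start days with detections pooled over replicates; days need not be
consecutive, because taxa may dip below the detection threshold and
reappear. Success additionally requires detection on the final day (D29)
in any replicate. Abundance trends are deliberately ignored — only
presence/absence enters. The nested chain successful ⊆ colonists ⊆
invaders ⊆ pool is asserted on every classification.

For the count ANOVA across units, the status definitions are re-applied
*within each replicate alone* (the replicate-level counting unit is not
uniquely determined by the workflow's description; within-replicate
re-application is the self-consistent choice and is exposed as such), and a
one-way ANOVA per category compares units with n = replicates per unit.

## Simulator

The generator emulates the post-denoising state of the experiment, not its
chemistry or hydrology: only the observable consequences of percolation,
washout and persistence are parameterised.

* Baseline communities are log-normal rank-abundance profiles (meanlog 0,
  sdlog 1.5) — a standard neutral-ish shape chosen as a declared modelling
  assumption, since real microcosm data pin down no particular abundance
  model. Soil-only,
  snow-only and shared blocks default to 120/60/20 taxa; shared taxa are
  floored at 5·10⁻⁴ relative abundance so pre-treatment soils reliably
  witness them.
* The snow community is compositionally stable across days by default
  (drift configurable), mirroring the tight clustering of snow samples.
* Planted invaders (default 12, of 60 snow-only taxa, at 5·10⁻³ relative
  abundance) arrive in treated soils on D5 with per-unit arrival
  probability 0.6, then persist through each subsequent sampling interval
  with survival probability 0.7, independently per replicate; the fast-flow
  condition multiplies survival by 0.6, encoding washout as a testable
  parameter. Planted taxa never occur in control microcosms or
  pre-treatment soils in the latent state, and multinomial sampling can
  only remove presences, so observed data obey the same constraint.
  Ground-truth statuses are derived from the realized latent trajectories
  with the same day-counting rules the classifier uses.
* Flow-through is a 40/60 snow/soil mixture (treatment) or washed-out soil
  (control), with a 2× relic-DNA boost of the soil component on D5 to give
  the qualitative day-5 spike; its magnitude is not a calibrated quantity.
* Contaminants (default 6) dominate lab controls at 0.15 relative abundance
  each; half also leak into every real sample at 2·10⁻⁴ so that both the
  exclusive and the diffuse contamination routes are exercised.
* Sequencing depth is fixed at 30,114 reads/sample (multinomial); depth
  variance is orthogonal to the presence/absence classification logic and
  is therefore not modelled. qPCR quantities are log-normal with
  compartment-level arithmetic means (snow 40.2 copies/ml; soil 5·10⁸/g and
  flow-through 2·10⁵/ml, orders of magnitude higher) and sdlog 0.5.

What passing synthetic tests show: the pipeline's *logic* is correct — with
certain detection the classifier recovers planted statuses exactly, and
degradation with detection probability behaves as expected. What they do
not show: robustness to real-data features the generator omits — variable
sequencing depth, compositional drift in snow, taxon-specific amplification
bias, index hopping, or abundance dynamics of native soil taxa responding
to water addition.

## Problem sizes and defaults used in checks

Recovery checks use the default design (4 units × 2 arms × 3 replicates,
~229 samples × ~206 taxa) at full depth with 20 planted taxa; permutation
tests default to 999 permutations in the pipeline and use 199 for the null
calibration (500 replicate null datasets of 10 samples); the contaminant
oracle enumerates all 1,639 2×2 tables with margins ≤ 12; exact PERMANOVA
enumeration is used for n ≤ 8. These sizes make every check exact or
tightly calibrated at desk scale.

## Known limitations

* Sequential (Type I) partitioning means results depend on term order; this
  matches the classical multi-factor semantics but users must order terms
  deliberately.
* The dispersion test's permutation scheme (full re-fit under label
  permutation) is one of several defensible choices; reference
  implementations permute model residuals and can give slightly different
  p-values.
* Bray–Curtis PCoA can produce negative eigenvalues; no correction is
  applied, and distance reconstructions are only exact for Euclidean
  inputs.
* The prevalence screen has low power with very few negative controls; the
  curation rule is the effective defence against abundant kit contaminants
  in small designs.
* The per-replicate ANOVA on invader/colonist counts treats replicates as
  independent units; with three replicates its power is limited and
  zero-variance cells can produce infinite F (reported as such).
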