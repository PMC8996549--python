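# Methods

This note documents the statistical model behind `indirect_ri`, the
numerical choices made where the design was open, what the synthetic
generator does and does not emulate, and the known limitations.

## Problem setting

A reference interval (RI) is the central 95% range of an analyte in a
healthy reference population, reported as the 2.5th and 97.5th percentiles
with 90% confidence intervals. Direct sampling recruits healthy children
a priori; indirect sampling extracts a presumed-healthy subpopulation from
routine outpatient (LIS) records, which mix healthy and pathological
values. The package implements two indirect partitioners — a univariate
3-component Gaussian mixture (GMM) and a 3×1 self-organizing map (SOM) on
the renal panel — and quantifies their agreement with a direct sample via
bias ratios.

All analyses run inside age/sex strata. The shipped scheme is creatinine in
three half-open age bands (1–<6, 6–<12, 12–<17 years) with the adolescent
band split by sex, and urea in a single 1–<17 y stratum; intervals are
half-open `[lo, hi)` in decimal years. Units: creatinine and uric acid in
μmol/L, urea in mmol/L.

## Cleaning chain

Steps, in order, each only ever removing records:

1. *Plausibility bounds* (config; defaults creatinine (1, 2000) μmol/L,
   urea (0.1, 100) mmol/L, uric acid (10, 3000) μmol/L). These separate
   data errors from biology; values outside are deleted outright.
2. *Deduplication*: one record per (subject, analyte), the earliest date
   (ties: lowest value, then input order). Rationale: repeat testing within
   the window implies a higher prior of pathology, and the first visit is
   the least selected one. The window is the whole extraction period; for
   single-year extracts this coincides with a per-year rule.
3. *Age filter* `1 ≤ age < 17`.
4. *Outlier removal per stratum*: if |bias-corrected skewness| > 0.5 the
   values are Box-Cox transformed, `y = (x^λ − 1)/λ` (log at λ = 0), with λ
   maximized over the normal profile likelihood (reported λ within 1e-4 of
   the optimum); Tukey fences `Q1 − 1.5·IQR` / `Q3 + 1.5·IQR` are computed
   on the working scale (quartiles by linear interpolation, type-7) and
   values strictly outside are flagged. Because the transform is monotone,
   flags computed on the transformed scale equal flags from the back-mapped
   raw fences; both fence scales are reported.
5. *Radical strategy* (optional, LIS): a subject flagged in any of
   creatinine, urea or uric acid is removed from all three. Subjects with a
   partial panel are judged on the evidence present, and their count is
   reported. Uric acid is screened in a single 1–<17 y stratum for this
   purpose even though no uric-acid RI is reported.

The skewness screen threshold (0.5) operationalizes an "as appropriate"
normality check; whether the transform fired is recorded per stratum.

An auxiliary greedy regression tree reproduces how such strata are derived:
binary splits on age restricted to integer-year cuts, chosen to maximize
within-leaf variance reduction, with a per-leaf sex split retained when it
reduces the leaf's pooled SSE by a configurable relative gain (default 1%).
The published scheme ships as the default, so pipeline results never depend
on tree behavior.

## Transference

Between-analyzer conversions are affine maps with positive slope. Two
published chains through a common source platform compose as
`slope = s_ac / s_ab`, `intercept = i_ac − slope · i_ab` (invert one leg,
apply the other). Composed coefficients are carried at full precision;
3-dp values are display only — the printed transferred means can only be
reproduced consistently with the full-precision slope, with residual 0.1
discrepancies fully explained by the 1-dp rounding of the printed source
means.

## GMM partitioning

Per stratum, LIS values are modelled as a 3-component univariate normal
mixture (low / healthy / high). Initialization is the method's defining
feature: component means start at the *transferred direct sample's*
quartiles (Q1, median, Q3) and all SDs at its sample SD, anchoring the
middle component in the healthy range. Initial weights are equal thirds
(unspecified in the source method; configurable).

EM alternates exact posterior responsibilities with weighted moment
updates; convergence when the relative log-likelihood change is < 1e-8
(configurable) or 500 iterations. Numerical choices: densities in log space
with log-sum-exp; component SDs floored at 1e-3 × sample SD (collapse
guard, warned); hard assignment by argmax responsibility with ties to the
lower-mean component. The healthy cluster is the component with the middle
*fitted* mean — EM may reorder components, so the middle is identified
after convergence. Hard (not probability-weighted) selection is used to
form the healthy subset.

A caveat documented by the tests: on genuinely single-component data the
three fitted components remain heavily overlapping rather than coinciding
(overlapping decompositions of a normal are near-equivalent in likelihood),
and the middle cluster is a central subset of roughly a third of the data.
Degenerate inputs therefore yield a conservative healthy subset, not the
whole sample.

## SOM partitioning

Subjects with a complete (creatinine, urea, uric acid) triple are clustered
jointly. Each variable is standardized (mean 0, SD 1, n−1 denominator).
The 3×1 map is initialized by PCA: codebooks at −2.5, 0, +2.5 SDs of the
PC1 scores along the first principal axis from the centroid. Batch
iteration assigns each subject to the nearest codebook (Euclidean, scaled
space) and re-estimates each codebook as the neighborhood-weighted mean,
with a Gaussian kernel over grid distance whose width decays linearly from
1.0 to 0 across the first half of the iteration budget (default 200).
After the width reaches zero the update is exactly Lloyd's k-means, and
with width 0 throughout the fit *is* k-means from the PCA init — the
equivalence the tests exploit. Convergence: unchanged assignments in the
zero-width regime. Empty nodes keep their codebook for the iteration.
The kernel shape and schedule stand in for a proprietary locally-weighted
smoother in the original software; they reproduce standard batch-SOM
behavior and the same cluster-mean fixed point, but numeric equality with
that implementation is not a goal — property-level equivalence is.

The middle node (by mean scaled codebook value) is the normal cluster.
SOMs are fitted within each reporting stratum's age/sex band (the urea
stratum spans all ages). Fitting is deterministic given the data — PCA
initialization removes run-to-run randomness.

## Reference intervals and bias

Limits use the rank rule `r = p(n+1)` with linear interpolation between
order statistics, clamped to `[1, n]` (the CLSI-style nonparametric
convention). 90% CIs per limit come from the distribution-free binomial
method: the narrowest symmetric-in-rank order-statistic pair whose coverage
reaches 0.90; when the ranks run off either end (small n at extreme
percentiles) a seeded 2,000-resample percentile bootstrap substitutes.
n < 20 is an error, n < 120 warns. Summaries report the n−1 SD,
bias-corrected skewness and bias-corrected excess kurtosis — conventions
chosen so near-normal data report near-zero shape values.

The bias ratio divides the per-limit difference (indirect − direct) by the
between-individual SD `sd_b = (direct UL − direct LL)/3.92`, i.e. the
direct RI width re-expressed as a normal SD; |ratio| ≤ 0.25 is allowable,
≤ 0.375 minimal, larger unacceptable. Report rounding: creatinine 1 dp,
urea 2 dp, ratios 2 dp.

## Synthetic generator

Per age/sex band the generator defines healthy, pathological-low and
pathological-high components for each analyte. Healthy marginals are
inverse Box-Cox transforms of normals: location/scale on the transformed
scale are set by the delta method so the raw mean/SD stay close to nominal
while a controlled right-skew appears (and λ remains recoverable by the
cleaning module). Healthy triples share a Gaussian copula (creatinine–urea
and creatinine–uric-acid correlation 0.4, urea–uric-acid 0.3); pathological
components are independent normals truncated positive, and a subject's
component label applies to the whole panel. Repeat visits (rate 0.3) add a
later record per analyte redrawn around the first with SD 0.3 × healthy SD;
a small fraction (0.5%) of LIS records get far-out-of-bounds values to
exercise the plausibility filter. Ages are uniform within band; direct
records are emitted on the direct platform's scale (inverse transference),
so the pipeline's transference step recovers the nominal distribution.

The default study spec anchors healthy creatinine at 28.9/5.6, 40.6/5.6,
60.8/12.7 (boys) and 52.2/8.3 (girls) μmol/L across the four bands and
urea at 4.33/0.99 mmol/L, with λ = 0.9/0.7/0.5/0.9 (creatinine) and 0.4
(urea) giving the published-style positive skewness, strongest for
adolescent boys. Uric acid parameters (200–310 μmol/L by band, SD 55–70)
are invented defaults — no published anchor exists. Mixing weights are
20/60/20. Pathological components sit at mean + 6·SD (high, same SD) and
`max(mean − 6·SD, 0.25·mean)` (low, SD halved): a literal −6·SD low
component would be negative for creatinine in young children and for urea,
so the low side is floored at a quarter of the healthy mean — separations
are then 3.3–6 healthy SDs depending on the analyte and band.

What the generator does *not* emulate: real pre-analytical confounders
(fasting, medication, specimen handling), demographic composition,
seasonal effects, analyte-specific pathology patterns (a "high" subject is
high in all three analytes), or residual between-platform nonlinearity.
Passing recovery tests therefore show the algorithms are correct under the
assumed mixture structure, not that indirect RIs are unbiased on real LIS
data — on real data the direct-vs-indirect deviations are the object of
study, not an error to eliminate.

## Default problem sizes

The study emulation defaults to 5,000 subjects per stratum per population
(20,000 LIS subjects overall), which keeps every stage's sampling error
well below the tolerances of interest while a full run completes in well
under a minute; component recovery and estimator-calibration checks use
2,000–100,000 draws as appropriate to the quantity being verified.

## Known limitations

- The GMM is univariate and K is fixed at 3; model-order selection and
  multivariate mixtures are out of scope.
- Only the 3×1 SOM grid is supported; the cubic clustering criterion is not
  implemented (a within/between variance ratio is logged instead).
- Transference maps are inputs (published chains); estimating new maps from
  paired measurements (Deming, Passing–Bablok) is out of scope.
- The LIS extraction window and platform metadata are provenance only; no
  unit auto-conversion or terminology (LOINC) handling.
- The SOM healthy fraction depends on panel completeness: subjects missing
  any of the three analytes are excluded from SOM (but not from the
  per-analyte GMM), which is one structural reason the SOM selector is
  stricter.
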