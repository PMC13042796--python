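# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the limits of what the test suite demonstrates.

## Estimation chain

The package estimates the incident disease burden attributable to
early maturation (early puberty timing) by a comparative-risk-
assessment chain: pooled relative risks → causal gate → pooled exposure
prevalence → Levin PAFs → attributable cases with draw-level
uncertainty → age-standardized rates.

### Relative-risk pooling

Study effects (OR, RR, HR) are pooled per disease on the log scale by
inverse-variance weighting. OR/RR/HR are treated as interchangeable
ratio measures: the source literatures report them jointly for rare
and common outcomes alike and no conversion is attempted. When only a
95% CI is reported, the SE is recovered as
(log hi − log lo)/(2·1.959964); the z-value 1.959964 is fixed
package-wide.

Heterogeneity drives the model choice: with Cochran's Q over fixed
weights and I² = max(0, 100·(Q − (k−1))/Q), the pool is fixed-effect
when I² < 50% (strict) and DerSimonian–Laird random-effects otherwise.
DL uses the method-of-moments τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw))
and re-weights by 1/(se² + τ²). A single study is pooled "fixed" by
convention (τ² undefined). The DL implementation is cross-checked in
the test suite against R's `metafor` (`method="DL"`) on a fixed
fixture.

### Mendelian-randomization gate

Two-sample MR with LD-independent SNP instruments for puberty timing.
Effects are expressed as an odds ratio per 1-year *increase* (delay)
in puberty timing throughout; OR < 1 therefore means early maturation
raises risk. Estimators:

- **Wald ratio** per variant: β_out/β_exp, SE = se_out/|β_exp|
  (first-order delta method, no-measurement-error assumption on the
  exposure side).
- **IVW** (primary): inverse-variance weighting of the Wald ratios
  with w_j = β_exp,j²/se_out,j², equivalent to zero-intercept WLS of
  β_out on β_exp; fixed-effect SE; Cochran's Q over ratios reported.
- **MR-Egger** and **weighted median** as the field-standard
  sensitivity pair (the Egger intercept tests directional pleiotropy;
  the weighted median tolerates up to 50% invalid weight). Egger uses
  multiplicative random-effects scaling floored at 1; the weighted
  median SE comes from a parametric bootstrap of the summary
  statistics. Both are advisory and never drive the gate.

The gate admits a disease when the forward IVW estimate has p < 0.05
and OR < 1. The reverse direction is estimated and logged but does not
veto: a reverse-causation signal is a flag for interpretation, not a
defined exclusion rule. Instrument filtering at p < 5×10⁻⁸ is
available but not applied to the synthetic instruments, which are
strong by construction. Harmonization of real GWAS files (allele
alignment, palindromic SNPs, clumping, Steiger filtering) is out of
scope.

### Prevalence pooling

Three tiers produce the region- and sex-specific exposure prevalence
Pe:

1. **Within country**: inverse-variance pooling over surveys with
   binomial SE √(p(1−p)/n). Surveys at p = 0 or 1 get an
   Agresti-Coull-style +2/+4 shift for the SE only, keeping their
   weight finite without moving the estimate.
2. **Geographical**: region Pe is the weighted average of country
   prevalences with weight = survey sample size × the country's
   disease case count. The pipeline uses all-cause case counts (the
   weight's case-count component is not obviously disease-specific;
   a per-disease variant only changes the weights, not the operator).
3. **Risk-based**: for survey-free regions, OLS of known-region Pe on
   the region's all-cause incidence rate, evaluated at the target
   region's rate and truncated to [0, 1] with a logged warning. The
   regression needs ≥ 2 known regions and non-constant incidence.

Prevalence is treated as constant over the exposure window
(1960s–2000s); a 20-year exposure lag is carried as metadata tagging
which historical window feeds which outcome year. The early-maturation
definition thresholds are survey metadata, not recomputed.

### Attribution and standardization

Levin's formula PAF = Pe(RR−1)/(Pe(RR−1)+1) is applied per (disease,
sex, region). RR < 1 strata are refused rather than given negative
PAFs: the attributable-fraction framework here is for harmful
exposures, and the gate should have removed protective associations —
if a gated disease's *pooled* RR still falls below 1 (possible by
sampling in small literatures), it leaves the burden calculation with
a logged warning. PAFs are uniform across age within (disease, sex,
region): age variation enters through incidence, since no age-varying
prevalence is available; a config path accepts age-specific Pe if
supplied.

Attributable cases = incidence × PAF, per draw. Aggregation is always
draw-wise (sum within draw index k, summarize last). ASIR is direct
standardization: Σ_a w_a (cases_a/pop_a) × 100,000, with the WHO World
Standard weights (the 2000–2025 table) renormalized over ages ≥ 20.
ASIR denominators use the population the stratum refers to: a
sex-specific ASIR is rated against that sex's person-years, a
disease-level total against the whole adult population (so a
male-only cancer's both-sex ASIR is half its male ASIR).

Reporting age bands are 20–49, 50–69, 70+ collapsed from the 5-year
bands; the boundary at 50 is assigned to the older band's start
(20–49/50–69). Development status follows the WESP dichotomy (Europe,
North America, Australia, New Zealand, Japan = more developed). All
internal math is unrounded; tables round to one decimal only when
written.

### Uncertainty

Quantities are carried as ordered vectors of Monte-Carlo draws; draw
index k is a coherent scenario across strata, so draw-wise sums are
valid before percentiles. The 95% UI is the 2.5th–97.5th percentile by
linear interpolation between closest ranks; the point estimate is the
draw mean. Default n_draws = 1000, configurable down to 100 for fast
tests. UIs carry incidence-draw uncertainty only, matching the way
such burden UIs are usually sourced; sampling RR draws (normal on the
log scale) and Pe draws (normal on the logit scale) is implemented and
off by default.

## Synthetic study conditions

The generator emulates the statistical shape of the four real inputs,
not their magnitudes (no real GBD levels, allele frequencies, or LD).
Defaults, chosen once as plausible for this exposure:

- **World**: 7 World Bank regions × 3 countries × 2 sexes × 14
  five-year age bands (20–24 … 85+); person-years decline linearly
  with age band. Countries in North America and Europe/Central Asia
  are classed more-developed (region-level proxy for the WESP country
  list, since synthetic countries are not real ones).
- **Diseases**: asthma, Type 2 diabetes, ischemic heart disease,
  stroke, testicular cancer (male only), uterine cancer (female only),
  depression. True RRs 1.06–1.55, giving PAFs of roughly 0.5–8% at the
  simulated prevalences — the range such analyses report. Incidence
  follows per-disease geometric age gradients (cardiovascular disease
  rising steeply with age, depression and testicular cancer
  concentrated at younger ages) with a mild female excess for asthma
  and depression.
- **True causal slopes** (log-OR per 1-year delay): −0.054 to −0.207,
  i.e., per-year risk reductions of ~5–19% — the magnitude range MR
  studies of puberty timing report.
- **Effect literature**: 10 studies per disease, between-study SD
  (τ) 0.1, per-study SEs uniform on (0.05, 0.25), CIs exact functions
  of the SEs.
- **Instruments**: 30 variants, exposure effects ~N(0.1, 0.03) years
  per allele with SE 0.005, outcome SE 0.005 — strong instruments, so
  the gate decision reflects the true slopes rather than power.
- **Surveys**: 2 surveys per (country, sex), n = 5000, binomial
  sampling around true prevalence drawn once from U(0.05, 0.25);
  male prevalence scaled by 0.75, reflecting the historically higher
  prevalence of early maturation among females. Sub-Saharan Africa is
  generated survey-free to exercise the risk-based pooling path.
- **Incidence draws**: log-normal, median-centered on each cell's
  estimate, with two log-scale components: cell-level SD 0.1
  (independent across strata) and per-disease SD 0.08 shared across
  all strata within a draw. The shared component represents common
  modeling uncertainty; without it, aggregate UIs would shrink toward
  zero as independent cell noise averages out. The estimate itself is
  log-normal around the truth with the same dispersion, which makes
  the 95% UI an approximately calibrated interval for the truth at
  any aggregation level — verified by coverage simulation in the
  acceptance tests.

A single seed is threaded to all generators through fixed per-table
substreams, so an identical config reproduces byte-identical tables.

## What passing tests do and do not show

Parameter recovery, interval coverage, and determinism on this
synthetic world validate the estimators and the draw machinery. They
do not validate performance on real data: the generator has no
publication bias, no between-region RR heterogeneity, no LD or allele
mismatches, no survey-definition drift, and independent draw noise
between diseases. Published per-disease PAFs and ASIRs for this
exposure depend on country-level prevalence tables and proprietary
GWAS/GBD inputs that are not redistributable, so they are checked here
only through the aggregation identities of the published tables (the
printed marginals are reproduced exactly by the aggregation operator)
and through the property suites, not as numeric targets.

Problem sizes in the test suite (replicate counts of 200–500,
n_draws of 50–500 in simulation-heavy checks) are chosen to keep the
full suite under a minute while leaving Monte-Carlo error well inside
the asserted tolerance bands.

## Known limitations

- OR/HR/RR equivalence ignores the rare-disease assumption; with
  common outcomes pooled ORs overstate RRs.
- The Levin formula with a single pooled RR assumes no confounding of
  the exposure-disease association and a uniform RR worldwide.
- Risk-based prevalence imputation leans on a cross-region
  prevalence–incidence relationship estimated from few points; its
  prediction SE is reported but not propagated into PAFs by default.
- The bootstrap SE of the weighted median is seed-dependent at small
  bootstrap counts.
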