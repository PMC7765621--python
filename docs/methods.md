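# Methods

## Data model and cleaning

A case report is keyed by an opaque case id and split over DRUG, REAC and
DEMO tables. The analysis table keeps one row per case id present in DEMO,
with the suspected drugs and reported preferred terms aggregated into
sets: a case counts once for a drug or an event no matter how many rows
mention it. Only drugs labelled *suspected* enter the analysis —
concomitant and interaction rows are discarded before deduplication.

Deduplication collapses exact duplicate tuples and, within a case,
repeated drug names or preferred terms, keeping the first occurrence. This
is deliberately conservative (no fuzzy matching of name variants), stable
in order, and idempotent; it is the contract the synthetic generator's
duplicate injection is written against.

Demographic recoding reflects how these databases band open-ended fields:
weights reported as "over 60 kg" are set to 65 kg and "under 10 kg" to
5 kg; decade age bands ("70s") map to their midpoint (75); exact-year
strings pass through. BMI = weight/(height/100)² is computed where both
fields are present, and cases with computable BMI < 5 or ≥ 100 are removed
as physically impossible. Cases with *missing* BMI are kept: each
downstream analysis handles missingness on its own terms (complete-case
per variable or per model), so cleaning removes only demonstrable errors
rather than discarding the majority of records that simply lack height or
weight.

## Disproportionality statistics

For drug D and event term set E, the 2×2 table (a, b, c, d) counts
reports with D and E, D only, E only, and neither. The reporting odds
ratio is computed on half-corrected cells (0.5 added to all four,
unconditionally), with the Wald interval
exp(ln ROR ± 1.96·√(Σ 1/cell′)). The half correction is applied even when
no cell is zero — the estimator is then a single continuous function of
the table, and its small-sample bias is well understood.

The significance criterion uses the two-sided Fisher exact test on the
*raw integer* cells (exact tests are defined on integers; the correction
applies only to the estimate). Two-sided p sums the hypergeometric
probabilities of all tables, at fixed margins, whose point probability
does not exceed the observed table's — the convention implemented by
`scipy.stats.fisher_exact`, which the test suite cross-checks against an
independent exhaustive enumeration. A drug is flagged as a signal when
ROR ≥ 1 **and** p < 0.05; the Wald CI is reported but plays no role in
flagging, and near the boundary the two can disagree (the suite pins one
such constructed table). No multiplicity adjustment is applied across
drugs — the screen is a hypothesis-generating filter, and its empirical
null behaviour (roughly α/2 of null drugs flagged, since the ROR ≥ 1 side
halves the rejection region) is measured by simulation rather than
assumed.

Volcano coordinates are x = ln ROR and y = −log₁₀ p, with p floored at
1e-300 before the logarithm so underflowing p-values keep finite
coordinates; the y = −log₁₀ 0.05 reference is exported with the table.

## Patient-background comparison

Continuous variables are compared between event and non-event reports
with the Wilcoxon rank-sum test: mid-ranks for ties, tie-corrected
variance, normal approximation with a 0.5 continuity correction applied
toward the null (so identical samples give exactly p = 1). For combined
n ≤ 20 the null distribution of the rank sum is enumerated exactly over
all group assignments, doubling the smaller tail; the two paths agree
within about 0.01 at the switch point. The two groups are independent
(split by event status), which is why an unpaired rank test — not a
paired signed-rank test — is the appropriate choice. Sex uses Fisher's
exact test. Every variable is analysed on its complete cases, so each
row of the summary reports its own n.

## Logistic risk model

Event presence is regressed on drug-exposure indicators plus female
(1/0), age (years), height (cm) and weight (kg) by plain maximum
likelihood (Newton iterations via statsmodels; no penalisation). Cases
missing any used covariate are dropped and counted. A predictor constant
on the complete cases, or a constant outcome, is a hard error naming the
term; suspected separation (failed Newton step) triggers a damped refit,
a `SeparationWarning`, and `converged_ = False` rather than a silent
answer. Unit odds ratios are exp(β) with Wald intervals; for continuous
covariates the range odds ratio exp(β·(max−min)) expresses the effect
over the covariate's observed span (interval endpoints transformed
identically and reported low-to-high). Model fit is McFadden's
pseudo-R² = 1 − logL/logL₀. With a single binary predictor the MLE
equals the log odds ratio of the outcome × predictor table, which the
suite asserts to 1e-8.

## Event profiling

Drugs are observations and event terms variables. Events reported in
fewer than `min_reports` cases (default 20) are dropped; each remaining
cell is ln of the half-corrected ROR, hence always finite. PCA is run on
the correlation matrix: columns standardised (SD with n−1), eigenvalues
λₖ of the correlation matrix give contribution ratios 100·λₖ/p summing
to 100 over the min(n_drugs−1, n_events) retained components, and
loadings are reported as variable–component correlations (eigenvector ×
√λ), so each event's squared loadings sum to 1. Eigenvector signs are
arbitrary; each component is oriented so its largest-|loading| entry is
positive. This fixes plots and exported coordinates; the subsequent
clustering is mathematically invariant to whole-column sign flips (a
reflection is an isometry), which the suite verifies.

Events are clustered by Ward's minimum-variance criterion on Euclidean
distances between their loadings on the first three components
(scipy's `linkage(..., method="ward")`, the Ward.D2-style update on raw
Euclidean input), and the dendrogram is cut at k = 2 by the maxclust
rule. Duplicate loading rows merge at height 0 and merge heights are
non-decreasing. The dendrogram is exported both as a merge table and as
Newick text.

## Synthetic report generator

The generator emulates the statistical structure of a spontaneous
reporting database, not its surface noise. Per case: sex ~ Bernoulli
(female 0.49); age ~ normal(60, 21) truncated to [0, 100]; height and
weight bivariate normal by sex (females 154 ± 7 cm, 52 ± 10 kg; males
167 ± 7 cm, 64 ± 11 kg; correlation 0.5) — values near the demographic
profile of an elderly-skewed reporting population. Drug exposures are
independent Bernoulli draws with configured marginals (optionally
Gaussian-copula correlated to emulate co-prescription). Each event is
drawn with probability logistic(baseline + Σ exposure·β(drug,event) +
female·b_F + (age−60)·b_A + (height−160)·b_H); centring age and height
keeps the baseline interpretable as roughly the marginal event logit.
Field-level missingness blanks DEMO cells (defaults 3% sex, 7% age, 55%
height, 48% weight — height/weight are the sparsely completed fields in
real extracts); weights above 60 kg and below 10 kg are emitted as the
open bands the recoding rule expects; a configurable fraction of
DRUG/REAC rows is duplicated as exact copies; an optional concomitant-row
rate adds non-suspected rows that the cleaning stage must discard.
Everything derives from one `numpy` Generator seed: identical configs
give byte-identical files.

Ages are emitted as exact integer-year strings by default. Decade-band
emission is available (`age_as_band=True`) and the band→midpoint recoding
is unit-tested, but exact years are the default because banding
introduces a small attenuation in covariate-recovery checks that is a
property of the banding, not of the estimators under test.

The default study configuration plants two latent mechanisms over the 13
osteonecrosis-query terms: antiresorptive drugs load jaw osteonecrosis
(log-OR ln 20), atypical femoral fracture (ln 12) and
osteomyelitis/osteonecrosis (ln 6), comparator drugs load the
infection/pain block (ln 6) plus a mild confounded jaw-osteonecrosis risk
(ln 1.5); demographic effects are female ln 1.3, age ln 1.02 per year,
height ln 0.99 per cm. Event baselines are 0.3% for jaw osteonecrosis and
0.08–0.1% for the rest, mirroring the skewed frequency profile of the
real query.

What the generator does *not* emulate: free-text drug-name variants,
Japanese-language fields, reporting-date structure, dose/duration, or
informative missingness. Passing recovery tests therefore demonstrates
estimator correctness under the designed mechanism, not robustness to
real-world coding noise.

## Problem sizes and numerical choices

Recovery checks run at the scale each estimate needs: single planted
ROR 20 at 200,000 cases (exposure 5%, baseline event rate 1%); CI
coverage at OR 5 over 1,000 replicate 2×2 draws of 20,000 reports each;
multivariate logistic recovery at 100,000 cases with acceptance at 3
standard errors; the full-pipeline determinism and smoke runs at
8,000–20,000 cases with the rare-event report filter lowered
accordingly (the ≥20-report rule assumes database scale). Fisher
enumeration is cross-checked on 500 random tables with N ≤ 200.
Convergence tolerance for the logistic Newton iterations is 1e-8 on the
score; p-values are floored at 1e-300 before −log₁₀; output ordering of
the signal table (reports desc, ROR desc, name asc) is fixed for
reproducibility.

## Known limitations

- The deduplication strategy is exact-match only; real extracts need
  name normalisation upstream.
- Wald intervals for the ROR undercover slightly for very sparse cells
  (the half correction trades bias for finiteness); the coverage check
  quantifies this at moderate cell sizes.
- The Ward/standardisation dialect of other statistical packages may
  order merges differently for near-ties; the exported merge table, not
  plot appearance, is the contract.
- Range odds ratios depend on the observed min/max and are therefore
  sample-dependent summaries, not model parameters.
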