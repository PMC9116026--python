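# Methods

## Data model

A cohort is a pair of tables. The **variant catalog** holds one row per
variant: gene, consequence (`missense` or `PTV`), allele frequency, up to
five in silico scores (CADD, Helix, BayesDel, REVEL, Align-GVGD), a
protein-domain label, a splice-disruption exclusion flag, and optional
functional (SGE, HDR) and ClinVar classes. The **subject table** holds one
row per person: country/ethnicity stratum, case-control status, age, study
design (`population` or `familial`), and the carried variant ids. Variant
ids are opaque strings; no coordinate arithmetic is performed anywhere.

Eligibility for the missense analyses is: consequence `missense`, allele
frequency strictly below 0.1% (the comparison is strict, matching the
definition "< 0.1%"), and not splice-flagged. Carriers of PTVs in a gene
under analysis are excluded from all of that gene's analyses *except* the
mixture fits, where they are re-included so the missense OR can be tied to
the PTV OR.

## Risk-category schemes

A scheme is an ordered list of (label, predicate) pairs over variant
records, expressed in a small declarative language (domain membership,
score cuts, class membership, disjunction) and serialisable to YAML. The
predicates must partition the eligible set: a variant matching zero or two
categories raises an error rather than being silently dropped. Built-in
schemes cover the five genes' published category definitions, the layered
BRCA1 scheme with saturation-genome-editing classes prioritised over Helix,
and the layered BRCA2 scheme with homology-directed-repair classes
prioritised.

Numerical conventions: a Helix score of exactly 0.5 is classed "low" (the
published definition leaves 0.5 unassigned; low is conservative). CADD
quintiles are computed over the unique eligible variants of the gene with
type-7 (linear-interpolation) empirical quantiles; the published ATM
quintile-5 boundary 3.736542 ships as a fixed parameter so results can be
reproduced without recomputing quantiles. Frequency bins for the burden-by-
frequency analysis are [0, 0.1%), [0.1%, 0.5%), [0.5%, 1%), [1%, 5%].

## Logistic layer

All association fits are maximum-likelihood binomial GLMs (IRLS via
statsmodels) with dummy-coded strata; the reference stratum is the largest.
Confidence intervals and p-values are Wald (the log-likelihood is exposed
for likelihood-ratio comparisons). Fractional frequency weights and fixed
offsets are supported because the EM M-step and the frozen-parameter
validation refits need them. Rank-deficient designs raise an error rather
than silently dropping a column. Separation is detected (via IRLS perfect-
prediction warnings and diverging indicator coefficients) and raised as an
error; no penalisation is applied, since the reported ORs are unpenalised.
Convergence: relative parameter tolerance 1e-10, at most 100 iterations.

## The mixture model

For gene *g* with categories *c*, each variant *v* is latently
risk-associated, z_v ~ Bernoulli(alpha_c(v)). Carriers of a risk-associated
variant have their disease log-odds shifted by beta_mis; PTV carriers by
beta_ptv. Modes: **constrained** (beta_mis = beta_ptv), **unconstrained**
(free beta_mis, separate beta_ptv), **two_level** (a high state tied to
beta_ptv and a moderate state with its own coefficient, with two alpha
vectors). The observed-data log-likelihood is

    sum_noncarriers Bernoulli(eta_i) + sum_PTV Bernoulli(eta_i + beta_ptv)
    + sum_v log( alpha_c L1_v + (1 - alpha_c) L0_v ),

where L1_v / L0_v multiply the Bernoulli terms of v's carriers with and
without the risk shift (non-carrier terms cancel from the ratio and are
kept once in the first sum).

EM details:

* **E-step**: p_v = alpha L1 / (alpha L1 + (1 - alpha) L0), computed in log
  space; a variant with no carriers has L1 = L0 = 1 and posterior alpha.
* **M-step**: each missense carrier becomes one pseudo-observation per risk
  state (weight = that state's posterior, carrying the state's exposure
  indicator) plus a benign pseudo-observation (weight = benign posterior,
  no exposure); PTV carriers enter at weight one. All coefficients are then
  refit by weighted logistic regression. Because the weighted fit depends on
  carriers only through (stratum, outcome) totals per state, the
  pseudo-observations are aggregated into those cells before fitting — an
  exact collapse that keeps the per-iteration cost independent of cohort
  size.
* **alpha update**: the unweighted mean posterior over the *unique variants*
  of each category — alpha is a proportion of variants, not of carriers.
* **Convergence**: absolute log-likelihood change below 1e-6 (default), at
  most 500 iterations by default; a non-converged fit is returned flagged,
  not raised. EM convergence near a flat alpha direction can take several
  hundred iterations at training scale, so the recovery and calibration
  studies pass `max_iter=2000`.
* **Initialisation**: alpha = 0.1 per category (0.05/0.1 for the two-level
  states), beta_mis = log 1.5, beta_ptv from a PTV-only logistic fit
  (clipped to ±5; a smoothed crude estimate backs it up on degenerate tiny
  data), nuisance from a non-carrier fit. `fit(n_starts=3)` (the default)
  adds jittered restarts and keeps the best log-likelihood; the large
  simulation studies in the test suite use a single start, which was always
  sufficient at that scale.

Subjects carrying two or more eligible missense variants of the gene are
excluded from the mixture fit with a logged count — the variant-level
likelihood factorisation assumes one eligible variant per carrier. Subjects
with both a PTV and a missense variant in the gene enter as PTV carriers
only.

Reported uncertainty: the OR interval comes from the final weighted M-step
fit (it conditions on the posteriors, so it slightly understates the full
uncertainty); alpha intervals use the **profile likelihood** — alpha_c fixed
on a bisection path, all other parameters re-maximised by EM, interval =
{alpha : 2 [l_max − l(alpha)] ≤ χ²₁(0.95)}, clipped to [0, 1], with a flat
profile reported as the full interval plus a warning. A percentile
bootstrap over variants (resampled with replacement within category,
`alpha_bootstrap_ci`, default B = 200) is available as a slower independent
cross-check.

Because risk-associated variants are over-represented among observed
(case-enriched) variants, the naive alpha is biased upward; the
**control-only alpha** averages posteriors over variants with at least one
control carrier (at-least-one is the adopted reading) and is the headline
estimate.

## Validation with frozen parameters

On a held-out cohort the category effects are entered as fixed offsets and
only the intercept and stratum coefficients are re-estimated. For mixture
models the carrier odds multiplier is alpha_val · exp(beta) + (1 −
alpha_val) — exact for a two-component mixture of carrier odds ratios —
with alpha transported to the validation case/control mix as the weighted
average of the posterior-weighted case-carrier and control-carrier
pathogenic fractions from training. Expected case (control) counts per
category sum the refit model's predicted probabilities (complements); the
intercept score equation makes expected and observed totals agree exactly.
The goodness-of-fit χ² runs over category × outcome cells with df =
(#categories − 1) by default (exposed as a parameter; the empirical mean χ²
under a true frozen model at the scales tested is ≈ 2.7 for three
categories, between the k − 1 and k conventions). Predicted per-category
ORs from training posteriors use the same linear-odds mixing per variant,
averaged over validation carriers, with carriers of variants unseen in
training dropped. The composite model fits all genes' category indicators
jointly against carriers-of-nothing, excluding (and counting) subjects with
eligible missense variants in more than one gene.

## Synthetic cohorts

The generator exists so that every stage is testable with known truth. Per
category it draws `n_variants` variants with log-uniform allele frequencies
(default bounds 2e-6 to 1e-4, giving published-scale carrier counts),
scores/domains sampled inside the category's defining template, and latent
pathogenicity Bernoulli(alpha). PTVs are represented as a single aggregated
record per gene, since the analyses use only gene-level PTV carrier status.

Subjects are simulated **prospectively** — carrier probability 2f per
variant (rare-heterozygote approximation, homozygotes ignored; at most one
eligible missense per gene per subject by construction), disease status
from the logistic model with stratum baselines around −2.2 log-odds
(≈ 10% disease probability, a lifetime-risk scale) — and then sampled
**retrospectively** to the target case/control counts, cases with an
inclusion-weight multiplier in familial-design strata. This two-stage
design makes the logistic model literally true, reproduces the
ascertainment effects the mixture model corrects for (pathogenic variants
are both more likely to be observed at all and more case-enriched once
observed), and is why the control-only alpha is close to unbiased for the
generating alpha in the recovery studies. The default configuration mirrors
the published five-gene training results: category sizes (e.g. 714/171/103
for ATM), alpha values (e.g. 0.54 for the top ATM category), mixture ORs
(2.16/10.61/5.87/1.75/4.87), PTV carrier frequencies derived from the
published carrier-frequency ratios, 35,000 cases and 38,000 controls drawn
from a 400,000-subject pool across five strata (one familial,
oversampling ×2). The CHEK2 block uses a PTV OR of 2.54 so the
missense-vs-PTV contrast the unconstrained model detects is present in
simulation. Ages are drawn independently of risk category, so age-trend
analyses are null in generated cohorts; sequencing error, linkage
disequilibrium and pedigree structure are not modelled. Passing tests on
these cohorts therefore demonstrate correctness of the estimators under
the model's own assumptions, not robustness to real-data artefacts.

## Problem sizes in the test suite

Parameter-recovery studies run 25 simulated cohorts per gene at the full
published training scale; EM-property sweeps use 50 reduced cohorts (~3,000
subjects); calibration-under-truth uses one 42,000-subject training cohort
and twenty 10,000-subject validation cohorts; the brute-force mixture
oracle uses ≤ 6-subject micro datasets where a dense (alpha, beta,
intercept) grid is exhaustive. The whole suite completes in a few minutes
on one core.

## Known limitations

* Mixture OR intervals condition on the fitted posteriors (no propagation
  of alpha uncertainty into the Wald interval); use the profile or
  likelihood-ratio machinery where that matters.
* The familial relative-risk formula is a rare-variant approximation: its
  monotonicity in p and r, and the additive cross-gene aggregation, are
  meaningful only at small allele frequencies (the implementation accepts
  p up to 0.5 but the properties are asserted only for p ≤ 0.01).
* The two-level mixture is fitted like the others but is weakly identified
  when the moderate-risk state is close to either neighbour; expect flat
  profiles.
* Familial ascertainment is modelled as a single case-inclusion multiplier,
  standing in for genuinely pedigree-based sampling; only the direction of
  the induced alpha bias is asserted in tests, not its magnitude.
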