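# missensemix

Statistical models for estimating disease risks of **rare missense variants**
in susceptibility genes from large case-control sequencing studies, built for
the setting of breast cancer gene-panel data (*ATM*, *BRCA1*, *BRCA2*,
*CHEK2*, *PALB2*): most missense variants are individually too rare to
analyse, so evidence is pooled across variants grouped by protein domain,
in silico deleteriousness scores (CADD, Helix, BayesDel, REVEL, Align-GVGD)
and functional-assay classes.

The package is aimed at statistical geneticists and genetic epidemiologists
who need to (a) estimate category-level odds ratios, (b) estimate what
*fraction* of a category's variants actually carries risk, and (c) check
those models on held-out data — all without access to the original
controlled-access cohort, via a synthetic cohort generator with known ground
truth.

## The models

**Burden model.** For subject *i* with case status *y<sub>i</sub>*, country
stratum *s(i)* and risk-category carrier indicators *x<sub>ic</sub>*,

> logit P(y<sub>i</sub> = 1) = μ + γ<sub>s(i)</sub> + Σ<sub>c</sub> β<sub>c</sub> x<sub>ic</sub>,

fitted by maximum likelihood (`GroupBurdenModel`), giving one OR =
exp(β<sub>c</sub>) per category versus non-carriers.

**Mixture model** (`MissenseMixtureModel`) — the core. Each variant *v* in
category *c* is latently risk-associated with probability α<sub>c</sub>;
risk-associated variants share a single carrier log-OR β (optionally
constrained to the protein-truncating-variant log-OR, or split into two risk
levels). Fitting is by EM: the E-step computes each variant's posterior
probability of being risk-associated from its carriers' case-control data,

> p<sub>v</sub> = α<sub>c</sub> L<sub>1v</sub> / (α<sub>c</sub> L<sub>1v</sub> + (1 − α<sub>c</sub>) L<sub>0v</sub>),

and the M-step refits a weighted logistic regression with carriers expanded
into posterior-weighted pseudo-observations, updating α<sub>c</sub> as the
mean posterior over the category's variants. Because case-enriched sampling
inflates the naive α, a **control-only α** (mean posterior over variants seen
in at least one control) is reported alongside. Profile-likelihood intervals
for α, frozen-parameter validation on held-out cohorts (observed-vs-expected
counts with a goodness-of-fit χ²), posterior-probability-weighted predicted
ORs, a cross-gene composite model, and the familial relative-risk
decomposition λ<sub>j</sub> = (p r² + q (p r + q)²)/(2 p r + 1 − 2 p)² round
out the workflow.

## Worked example

Simulate a training-scale ATM cohort (73,000 subjects, 988 rare missense
variants, 54% of the top-category variants truly risk-associated with OR
2.16), group variants by domain and CADD quintile, and fit both models:

```python
import missensemix as mm

config = mm.default_config().subset(["ATM"])
cohort, truth = mm.simulate(config, seed=1)
assignment = mm.assign_groups(cohort.variants, mm.builtin_scheme("ATM"))

lr_cohort = mm.filter_subjects(cohort, drop_ptv_carriers_in=["ATM"])
print(mm.GroupBurdenModel(lr_cohort, assignment).fit().summary())

spec = mm.MixtureSpec("ATM", mode="constrained", max_iter=2000)
print(mm.MissenseMixtureModel(cohort, assignment, spec=spec).fit(n_starts=1).summary())
```

```
group burden for ATM: n=72692, loglik=-50254.28, multi-missense subjects dropped=0
category                   variants   cases controls      OR            95% CI          p
outside_FAT_PIK                 714    1201     1325    0.99       (0.92–1.07)       0.83
FAT_PIK_CADD1-4                 171     376      351    1.17       (1.01–1.36)      0.032
FAT_PIK_CADD5                   103     301      191    1.72       (1.43–2.06)   5.43e-09

mixture fit (constrained) for ATM: n=73000, loglik=-50447.1032, iterations=723, converged=True, multi-missense excluded=0
missense OR 2.342, PTV OR 2.342
  risk: OR 2.342 (2.008–2.731)
alpha (naive / control-only):
  outside_FAT_PIK: 0.0000 / 0.0000
  FAT_PIK_CADD1-4: 0.1753 / 0.1415
  FAT_PIK_CADD5: 0.6088 / 0.5787
```

Reading the output: only the top category (inside the FAT/PIK domains with a
top-quintile CADD score) shows a clear burden signal (OR 1.72); the mixture
model attributes it to roughly 58% of that category's variants carrying a
PTV-level risk (OR 2.34) — close to this simulation's generating values
(α = 0.54, OR = 2.16), with the remaining gap being one seed's Monte-Carlo
error. The control-only α sits below the naive α, as expected under case
enrichment.

The same workflow runs from the shell: `missensemix simulate`, `group`,
`fit-lr`, `fit-mixture`, `validate`, `frr`, or `run-all` for the whole
pipeline from one YAML configuration.

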