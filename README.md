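# immunesig

Immune-signature analysis of neoadjuvant chemotherapy (NAC) response in
breast cancer.

Only 30–50% of patients reach a pathological complete response (pCR) after
NAC, and immune activation in the tumor microenvironment is one of the
strongest known correlates of chemosensitivity. This package implements, as
a tested and reusable pipeline, the analysis built around a 19-gene
(23-probe) immune-related expression signature scored by diagonal linear
discriminant analysis (DLDA): cross-platform preprocessing, immune scoring
and responder classification, intrinsic-subtype assignment and joint
immune subtypes, contingency/pooled/meta response statistics, ROC
comparison, and post-NAC survival stratification. A synthetic cohort
generator carries the statistical structure the analysis assumes, so every
stage is testable without any external download.

It is written for computational biologists and biostatisticians evaluating
expression-based chemosensitivity predictors on microarray or RNA-seq
cohorts shaped like GEO series matrices.

## The model

The immune score (IS) of a sample *x* is a diagonal linear discriminant
over the signature genes:

    IS(x) = Σ_j w_j (x_j − m_j),    w_j = (μ̂1j − μ̂0j) / s_j²,
                                     m_j = (μ̂1j + μ̂0j) / 2,

where μ̂1j, μ̂0j are the per-gene means of the responder / non-responder
training classes and s_j² the pooled within-class variance (floored at
ε = 10⁻⁶). With equal class priors the decision threshold is 0:

* **Gp-R** (chemotherapy-sensitive): IS > 0
* **Gp-NR** (less sensitive): IS ≤ 0, with a low-sensitivity stratum at IS ≤ −25

Around the score, the package provides:

* probe→gene aggregation (mean of post-log2 probe values), per-feature
  mean-centering or z-scaling per dataset;
* signature adaptation when a platform supports only a subset of the genes
  (refit on the intersection, minimum 16 of 19);
* nearest-centroid intrinsic subtyping (Pearson correlation; LumA, LumB,
  HER2-enriched, Basal-like) and the joint immune scheme that splits each
  subtype by the Gp-R call (e.g. `LumA-immune`), plus average-linkage
  clustering (1 − r distance) and PCA with a |loading| > 0.10 gene filter;
* 2×2 pCR statistics: Fisher / Yates chi-square chosen by the expected-cell
  rule, Haldane-corrected odds ratios with Woolf intervals, cell-wise
  pooling, and Mantel–Haenszel fixed-effect meta-analysis
  (Robins–Breslow–Greenland CI; DerSimonian–Laird behind a flag);
* midrank ROC/AUC with the DeLong paired test, Kaplan–Meier curves,
  log-rank tests and reverse-KM median follow-up;
* the combined recurrence+immune score RI = RS + IS with its
  (IS −25, RS 25) quadrants, and a univariate predictor screen at the
  conventional cutoffs (RS > 25, Ki67 ≥ 20%, TILs > 20%, HRD ≥ 42, TMB ≥ 2).

## Worked example

```python
from immunesig import (SyntheticConfig, simulate_cohort, make_table,
                       odds_ratio, rates, auto_test)
from immunesig.reference import reference_model
from immunesig.stats import percent

config = SyntheticConfig(n_samples=1000, n_datasets=4, seed=7)
expression, clinical, truth = simulate_cohort(config)

model = reference_model()                 # packaged DLDA signature
scores = model.score(expression)          # IS + Gp-R/Gp-NR call per sample
table = make_table(scores.group, clinical.data["pcr"])
r_gp_r, r_gp_nr = rates(table)
or_, (lo, hi) = odds_ratio(table)
p, test = auto_test(table)
print(f"Gp-R pCR rate: {percent(r_gp_r):.0f}%  ({table.a}/{table.a + table.b})")
print(f"Gp-NR pCR rate: {percent(r_gp_nr):.0f}%  ({table.c}/{table.c + table.d})")
print(f"OR = {or_:.2f} (95% CI {lo:.2f}-{hi:.2f}), p = {p:.2e} [{test}]")
```

prints

```
Gp-R pCR rate: 29%  (121/420)
Gp-NR pCR rate: 8%  (48/580)
OR = 4.49 (95% CI 3.12-6.45), p = 2.53e-17 [chi-square-yates]
```

i.e. on this simulated validation cohort the signature's responder group
reaches pCR about four-and-a-half times as often (on the odds scale) as the
non-responder group — the qualitative behaviour the published validations
report (pooled Gp-R 40% vs Gp-NR 12%, meta OR ≈ 5).

The same flow is available from the shell:

```sh
immunesig fixture --out demo --seed 0      # writes a self-contained dataset
immunesig run --config demo/pipeline.yaml  # full analysis -> report.json
immunesig validate-tables                  # published pooled contingency stats
```

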