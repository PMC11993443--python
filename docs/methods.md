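# Methods

## Signature model

The immune signature is a two-class diagonal linear discriminant (DLDA):
per feature *j*, weight w_j = (μ̂1j − μ̂0j)/s_j² and midpoint
m_j = (μ̂1j + μ̂0j)/2, with s_j² the pooled within-class variance
(denominator n₁ + n₀ − 2) floored at ε = 10⁻⁶ to guard degenerate features.
The immune score IS(x) = Σ_j w_j (x_j − m_j) is the Gaussian log-likelihood
ratio under per-feature independence, equal priors and shared per-feature
variance; the decision threshold is therefore 0, matching the IS > 0
responder rule. No log-prior offset or extra intercept is used. Two
properties follow and are enforced by tests: the exact class-midpoint
vector scores 0, and rescaling any feature by a positive constant in both
training and test data leaves refitted scores unchanged.

The coefficients of the originally published 19-gene signature are
distributed through an external repository/patent and are not reproduced
here; the packaged reference model is a DLDA of the same form trained on a
fixed-seed synthetic cohort (n = 400), which keeps the artifact
self-contained. Platform adaptation refits the discriminant on the
intersection of signature genes with the platform's gene universe and
refuses to proceed below 16 genes, the precedent set when the 19-gene
signature was carried to arrays supporting only 16 of them.

## Preprocessing conventions

Probe-level matrices are collapsed to gene symbols by the arithmetic mean
of post-log2 probe values (median available); aggregation order is
aggregate-then-scale by default, with both orders exposed. Scaling is
per-feature mean-centering when raw data were renormalised, or per-feature
z-scaling (sample sd, n − 1) when only processed values are available;
z-scaling is applied within each dataset, since datasets differ by
platform. Constant feature rows z-scale to zero with a warning rather than
dividing by zero. Readers reject, never coerce, ragged rows, duplicate
ids and non-numeric cells.

## Subtyping and immune subtypes

Intrinsic subtype is assigned by highest Pearson correlation with the
subtype centroids over shared genes (≥3 required), with an `exclude` set
honouring the convention of dropping the normal-breast-like class.
Published centroid profiles are not shipped; centroids are trained from
labelled data or loaded from JSON, and the generator's block centroids act
as the packaged stand-in. Correlation ties (probability zero on continuous
data) break alphabetically with a warning; constant sample profiles are
flagged unclassified. The joint immune scheme appends `-immune` to the
intrinsic label when the sample is Gp-R; this thresholded rule is the
canonical, reproducible definition, while average-linkage clustering
(distance 1 − r) over the joint gene set is retained separately for
visualisation. A merged 6-level scheme pools LumA with LumB for survival
contrasts.

PCA is a centered SVD over the selected genes; the sign of each component
is fixed by requiring its largest-|loading| gene positive, and the
|loading| > 0.10 filter exports gene lists for external enrichment tools.

## Response statistics

2×2 tables are group × pCR with unknown outcomes excluded and counted.
The test is chosen by the standard expected-cell rule — Fisher's exact test
when any expected cell is below 5, otherwise the Yates-corrected
chi-square — and the test name is always reported, because the original
analyses do not state which test produced which p-value (two different
p-values are printed for the same comparison in one instance), so p-values
are reproducible to order of magnitude only. Odds ratios are ad/bc with
the Woolf interval; a zero cell triggers the Haldane–Anscombe +0.5
correction (default on — one published stratum has a 1/70 cell).
Meta-analysis is fixed-effect Mantel–Haenszel with the
Robins–Breslow–Greenland variance, the standard for sparse 2×2 series;
DerSimonian–Laird random effects is available behind a flag. Percentages
are rendered by round-half-up to match displayed rates (e.g. 170/424 →
40%, 83/679 → 12%, 64/184 → 35%).

## Discrimination and survival

AUC uses the midrank (ties = 1/2) convention, identical to Mann–Whitney
U/(n₁n₀); the DeLong comparison derives the variance of the paired ΔAUC
from placement values and refers ΔAUC/se to the standard normal, with
p = 1 by convention when the variance is zero and the AUCs equal.
Kaplan–Meier estimation and the log-rank test are delegated to lifelines
(events before censorings at tied times); median follow-up is the reverse-KM
median. The published real-data AUCs (0.767, 0.753 vs 0.703) require the
original pooled cohorts and define the report format only; the package's
claims about its own correctness rest on the oracle and calibration tests.

## Synthetic cohort generator

Per sample the generator draws an intrinsic subtype from configurable
proportions (default 0.35/0.25/0.20/0.20 — a luminal-dominant mix), a
latent immune activation A ~ N(0,1), and expression on a log2-like scale:
subtype block centroids (amplitude 2) on 50 subtype genes, a loading of
1.0·A on the 19 signature genes and 0.6·A on the 11 immunoglobulin
comparator genes, N(0, 0.5²) noise, and per-dataset per-gene mean shifts
(sd 0.3) as the only batch structure. pCR is Bernoulli with logit
−1.8 + 1.2·A + subtype shift (−1.0, −0.3, 0.4, 0.6), giving a marginal pCR
rate near 20% and a marginal Gp-R/Gp-NR odds ratio of ≈5 by 10⁶-sample
Monte Carlo — inside the published 4–6 range. Ki67, TILs, HRD, TMB, NLR,
PLR, recurrence score and receptor statuses are drawn as mixtures
correlated with A and subtype so the univariate screen has signal; the
A-correlations scale with one knob. Survival times are exponential with
proportional hazards (baseline 0.01/month, ratios 2.5 for non-pCR and 1.8
for non-immune status); censoring is independent with the configured
probability, a censored subject observed uniformly before its event time.
Probe redundancy adds per-probe fixed offsets (sd 0.2) and per-cell noise
(sd 0.1); a noise/offset of zero reproduces the gene matrix exactly, which
the degenerate-limit tests use. A noise sd of zero is likewise accepted as
the degenerate limit for round-trip tests, while negative values are
rejected.

The generator emulates multi-dataset structure, probe redundancy, platform
gene dropout and outcome/covariate coupling — not real GEO contents,
nonlinear batch effects, FFPE degradation, or array-specific noise. Tests
passing on these cohorts therefore demonstrate internal correctness and
calibration of the statistics, not clinical performance on real cohorts.

## Problem sizes and numerical choices

Simulation-backed checks use: 10⁶ Monte-Carlo samples for the true marginal
odds ratio; 100 replicate cohorts of n = 5000 for Woolf-CI coverage; 500
six-study simulations (n = 150 each) for Mantel–Haenszel coverage; 1000
null simulations each for DeLong and log-rank type-I error; 50 replicates
for the subtype-accuracy and AUC-dominance properties. Oracle equivalences
(DLDA vs per-feature Gaussian log-likelihood ratio, Fisher vs exhaustive
hypergeometric enumeration, AUC vs pair counting, KM vs hand-computed
product limit, log-rank vs 10⁴-permutation null) are exact to the stated
tolerances (10⁻⁹ for scores, 10⁻¹² for probabilities, Monte-Carlo error for
the permutation null).

## Known limitations

* The reference model is synthetic; real-cohort scoring requires loading
  the original coefficients as a model JSON.
* The RI-score is the plain sum RS + IS (configurable a·RS + b·IS); the
  original construction's exact scaling is not public.
* Random-effects meta-analysis uses the simple DerSimonian–Laird moment
  estimator; no Knapp–Hartung adjustment.
* Cox regression, multivariable logistic models and GSEA are out of scope;
  gene lists are exported for external enrichment tools instead.
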