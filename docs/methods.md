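# Methods

## The model

The phenotype risk score treats a Mendelian disease as a set of
characteristic phenotypes (phecodes) and a patient's record as a set of
binary indicators over those phenotypes. For person *i* and disease *k*,

    s_ik = Σ_{j ∈ P_k} w_j · x_ij,      w_j = log10(N / n_j),

with *P_k* the disease's phecode set, *x_ij* = 1 iff the person has at
least one occurrence of phecode *j*, *N* the cohort size and *n_j* the
number of individuals with at least one occurrence of *j*. The score is
a weighted count, not a probability: rarity is the only notion of
informativeness, and co-occurrence structure between phecodes is
ignored. Occurrence counts beyond the first carry no information under
the binary indicator, which is why same-day duplicate ICD postings are
collapsed on load.

Key conventions:

- *N* counts every person in the demographics table (everyone with at
  least one visit), not just persons with a mapped phecode.
- Weights are base-10 logarithms, non-negative by construction.
- Phecodes never observed in a cohort have no defined weight
  (log10(N/0)); they are omitted from the weight table and contribute 0
  to scores, with a warning. Externally supplied weight tables (e.g.
  from a larger reference cohort) may be used instead, in which case
  prevalence columns are marked unknown.
- The score grid is dense: every person × every disease, zeros
  explicit, so downstream regressions see the cohort's zero-inflation
  rather than a carrier-only subset.

## Residual scores

Raw scores correlate with record length, age and sex simply because the
opportunity to accumulate codes does. Residual scores are per-disease
OLS residuals of the raw score on an intercept plus covariates
(default: sex indicator with female as the alphabetically first
reference level, age at first visit in years, and the first-to-last
visit span in years), divided by the residual standard deviation with
denominator (n − p), p the number of fitted parameters. Under this
convention the residual scores have sample mean 0 and variance exactly 1
per disease, which is what makes them comparable across diseases. The
fit uses `numpy.linalg.lstsq`; tests cross-check against statsmodels
OLS. Zero-variance covariates are dropped with a warning; a disease
whose residual variance is numerically zero (score an exact linear
function of the covariates) is an error rather than a silent division
by zero. Residualization is fit on the full cohort including diagnosed
cases, and the fit is invariant to affine rescaling of any covariate.

## Case/control assignment

A person is a case for a disease if any of the disease's diagnostic ICD
codes appears on ≥ 2 distinct calendar dates, a control on 0 dates, and
neither on exactly 1 — requiring two distinct dates improves positive
predictive value over one. Distinct-date counting pools all of a
disease's diagnostic codes. "Distinct dates" is a calendar concept, so
timestamps are truncated to days on load. The threshold is exposed
(`case_min_dates`); with a threshold of 1 the "neither" category is
empty by construction. The validation regression (score on a case
indicator plus covariates) skips diseases with fewer than 2 cases or
controls; the CLI raises this reporting screen to 50 cases by default,
a conventional minimum for a stable comparison, without ever affecting
status assignment itself.

## Association tests

Associations are ordinary least squares of the score on an encoded
genotype plus intercept and covariates, with t-based two-sided p-values
at n − p degrees of freedom. Encodings for alternate-allele count
g ∈ {0, 1, 2}: additive [g]; dominant [g ≥ 1]; recessive [g = 2];
genotypic [g = 1, g = 2] against the homozygous-reference baseline.
The genotypic model is the diagnostic readout for recessive disease: a
pathogenic variant shows a positive homozygote coefficient with a
near-zero heterozygote coefficient. Missing genotypes are excluded
pairwise per variant (each disease–variant pair keeps the maximal
sample); reported genotype counts always cover the full cohort
including missing, and are independent of the model. Rank-deficient
designs (e.g. no homozygotes under the recessive encoding) yield rows
flagged `estimable = False` instead of an exception. p-values are
reported raw; an optional Bonferroni column over the supplied pair list
is available. The default outcome column is the residual score when
present (cross-disease comparability), else the raw score.

## Map assets

Three maps drive the pipeline: ICD → phecode, disease → phecode, and
diagnostic-ICD → disease. The disease → phecode map can be built from a
disease → HPO-term annotation table (with gene, inheritance pattern and
provisional flag) joined to an HPO-term → phecode link table. Filters,
in order: rows with multifactorial, somatic or unspecified inheritance
(case-insensitive, configurable) and provisional rows are dropped —
exclusion is row-level, so a disease annotated through another gene
with a retained pattern survives; the join is exact on the HPO term id;
the result is deduplicated on (disease, phecode); diseases with fewer
than 3 distinct phecodes are removed (a one- or two-feature "pattern"
is not a pattern). Link match quality (exact vs broader) is carried
through for user-side filtering but does not affect scoring. All joins
on ICD codes are exact-string after trimming and upper-casing; no
prefix/rollup matching is attempted because phecode maps enumerate
codes explicitly, and diagnostic-code exclusion removes exactly the
listed codes. User-supplied custom maps may violate the ≥ 3-phecode
filter; the loader warns rather than refuses.

The bundled maps are synthetic toy fixtures (~30 phecodes, 5 diseases,
3 of them with diagnostic codes) written to look like real ICD-9/ICD-10
and OMIM-style identifiers so examples read naturally. They exist so
the package is testable offline; they are not curated clinical content.

## The synthetic cohort generator

The generator emulates the inputs of a score analysis with a planted,
known truth:

- **Demographics.** Sex Bernoulli(0.5); age at first visit uniform on
  0–90 years (the range seen in large hospital cohorts); visit span
  exponential with mean 5 years, floored at 30 days so two distinct
  diagnostic dates always fit inside a window.
- **Background code burden.** Per-person Poisson counts at
  `background_code_rate` (default 6 codes/person) scaled by log-linear
  sex/age/span effects (defaults 0.2/0.5/0.3 on centered covariates),
  so raw scores are genuinely confounded with the default covariates
  and residualization has something to remove. Codes are drawn from the
  ICD → phecode map with disease-feature codes at a quarter the
  frequency of filler codes — Mendelian features are rarer than
  hypertension — plus two deliberately unmappable codes to exercise the
  unmapped-code accounting. Diagnostic codes never appear in the
  background, keeping case/control truth exact.
- **Cases.** Each configured disease plants `n_cases` persons (default
  50 at n = 5000) who emit each feature phecode's source ICD code with
  probability `feature_emission_prob` (default 0.8) and receive a
  diagnostic code on two distinct dates; a further n_cases/5 persons
  get a single-date diagnostic posting to populate the "neither"
  category.
- **Genotypes.** Allele counts Binomial(2, q) — Hardy–Weinberg by
  construction. Defaults: a pathogenic variant at q = 0.05 with
  homozygote effect 2.0 on the raw-score scale, and a benign variant at
  q = 0.20 with no effect.
- **Effect calibration.** Variant effects are planted on the raw-score
  scale so recovery tests have an analytic target. For each carrier,
  the linked disease's phecodes the carrier lacks are emitted greedily
  in decreasing-weight order while the accumulated weight stays below
  the effect, then one more phecode is emitted with the Bernoulli
  probability that tops the expectation up to the effect exactly.
  Weights for this calibration come from the pre-boost cohort. The
  greedy-plus-top-up scheme keeps carrier-level shift variance near the
  minimum a discrete emission process allows; a fully independent
  per-phecode Bernoulli scheme delivers the same expectation but
  inflates the homozygote-group variance enough that classical OLS
  standard errors undercover. Emission sources are restricted to ICD
  codes mapping to exactly one phecode, so a planted emission moves
  only the intended indicator. Carriers already holding nearly all
  feature phecodes receive the largest shift still available (the
  capped mean delivered shift is recorded in the truth record); at the
  default prevalences this caps about 2% of the target on average.

All randomness flows from a single `numpy.random.default_rng(seed)`;
identical config and seed reproduce byte-identical tables, which is
what the end-to-end CLI determinism test checks.

What the generator does *not* emulate: visit clustering and temporal
autocorrelation of codes, coding-era shifts (ICD-9 → ICD-10 migration),
correlated comorbidity structure, relatedness or population structure
in genotypes, and diagnostic codes appearing without true disease.
Passing tests therefore demonstrate the pipeline's statistical
machinery — calibration, unbiasedness, determinism — on idealized data,
not robustness to real EHR pathologies.

## Problem sizes and test design

Unit tests run on handfuls-to-hundreds of persons with brute-force
oracles (double-loop score computation, per-row join expansion,
closed-form OLS). The type-I error checks use 1000 null replicates at
n = 500 and require empirical rejection at α = 0.05 inside the binomial
99% CI. Planted-effect recovery uses 100 replicates at n = 5000 —
large enough that the homozygote count (~12) supports a stable
coefficient, small enough to keep the whole suite under a minute — and
requires the hom-alt 2-SE interval to cover the planted effect in ≥ 90%
of replicates with the replicate mean within 5%. The acceptance script
reports the same quantities at 30 recovery replicates.

## Numerical choices

- Score summation is accumulated per disease over phecodes in
  ascending code order, so results are bit-reproducible by a
  sequential oracle and across runs.
- Degenerate residualization (sd ≤ 1e-10 relative to score scale) and
  n ≤ p are errors, not NaNs.
- Design-matrix rank is checked explicitly before each association fit;
  non-estimable results are flagged, never imputed.
- Canonical sort orders (each table's key) make loading
  order-invariant and outputs deterministic.

## Known limitations

- Exact-string ICD joins mean dialectal code variants (ICD-10 vs
  ICD-10-CM) must be reconciled by the supplied map, not the package.
- The binary x_ij model ignores recurrence and severity; zero-inflated
  or time-aware scoring is out of scope.
- Case identification from diagnostic codes is only possible for the
  minority of Mendelian diseases with a specific ICD code, and a
  diagnostic code is not a confirmed genetic diagnosis.
- Association tests assume independent individuals; no kinship or
  ancestry adjustment beyond user-supplied covariate columns.
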