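# Methods

This note documents the models, numerical choices and limitations behind
`osagut`, in the order the pipeline runs.

## Synthetic cohort model

The generator exists so that every analysis stage can be validated against a
known truth.  It emulates the statistical structure the analysis assumes; it
does not emulate sequencing.

**Exposures.**  A trivariate Gaussian copula drives AHI, ODI and T90.  The
three latent normals are drawn from the full 3×3 correlation matrix with
default targets 0.92 (AHI–ODI), 0.56 (AHI–T90) and 0.63 (T90–ODI); a
single-factor construction cannot reproduce this triangle (the implied ODI
loading exceeds 1), which is why the full matrix is factorized by
eigendecomposition — this also makes the degenerate all-correlations-1
configuration representable, in which all three parameters collapse to
monotone transforms of one severity score.  The latent severity factor is
*defined* as the ODI latent, ODI being the cleanest intermittent-hypoxia
measure.  Marginals: AHI = exp(1.335 + 1.296 z) and ODI = exp(1.411 +
1.251 z) events/h (medians ≈ 3.8 and 4.1, right-skewed as in middle-aged
population screening); T90 = max(0, exp(1.072 + 2.2 z) − c) percent, capped
at 100, with the shift c set so a configurable fraction (default 0.30) is
exactly zero — the hurdle that creates the "T90 = 0" severity group.
Monte-Carlo rank correlations land within ±0.02 of the targets at n ≥ 2,000
(the contract allows ±0.08; the zero point mass attenuates the T90 pairs
slightly).

**Covariates.**  Age uniform on 50–64 y; sex binary; smoking (3 levels),
education (4), physical activity (4), birth country (4), season (11), DNA
plate (≥8 levels, ~96 samples per plate) with realistic frequencies;
alcohol/fiber/energy log-normal (energy median ≈ 1,611 kcal/d); hemoglobin
normal with a +13 g/L male shift; waist-to-hip ratio tied to the BMI latent.
BMI is the confounder: BMI = 26.5 + 3.5·(w·severity + √(1−w²)·ε) with
w = `confounding_strength` (default 0.3).  Fiber and energy receive a small
MCAR missing fraction (3%) so the extended model's complete-case sample is
genuinely smaller than the main model's.

**Abundances.**  Latent Gaussian per species: g = β·severity + γ·BMIz + ε,
with β = ±`effect_size` for the planted positive/negative species (defaults:
15 + 15 of 300, effect 0.5) and γ = 0.35 for the BMI-confounded species
(default 10, drawn from the null set).  Abundance = exp(μⱼ + σⱼ g), μⱼ ~
N(−1, 2²), σⱼ ~ U(0.5, 1.5), left-censored at a per-species detection
quantile (Beta-distributed censoring probabilities, mean = `zero_inflation`)
so rarity couples with low abundance; a tail of null species is forced below
1% prevalence to exercise the prevalence filter.  Rows are closed to sum 1.

Two deliberate design choices here: (i) planted positive and negative
species are *paired* on (μⱼ, σⱼ) so their opposite severity effects cancel
in the row totals — without the pairing, closure pushes a spurious severity
signal of order ρ ≈ 0.03 into every null species at n = 2,000, and
BMI-confounded hits cannot be cleanly removed by BMI adjustment because the
compositional signal is not a BMI path; (ii) the confounder loading 0.35 is
chosen so confounded species are reliable screening-stage hits while the
residual association left after linear rank-residualization on BMI (ranks
are sigmoid, not linear, in the latent — the familiar imperfection of
partial rank correlations) stays below the detection threshold.  Both are
properties of the data-generating design, not of the inference code.

**Function.**  ~20 synthetic GMMs with 2–8 steps (1–3 KO alternatives per
step, 20% of modules with a second path) over a 1,500-KO universe.  Carriage
of the planted modules (default 3) is 0.9 among planted-positive species and
0.08 elsewhere; non-planted modules are carried at 0.30 everywhere.  A share
of carriers gets only the minimal step coverage and some non-carriers a
near-miss one step short, so both sides of every detection-rule branch occur.
Background KOs are sampled outside the module KO pool so carriage is always
deliberate.

**Event records.**  Flow/SpO₂ recording times ~7 h; event counts are rounded
from rate × recording time, so recomputing the parameters from records
reproduces the exposure table within count rounding.  A configurable
fraction (default 10%) of flow recordings is drawn below the 4-h validity
threshold (SpO₂ stays valid), under MCAR or a BMI-dependent MAR mechanism —
this is the source of missing AHI that the imputation stage addresses.

**Outcomes.**  SBP/DBP depend on age, sex, BMI and, for the planted outcome
species (a subset of the positive species), on rank-normalized abundance at
`bp_effect` mm Hg per SD (default 2.5); HbA1c has no planted microbiota
effect by default.  Because BMI affects both the confounded species and BP,
a BMI-mediated species–BP association exists and attenuates under BMI
adjustment, as the post hoc stage expects.  Medication indicators are
independent Bernoulli draws with configurable prevalences.

**What passing tests do and do not show.**  The generator has Gaussian-copula
dependence, independent participants, no batch structure beyond a random
plate factor, no phylogenetic correlation among species, and medication
assignment independent of health state.  Recovery and calibration results
therefore validate the *inference machinery* under the assumed structure;
they are not evidence about effect sizes, power or confounding behaviour in
real cohorts.

## OSA parameters

Channel-specific denominators: events per hour of *flow* recording for AHI,
per hour of *SpO₂* recording for ODI, and SpO₂ time for T90 — validity is
assessed per channel (4-h rule), and AHI additionally requires the SpO₂
channel because hypopnea scoring needs a desaturation.  Severity intervals
are closed on the left ([5,15), [15,30), ≥30).  T90/ODI group breaks are
empirical quantiles with linear interpolation; values tied at a break go to
the lower group.  Missing parameters propagate as missing labels, never as
zeros.  Energy cleaning flags ln-scale values beyond mean ± 3 SD (computed
before flagging); if the SD is zero nothing is flagged.

## Diversity and PERMANOVA

Shannon uses natural log (a log2 flag exists).  Bray–Curtis is computed in
chunked vectorized form and symmetrized exactly.  PCoA eigendecomposes the
double-centered Gower matrix; negative eigenvalues stay in the reported
spectrum but are excluded from the explained-variance denominator, and no
Lingoes/Cailliez correction is applied.  PERMANOVA enters covariates before
the group term (sequential SS) using the trace identities SS = tr(H G) with
QR-derived projection hat matrices; quantitative covariates are standardized
and categoricals one-hot encoded before the partition.  The default null
permutes raw rows (rows/columns of G jointly); a Freedman–Lane residual
permutation is available via `method="freedman-lane"`.  The permutation
p-value is (1 + #{F* ≥ F}) / (1 + B) with B defaulting to 9,999 for the
library function; the pipeline config defaults to 999, a desk-scale choice
that still resolves p ≈ 0.001.  A group term collinear with the covariates
raises rather than returning a zero-df statistic.

## Association cascade

Partial Spearman is the rank-then-residualize variant; the
correlation-matrix-inversion variant gives identical ρ and serves as the
test oracle.  Ties get mid-ranks.  p-values use the t approximation with
df = n − 2 − k.  Zero-variance rank residuals and covariates identical to a
correlated variable raise — never a silent number.  Complete-case sets are
recomputed per exposure and per model, so AHI analyses have smaller n than
T90/ODI (invalid flow) and extended-model analyses smaller n than main
(diet missingness).  BH runs within each (exposure, stage) family — the
narrowest reading consistent with per-exposure q-values; the screening
threshold defaults to the FDR level (0.05) and is configurable.  Degenerate
categorical levels after subsetting are dropped from the design with a
warning.  Diversity associations run the Shannon index through the same
engine under the main and extended models.

## Heterogeneity by hemoglobin

Strata are sex-specific: at or below the sex median → low (ties low).  The
stratified coefficient comparison is on the raw ρ difference,
z = (ρ_low − ρ_high)/√(SE² + SE²), with bootstrap SEs (default B = 1,000)
from a full-pipeline bootstrap — participants resampled with replacement,
ranks and covariate residualization recomputed per resample (batched normal
equations with a 1e-8 ridge against one-hot degeneracy).  A Fisher-z variant
with analytic 1/(n−3) variances sits behind a flag.  BH runs across species
within exposure.

## Imputation

PMM type-1 matching: coefficients perturbed by a scaled-inverse-χ²/normal
posterior draw, predictions for missing rows matched to the k = 5 nearest
observed predictions, donor drawn uniformly; observed values are never
altered and imputed values are always members of the donor pool.  One
imputation round per species, with the species' rank-transformed abundance,
the extended covariates (numerically encoded), Shannon, T90, ODI and WHR as
predictors; m = 10.  Per-imputation ρ is Fisher-z transformed with variance
1/(n − 3 − k) (the partial-correlation analogue of 1/(n−3)), pooled by
Rubin's rules (total = W + (1 + 1/m)B, df = (m−1)(1 + W/((1+1/m)B))²), and
the pooled z is back-transformed for reporting.  `rubin_pool` itself is
scale-agnostic: it pools whatever estimates/variances it is given.

## GMM detection and enrichment

Step coverage counts *steps*, not KOs: a path qualifies when covered steps
≥ ⌈2/3 · n_steps⌉ for paths longer than three steps, or all steps otherwise;
any qualifying path suffices.  The ceiling implements "at least two-thirds"
as a lower bound; a per-KO-fraction variant was considered and rejected as
the default because the all-steps rule for short modules is itself stated in
steps.  Enrichment restricts to species whose extended-model ρ has the
requested sign, ranks by ascending p, and applies a one-sided Mann–Whitney
test (carriers lower); the normalized score is the standardized U statistic.
Enrichment consumes extended-model results for *all* prevalence-filtered
species (one row per species) — restricting to cascade hits would leave no
non-carrier contrast.  Modules with fewer than three carriers or
non-carriers in the stratum are skipped with a warning; BH runs within
(exposure, direction).

## Co-occurrence

Presence is abundance > 0 (the same convention as the prevalence filter; no
detection threshold).  Exact hypergeometric tails classify each pair at
α = 0.05 (configurable): positive if P(X ≥ obs) < α, negative if
P(X ≤ obs) < α, else random.  Both tails include the observed point mass, so
p_lt + p_gt ≥ 1.  Pairs whose most extreme attainable count could not reach
α are flagged untestable.  Following the convention of probabilistic
co-occurrence analysis, no multiple-testing correction is applied to pair
classifications — a documented caveat when reading edge counts.

## Post hoc outcome models

Hit species and their combined relative abundance are tested against SBP,
DBP and HbA1c under age, sex, alcohol, smoking, fiber, energy, physical
activity, birth country, all three OSA parameters and plate; season is not
in this covariate set, and BMI enters only in a second pass.
Antihypertensive users are excluded from BP models, antidiabetic users from
HbA1c.  Combined abundance and individual species share one BH family per
(outcome, BMI-pass) — the open choice was one family vs two; one family is
the more conservative reading and is used throughout.

## Problem sizes and numerical notes

Unit tests use cohorts of 350–500 participants; recovery checks use the
generator's default study conditions (n = 2,000, 300 species, effect 0.5,
20 replicates) and calibration checks use ≥2,000 null replicates per
statistic — sizes at which every contract bound is met with Monte-Carlo
margin while the whole suite runs in a couple of minutes.  Vectorization
carries the load: the cascade ranks all species at once and residualizes
them with a single multi-RHS least-squares solve; PERMANOVA permutations
reindex the precomputed Gower matrix; the bootstrap solves batched normal
equations.  lstsq/QR handle rank deficiency; correlations are clipped to
[−1, 1] before the t transform; |ρ| = 1 maps to p = 0 rather than a
division-by-zero.

## Known limitations

No compositional transform (CLR) is offered: relative abundances are
correlated directly, by design, so compositional coupling is a real
(documented) phenomenon in both the generator and the inference.  PERMANOVA
assumes exchangeability under the chosen permutation scheme; the
Freedman–Lane option mitigates but does not eliminate covariate leakage.
Partial rank correlation does not exactly remove monotone-but-nonlinear
covariate effects.  The heterogeneity z-test relies on bootstrap SEs being
approximately normal.  Imputation covers AHI only (single-variable PMM, not
chained equations).
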