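# Methods

This note documents the models, numerical choices and known limitations
of `dualrisk`. It is written for users who want to know exactly what
the package computes and what its tests do and do not establish.

## Scores

**M-value transform.** Beta fractions are mapped to M-values by
`M = log2(β / (1 − β))` after clamping β to `[ε, 1 − ε]` with
`ε = 1e-6` (configurable, `0 < ε < 0.5`). The transform is undefined at
0/1 and normalized arrays can produce boundary values, so clamping is
applied unconditionally; it is a no-op for any β at least ε from the
boundary. The transform is strictly increasing and antisymmetric about
β = 0.5.

**EIS.** `eis_raw_i = Σ_j w_j · M(β_ij)` over the probes shared between
the beta matrix and the weight table; the composite is then
z-standardized (sample SD, n−1 denominator) over the scoring sample.
Standardization pools both waves by default so that between-wave change
is preserved; per-wave standardization is available. Probes missing
from a given array are scored with the available probes — coverage is
recorded per observation and a warning is issued below 95% — with **no
weight renormalization**: renormalization would change the score scale
across cohorts, while the subsequent z-standardization already absorbs
constant offsets. A zero-variance composite or a single observation is
an error, not a silent degenerate z-score.

**CRI.** The plain mean beta over six cardiac-risk CpGs, reported in
beta-fraction units. Lower values mean higher risk; the package never
sign-flips the index, so negative regression coefficients on CRI
predictors read as "higher predictor, more demethylation, more risk".
By default the mean is taken over whichever of the six probes are
observed (with `n_cri_probes_used` recorded); a strict 6-of-6 mode is
available. A constant probe set returns that constant exactly.

**ATS.** An unweighted sum of four per-locus z-scores. The assay is a
fixed 4-plex: a missing locus value is an error (no partial ATS). The
reference distribution for the z-scores is injectable: by default each
locus is standardized against the pooled scoring sample; fixed
per-locus (mean, SD) pairs can be supplied instead. The validated
elevated-use cutoff 2.35 presumably refers to an external calibration
that is not published, so the package keeps the reference explicit
rather than pretending pooled-sample z-scores are automatically on the
validated scale. Classification uses strict `ats > 2.35`.

## Estimation core

**EM for the partially observed MVN.** The joint vector is modelled as
multivariate normal. Rows are grouped by missingness pattern; the
E-step computes conditional means and covariances of each missing block
given the observed block, the M-step pools the expected sufficient
statistics with the ML (n) denominator. Convergence is declared when
the observed-data log-likelihood changes by less than 1e-8 (max 500
iterations; non-convergence sets a flag rather than raising — these are
desk-scale problems and strictness is cheap). Initialization is the
diagonal of the per-variable ML variances, which is always PSD; the EM
log-likelihood is monotone from any start. A singular covariance is
ridge-regularized by `1e-8 · trace/d` on the diagonal, always with a
warning — silent regularization corrupts inference. Fully missing rows
are dropped with a warning; a variable observed fewer than twice is an
error.

**FIML regression.** Coefficients come from the fitted joint moments:
`b = Σ_xx⁻¹ σ_xy`, intercept `μ_y − b′μ_x`. This matches a saturated
joint-normal ML treatment of (outcome, predictors) and uses rows with a
missing outcome *or* missing predictors — which is why per-model N can
exceed the completer count. `R² = b′ Σ_xx b / σ_yy`; standardized
coefficients are `β_j = b_j · sd(x_j)/sd(y)` with **model-implied**
SDs (the natural choice under FIML; sample SDs on complete cases would
mix estimands across missingness patterns).

**Cluster sandwich.** Standard errors are computed on the joint
parameter vector θ = (μ, vech Σ): per-row analytic scores of the
observed-data log-likelihood are summed within clusters (couples) to
form the meat `Σ_g s_g s_g′`, the bread is the observed information
obtained by complex-step differentiation of the analytic score
(machine-precision derivatives, step 1e-20), and the delta method maps
`V_θ` to the regression coefficients, again via complex step. At the
MLE this construction is exactly equivariant under reparametrization,
which yields a sharp check: with complete data and singleton clusters
it reproduces HC0 standard errors to machine precision, and the test
suite asserts this at 1e-8. The meat is multiplied by `G/(G−1)`
(G = number of clusters) by default — the common CR1-style small-sample
factor — switchable to plain CR0 via `small_sample="none"`. Wald tests
use the standard normal (z), not t.

**Fit indices.** `χ² = 2(ll_sat − ll_model)`,
`RMSEA = sqrt(max(χ²−df, 0)/(df (n−1)))`,
`CFI = 1 − max(χ²_m−df_m, 0)/max(χ²_b−df_b, χ²_m−df_m, ε)`, with the
baseline the independence model with free means and variances. Because
every regression here is a reparametrization of the saturated joint
normal, its χ² is 0 on 0 df and RMSEA is reported as 0 with an explicit
note. Published tables of this model family sometimes print a large
baseline-style chi-square next to RMSEA = 0 and CFI = 1 for the same
model, which is internally inconsistent with these formulas; the
package always reports all three from its own definitions and leaves
the model and baseline chi-squares separately visible.

**Paired change test.** One-sample t on within-person differences over
complete pairs, `df = n_pairs − 1`. All-zero differences return t = 0
(the 0/0 limit by convention); identical *nonzero* differences are an
error, since the zero-SD statistic is undefined.

## Analysis models

**Prediction series.** Model 1: CRI6 ~ age + sex + CRI5; Model 2 adds
ATS5 and EIS5; Model 3 adds wave-5 self-reported binge drinking (raw
self-report scale, untransformed); Model 4 adds EIS5 × age with both
parents mean-centered before the product (main effects stay on their
raw scales). All fits are couple-clustered FIML; standardized
coefficients are reported with two-tailed stars (* < .05, ** < .01),
and the ΔR² chain is checked against the R² column to 1e-10.

**Change models.** With exactly two waves a person-specific random
slope is not identified separately from residual variation, so the
primary formulation operationalizes each person's slope as the simple
between-wave difference (one wave unit ≈ 3 years):
`ΔCRI ~ (age − 40) + sex + CRI5 + ΔATS + ΔEIS`, raw coefficients
reported, baseline CRI read as a lagged adjustment. People missing a
wave contribute through FIML over the joint vector. The stacked
person-wave formulation is a labelled sensitivity analysis: outcome CRI
per person-wave, a wave (time) main effect, person-mean (between) ATS/
EIS and within-person-centered ATS/EIS; its within coefficients carry
the change effects. Because baseline CRI absorbs part of the
within-person outcome variation in the stacked form, its change
coefficients are attenuated relative to the difference form; the two
are required to agree in sign, not magnitude.

## Synthetic cohort generator

The generator emulates a two-wave couples design: person-level
6-vectors (ATS5, EIS5, CRI5, ATS6, EIS6, CRI6) with a target
correlation matrix, a shared couple factor giving within-couple
correlation `couple_icc` (default 0.2) with unchanged marginals, ages
N(44.61, 8.22²) in years, 54% female (sex coded 1 = female — the
coding is a config note, not a substantive claim), and a three-category
participation pattern (both / wave-5 only / wave-6 only) with default
probabilities (271, 77, 35)/383 per person. Every recruited couple
contributes both partners, so the default cohort has 442 individuals
rather than the 383 of a design where some couples enroll one partner;
the correlation and effect structure — what the recovery checks consume
— does not depend on that difference. (Published counts for such
designs can themselves disagree: 2·271 + 77 + 35 = 654 person-waves,
while an overall figure of 661 is sometimes quoted alongside it; the
generator reports its realized counts and takes no side.)

Nine of the fifteen target correlations are fixed from the printed
two-wave structure (stabilities 0.846/0.639/0.479; within-wave
ATS–EIS 0.403/0.413, ATS–CRI −0.378/−0.434, EIS–CRI −0.580/−0.650).
The six unprinted cross-wave cross-trait entries are filled by the
product rule `r(X5, Y6) = r(X5, Y5) · r(Y5, Y6)` and the matrix is
projected to the nearest PSD correlation matrix (eigenvalue floor,
rescale to unit diagonal). A consequence worth knowing: the product
rule makes the *partial* cross-wave effects zero given baseline, so in
the default correlation mode the prediction models correctly estimate
near-zero ATS5/EIS5 coefficients. The structural modes exist to inject
nonzero effects:

* **structural** — CRI6 (z scale) is `Σ β_j x_j + e` with standardized
  coefficients on standardized age, sex, CRI5, ATS5, EIS5 (defaults are
  the full prediction-model effect block: −0.108, 0.112, 0.368, −0.193,
  −0.042) and residual variance `1 − β′Rβ` (error if ≥ 1);
* **structural_change** — the CRI difference is generated from raw
  coefficients on age−40, sex, CRI5, ΔATS, ΔEIS (defaults 0.0001,
  0.0106, 0.6098, −0.0004, −0.0145) plus N(0, 0.025²) residual; the
  residual SD is chosen so the model's explained-variance share is in
  the ballpark of the published change models.

ATS marginals default to means 2.201/2.195 with SD 1; EIS is on its z
scale (0, 1). CRI marginals (0.55, 0.05 on the beta scale) are **not**
published values — they are plausible mid-range beta fractions chosen
once to avoid boundary clamping, and documented as arbitrary. Wave-5
binge drinking loads 0.3 on the ATS5 latent (chosen as a moderate
self-report/biomarker agreement) and is otherwise independent, so the
binge step of the prediction series is a true null. Missingness is
MCAR by default; setting `mar_logistic_coef` makes wave-6 dropout
depend logistically on the wave-5 ATS z-score, giving a genuinely MAR
mechanism for stress-testing FIML. Ages are drawn once per person
(age at wave 5) and held fixed across waves; models only ever use
baseline age.

**Beta embedding.** `embed_betas` inverts the scoring step so the whole
pipeline can run from CpG level: M-values at the weight probes are the
minimum-norm solution of `w·M = eis` plus noise projected onto the
null space of `w` (the weighted sum is exact by construction); the six
CRI probes are `cri + δ` with zero-sum δ (exact mean, barring [0,1]
clamping, which is warned); the four ATS probes encode `ats/4` plus
zero-sum deviations linearly around beta 0.5. Scoring the ATS probes
against the fixed per-locus reference recorded in `CohortTruth`
recovers the target exactly; pooled-sample scoring — an affine map of
the same values — recovers it up to location/scale (correlation 1).
Exact pooled-route recovery is impossible in general, since pooled
standardization re-anchors the scale to the sample at hand.

## What passing tests show — and what they do not

The recovery tests demonstrate that *if* data arise from the calibrated
generative structure, the pipeline estimates that structure without
bias at Monte-Carlo tolerance (correlations ±0.03, standardized
effects ±0.02, change effect ±0.002), under the study-sized cohort and
missingness pattern. The generator draws scores from exact multivariate
normals; real methylation scores have skew, heavy tails, batch
structure, assay noise correlated across loci, and missingness that
need not be MAR — none of which are emulated (beyond the optional
logistic MAR mechanism). Passing therefore validates the estimator and
the plumbing, not the biological claims, and says nothing about
unmodelled confounding in real cohorts.

## Numerical choices, degenerate inputs, limitations

* EM tolerance 1e-8 on the log-likelihood, max 500 iterations; ridge
  `1e-8·trace/d` only on singularity, always warned.
* Collinearity: an error naming the offending pair when the largest
  off-diagonal predictor correlation exceeds `1 − 1e-6` or the
  condition number of the predictor correlation matrix exceeds 1e10.
* Fewer clusters than predictors + 1 is an error.
* Complex-step derivatives use step 1e-20; no finite-difference
  truncation error enters the sandwich.
* The seeded pipeline is bit-reproducible; one global seed fans out to
  independent per-stage streams (SeedSequence), so stages re-run in
  isolation match the pipeline run.
* Not implemented (out of scope): IDAT parsing and array normalization
  (the package consumes already-normalized betas), derivation of EWAS
  weights (consumed as an input file), latent-variable SEM, multiple
  imputation, actor–partner interdependence models (couples are
  nuisance clusters only), and any causal adjustment beyond the stated
  regressions.
* Whether array-derived betas at the four ATS loci are a valid
  substitute for the digital-PCR assay is untested; the scoring module
  supports both input routes but does not claim equivalence.
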