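# Methods

`crtmi` studies how to impute missing binary outcomes in two-arm cluster
randomized trials (CRTs), where patients are randomized in groups (here:
family practices) and outcomes within a group are correlated. Standard
multiple-imputation (MI) procedures assume independent observations; this
package implements the standard procedures alongside cluster-aware variants
and quantifies, by simulation, what ignoring the intra-cluster correlation
costs.

## Outcome model and synthetic cohort

The generative model is a random-intercept logistic regression

    logit Pr(Y_jl = 1 | u_j) = x_jl' beta + u_j,    u_j ~ N(0, sigma_b^2),

for patient `l` in cluster `j`, with covariates: treatment arm, diabetes,
heart disease, age (years, centered), baseline blood-pressure control, and
sex. On the latent (logistic) scale the intra-cluster correlation is

    rho = sigma_b^2 / (sigma_b^2 + pi^2/3).

The default cohort emulates a community hypertension trial in elderly
primary-care patients: 14 clusters per arm, 55 patients per cluster (1540
patients), marginal outcome prevalence 0.55, latent ICC 0.055
(`sigma_b^2 = 0.1915`), and an adjusted arm odds ratio of 1.14
(`beta_arm = log 1.14 = 0.1310`).

Defaults and their provenance:

| parameter | default | why |
|---|---|---|
| clusters per arm | 14 | trial design being emulated |
| cluster size | 55 | trial design being emulated |
| `beta_arm` | log(1.14) | matches the adjusted treatment OR |
| `beta_diabetes` | −0.04 | published model coefficients for this trial |
| `beta_heart_disease` | 0.1224 | " |
| `beta_age` (per year) | −0.0066 | " |
| `beta_baseline_control` | 1.1487 | " |
| `beta_sex` | 0.0873 | " |
| `sigma_b^2` | 0.1915 | solves rho = 0.055 on the latent scale |
| intercept | −0.47392 | calibrated so marginal prevalence = 0.55 |
| age | TruncNormal(75, 6²) on [65, ∞) | plausible for an elderly hypertension cohort (≥65 enrolment); not published |
| sex, baseline control | Bernoulli(0.5) | not published; configurable |
| diabetes, heart disease | Bernoulli(0.2) | not published; configurable |

The published SAS starting values for this model include `s2u = 0.5`, which
is inconsistent with the reported ICC of 0.055; we treat all of those numbers
as optimizer starting values, not data estimates, and take the slopes from
the model estimates listed above.

`calibrate_intercept` solves for the intercept by root-finding on a smooth
prevalence curve built from one large fixed Monte-Carlo sample (10^6 draws by
default) of the non-intercept linear predictor; the root is deterministic
given the calibration seed and accurate to ~5×10⁻⁴ in prevalence. Targets
unreachable inside the intercept bracket raise a calibration error.

What the generator deliberately does not emulate: covariate correlations
(all covariates are independent), informative cluster sizes, covariates
associated with the random effect, and missing covariates. Results on this
cohort therefore demonstrate the *mechanics and relative behaviour* of the
strategies under clean conditions, not their performance on any real trial.

## Missingness

Only the outcome is ever masked.

* **MCAR** — i.i.d. Bernoulli(f) per patient, independent of everything.
* **CD (covariate-dependent)** — males, control-arm patients, and patients
  uncontrolled at baseline are 1.2, 1.3 and 1.4 times more likely to be
  missing. "Times more likely" is read as an *odds* multiplier inside a
  logistic missingness model whose intercept is solved numerically so the
  expected overall fraction equals f; this keeps probabilities in (0,1) even
  at f = 0.5. A risk-multiplier reading (probabilities capped at 1) is
  available via `interpretation="risk"`.

Both mechanisms are outcome-independent given covariates (ignorable), which
is what justifies the imputation strategies studied.

## Imputation strategies

Ten strategies = engine × scope:

| scope | engines | clustering handled how |
|---|---|---|
| ignore_cluster | logistic, propensity/ABB, MCMC | not at all (standard MI, run separately per arm) |
| within_cluster | logistic, propensity/ABB, MCMC | each cluster imputed from its own rows |
| across_cluster | propensity (+cluster covariate), random-intercept logistic, fixed-effects logistic | clustering modeled explicitly |
| complete_case | — | missing rows dropped |

Engine details:

* **Logistic predictive model** — ML fit on observed rows; each of the m
  imputations draws coefficients from the asymptotic Normal(estimate,
  covariance) posterior and imputes Bernoulli(expit(x'beta*)). One-class
  outcomes or quasi-complete separation (any fitted probability within 1e−8
  of 0/1, or |coefficient| > 15) abort the whole strategy run with a reason
  naming the offending cluster/stratum.
* **Propensity score + ABB** — logistic model of the missingness indicator,
  quantile stratification into 5 strata (collapsed with a warning when there
  are fewer distinct scores), then the approximate Bayesian bootstrap per
  stratum: bootstrap the observed pool to its own size, then draw the
  imputations from the resample. An empty stratum pool is a strategy failure.
  The small-sample "modified ABB" correction is deliberately not implemented
  (`modified_abb` raises).
* **MVN MCMC (data augmentation)** — outcome and covariates treated as
  jointly normal. EM (tolerance 1e−4 per parameter) provides the ML start;
  a single chain then alternates drawing the missing entries from their
  conditional normals and (mu, Sigma) from the Jeffreys-prior posterior
  (Normal–inverse-Wishart). 200 burn-in iterations, then one imputation every
  100 iterations — chain lengths are our choice (unstated in the source
  procedures) and configurable. Continuous imputations are rounded: < 0.5 →
  0, otherwise 1. Degenerate covariances get an escalating diagonal ridge
  (from 1e−10), logged. Same-shaped groups (e.g. the 28 within-cluster
  chains) run as one batch of chains with batched linear algebra; the sampler
  is statistically identical to the per-group chain and is tested against it.
* **Random-intercept logistic (three-step)** — (1) ML fit of the
  random-intercept model on observed rows by adaptive Gauss–Hermite
  quadrature (11 nodes by default; per-cluster modes by damped Newton, joint
  covariance of (beta, sigma_b²) from the numerical observed information);
  (2) a joint Normal posterior draw of (beta, sigma_b²), redrawn (≤100×, then
  clamped) if sigma_b²* < 0; (3) Bernoulli imputation from the simulated
  model. The default draws a *fresh* N(0, sigma_b²*) deviate for every
  missing record (`per_record`), mirroring the published implementation which
  samples inside the per-row loop; the statistically conventional shared
  per-cluster deviate is available as `per_cluster`. Neither is endorsed; the
  default merely reproduces the documented procedure.
* **Fixed-effects logistic** — the logistic predictive engine with cluster
  indicator columns. Cluster indicators absorb the arm term (clusters are
  nested in arms), so arm is dropped from that design; predictions are
  unchanged.

Invariants enforced and tested: observed outcomes pass through every engine
byte-identical in all m copies; imputed values are exactly {0,1}; with
nothing missing every strategy is the identity.

## Analysis and pooling

The treatment effect is the arm coefficient (log odds ratio), adjusted for
the five covariates, from either

* **GEE** — logit link, exchangeable working correlation, robust sandwich
  covariance (statsmodels; moment estimator for the correlation, no
  small-sample correction), or
* **RE logistic** — the same adaptive-quadrature ML fit used by the
  imputation engine.

Per-imputation estimates q_i with variances u_i combine by Rubin's rules:

    Qbar = mean(q),  U = mean(u),  B = var(q),  T = U + (1 + 1/m) B,
    df = (m−1) (1 + U / ((1+1/m) B))²,

with a t(df) interval on the log-OR scale, exponentiated for display. B = 0
falls back to the normal quantile. Only the arm coefficient is pooled.

Agreement between imputations and truth is Cohen's kappa
κ = (p_o − p_e)/(1 − p_e) on the 2×2 table of the true outcomes tiled m
times against the m stacked completed copies. Because observed rows agree by
construction, this all-rows kappa scales roughly like 1 − f; a
missing-rows-only kappa is available via `missing_only=True`. When both
vectors are constant and equal (p_e = 1), κ is defined as 1.

A useful identity for interpreting the kappa benchmarks: if missing values
are imputed by draws from the marginal outcome distribution (which is what
ABB reduces to when the propensity strata carry no outcome signal, as under
MCAR), then p_o = (1−f) + f·p_e and hence κ = 1 − f exactly, for any
prevalence. Informative imputation models raise κ above 1 − f; the
propensity strategies under MCAR therefore sit essentially at that floor,
while the logistic/MCMC/random-intercept strategies gain a small margin from
the covariate and cluster signal.

## Simulation design

Per run: generate a cohort, mask at fraction f under the chosen mechanism,
impute with each strategy (m = 5), score kappa, fit GEE and/or RE per
completed copy, pool. Per cell, run-level results are averaged — mean kappa,
mean pooled log-OR, mean pooled SE — and the displayed CI is rebuilt as
exp(mean log-OR ± 1.96 × mean SE). Averaging is done on the log-OR scale.
Strategy failures are counted and excluded from the averages; a cell with no
successful run is left blank in the emitted tables.

Seeding: a master seed spawns per-(run, purpose, fraction, strategy) child
seeds through `numpy.random.SeedSequence` entropy tuples, so any cell is
reproducible in isolation and the same run index reuses the same cohort
across fractions and strategies.

The desk-scale default is 100 runs per cell (the headline benchmarks in
`scripts/acceptance.py` use exactly that); the full design scales to 1000
runs per cell by setting `n_runs=1000`, with per-cell CSV checkpointing for
resumption.

## Numerical choices and degenerate inputs

* Logistic IRLS: Newton steps damped at norm 50 so separated fits diverge
  detectably but finitely; convergence at step < 1e−10; singular information
  matrices get a 1e−8 ridge.
* Separation thresholds: fitted probability within 1e−8 of {0,1} or
  |coefficient| > 15.
* Propensity models never abort a run on separation: they only rank rows, so
  a separated fit falls back to a ridge-penalised fit (λ = 0.01), and a
  one-class indicator to the constant empirical fraction.
* Posterior-draw covariances are ridge-repaired (diagonal ladder up to 1e−4)
  before Cholesky; an exactly zero covariance is treated as a point mass.
* EM convergence: largest absolute parameter change < 1e−4 (configurable);
  exceeding max iterations raises with the last delta.
* Quadrature fit: BFGS on (beta, log sigma) with warm-started inner Newton;
  boundary estimates (sigma_b² < 1e−5) are flagged and their variance row is
  zeroed rather than inverted.

## Behaviour under the default synthetic conditions

Within-cluster logistic imputation is fragile by design of the comparison:
with diabetes/heart-disease prevalences of 0.2, a 55-patient cluster contains
~11 patients per comorbidity subgroup, and the chance that some cluster's
observed subgroup is all-one-outcome is substantial even at 5% missingness.
Under the separation rule above this aborts the strategy run, so
`within_cluster:logistic` fails in most runs at every missing fraction here
— a sharper version of the failures that motivate reporting blank cells for
this strategy at high missingness. The other eight strategies essentially
never fail at f ≤ 0.5 with 55-patient clusters.

## Known limitations

* MAR-on-previous-responses and MNAR mechanisms are out of scope, as is
  missingness of whole clusters or of covariates.
* The MVN MCMC engine knowingly violates normality for binary columns; the
  rounding rule is known to bias proportions near 0 or 1 (not near 0.55).
* No fully Bayesian logistic imputation: parameter uncertainty uses the
  asymptotic-normal posterior approximation throughout.
* No standardized-bias or CI-coverage metrics; the simulation reports
  agreement (kappa) and averaged effect estimates only.
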