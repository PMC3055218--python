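# crtmi — multiple imputation for missing binary outcomes in cluster randomized trials

In a cluster randomized trial (CRT) whole groups of patients — here, family
practices — are randomized together, so outcomes within a cluster are
correlated. Standard multiple-imputation (MI) procedures for a missing
binary outcome assume independent observations and ignore that correlation;
the consequence is an underestimated variance for the pooled treatment
effect and over-confident confidence intervals.

`crtmi` is a library + CLI for studying this problem end to end. It
provides:

* a **synthetic cohort generator** emulating a community hypertension trial:
  28 clusters (14 per arm) × 55 elderly patients, binary blood-pressure
  control outcome with marginal prevalence 0.55, generated from a
  random-intercept logistic model
  `logit Pr(Y_jl=1|u_j) = x_jl'β + u_j`, `u_j ~ N(0, σ_B²)` with latent-scale
  ICC ρ = σ_B²/(σ_B² + π²/3) = 0.055 and arm odds ratio 1.14;
* **missingness mechanisms** on the outcome: MCAR, and covariate-dependent
  (CD) with odds multipliers 1.2 (male), 1.3 (control arm), 1.4 (baseline
  uncontrolled), calibrated to any overall fraction;
* **ten strategies**: standard MI run per arm (logistic-regression,
  propensity-score/approximate-Bayesian-bootstrap, multivariate-normal MCMC),
  the same three engines run within each cluster, three cluster-aware
  across-cluster strategies (propensity with a cluster covariate, a
  three-step random-intercept logistic procedure, fixed-effects logistic),
  and complete-case analysis — each producing m completed datasets with
  explicit failure accounting for separated/one-class clusters and empty
  resampling strata;
* **analysis & pooling**: GEE with exchangeable working correlation and
  robust covariance, random-intercept logistic regression by adaptive
  Gauss–Hermite quadrature, Rubin's rules
  `T = U + (1 + 1/m)B` with `df = (m−1)(1 + U/((1+1/m)B))²`, and Cohen's
  kappa `κ = (p_o − p_e)/(1 − p_e)` between stacked imputations and truth;
* a **simulation driver** over mechanism × fraction × strategy × model grids
  that averages kappa, log-OR and SE across runs and emits kappa/effect
  tables with blanks where a strategy failed every run.

See `docs/methods.md` for the model, defaults, numerical choices and
limitations.

## Worked example

```python
from crtmi import (CohortConfig, generate_cohort, MissingnessSpec, apply_mask,
                   impute, fit_gee_exchangeable, pool_rubin)
from crtmi.missingness import make_mask
from crtmi.analysis import mi_kappa

cohort = generate_cohort(CohortConfig(), seed=1)          # 1540 patients, 28 clusters
mask = make_mask(cohort.data, MissingnessSpec("MCAR", 0.30), seed=2)
masked = apply_mask(cohort.data, mask)                    # 478 outcomes set missing

mi = impute(masked, "across_cluster:re_logistic", m=5, seed=3)
print(mi_kappa(mi, cohort.outcome).kappa)                 # 0.698

pairs = []
for i in range(5):
    fit = fit_gee_exchangeable(mi.completed(i))
    pairs.append((fit.coef("arm"), fit.var("arm")))
pooled = pool_rubin(pairs)
print(pooled.odds_ratio, pooled.ci_low, pooled.ci_high)   # 1.29 (0.88, 1.91)
print(pooled.U, pooled.B, pooled.T, pooled.df)            # 0.0237 0.0104 0.0362 33.6
```

Reading the numbers: with 30% of outcomes missing MCAR, the stacked
imputed-vs-true agreement is κ ≈ 0.70 (≈ 1 − f, since observed rows agree by
construction); the pooled arm odds ratio 1.29 (95% CI 0.88–1.91) is one
run's estimate of the generating OR 1.14, with total variance T split into
within- (U) and between-imputation (B) components.

The same pipeline from the shell:

```bash
crtmi generate --seed 1 --out cohort.csv
crtmi mask cohort.csv --mechanism mcar --fraction 0.3 --seed 2 --out masked.csv
crtmi impute masked.csv --strategy across_cluster:re_logistic -m 5 --seed 3 --out imputed.csv
crtmi analyze imputed.csv --model gee
crtmi simulate --mechanisms MCAR --fractions 0.05,0.30 --runs 100 --seed 1 --out results/
```

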