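"""Analysis models, Rubin's pooling and agreement scoring.

The treatment effect is the arm coefficient (log odds ratio) from either a
population-averaged GEE logistic model with exchangeable working correlation
and robust (sandwich) covariance, or a cluster-specific random-intercept
logistic regression.  Per-imputation estimates are combined with Rubin's
rules: Qbar = mean estimate, U = mean within-imputation variance, B = sample
variance of the estimates, T = U + (1 + 1/m) B, with the classic
Barnard-Rubin-style degrees of freedom df = (m-1)(1 + U/((1+1/m)B))^2.
Agreement between imputed and true outcomes is scored with Cohen's kappa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

from . import engines
from ._errors import ConvergenceError, ValidationError
from .cohort import COVARIATES
from .strategies import _design

logger = logging.getLogger(__name__)

ANALYSIS_COVARIATES = COVARIATES  # arm is added separately


@dataclass
class FitResult:
    """A fitted analysis model reduced to what pooling needs."""

    params: np.ndarray
    cov: np.ndarray
    names: list
    model: str  # "GEE" or "RE"
    converged: bool = True
    sigma_b2: float | None = None
    boundary: bool = False

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def var(self, name: str) -> float:
        i = self.names.index(name)
        return float(self.cov[i, i])


def _analysis_design(data: pd.DataFrame):
    X, names = _design(data, ANALYSIS_COVARIATES, float(data["age"].mean()), add_arm=True)
    return X, names


def fit_gee_exchangeable(
    data: pd.DataFrame,
    outcome: str = "outcome",
    cluster_col: str = "cluster_id",
) -> FitResult:
    """Logit-link GEE with exchangeable working correlation and sandwich
    covariance (statsmodels), adjusting for arm and the five covariates."""
    groups = data[cluster_col].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValidationError("fit_gee_exchangeable requires >= 2 clusters")
    X, names = _analysis_design(data)
    y = data[outcome].to_numpy(dtype=float)
    model = sm.GEE(y, X, groups=groups, family=sm.families.Binomial(), cov_struct=sm.cov_struct.Exchangeable())
    try:
        res = model.fit(maxiter=100)
    except Exception as exc:  # statsmodels raises bare exceptions on failure
        raise ConvergenceError(f"GEE fit failed: {exc}") from exc
    if not res.converged:
        raise ConvergenceError("GEE fit did not converge")
    return FitResult(
        params=np.asarray(res.params),
        cov=np.asarray(res.cov_params()),  # robust by default
        names=list(names),
        model="GEE",
        converged=True,
    )


def fit_re_analysis(
    data: pd.DataFrame,
    outcome: str = "outcome",
    cluster_col: str = "cluster_id",
    n_nodes: int = 11,
) -> FitResult:
    """Random-intercept logistic regression on a completed (or complete-case)
    dataset; shares the adaptive-quadrature ML implementation with the
    imputation engine."""
    X, names = _analysis_design(data)
    fit = engines.fit_re_logistic(
        X, data[outcome].to_numpy(dtype=float), data[cluster_col].to_numpy(), n_nodes=n_nodes, names=names
    )
    return FitResult(
        params=fit.params,
        cov=fit.cov[: len(fit.params), : len(fit.params)],
        names=list(names),
        model="RE",
        converged=fit.converged,
        sigma_b2=fit.sigma_b2,
        boundary=fit.boundary,
    )


@dataclass
class PooledEstimate:
    """Rubin-combined log odds ratio with its variance decomposition."""

    qbar: float
    U: float
    B: float
    T: float
    df: float
    m: int
    odds_ratio: float
    ci_low: float
    ci_high: float

    @property
    def se(self) -> float:
        return float(np.sqrt(self.T))


def pool_rubin(estimates, variances=None, alpha: float = 0.05) -> PooledEstimate:
    """Combine per-imputation (estimate, variance) pairs by Rubin's rules.

    ``estimates`` may be a list of (q, u) pairs or a list of estimates with
    ``variances`` given separately.  B = 0 (identical estimates) falls back to
    a normal quantile with infinite df.
    """
    if variances is None:
        pairs = list(estimates)
        q = np.array([p[0] for p in pairs], dtype=float)
        u = np.array([p[1] for p in pairs], dtype=float)
    else:
        q = np.asarray(list(estimates), dtype=float)
        u = np.asarray(list(variances), dtype=float)
    m = len(q)
    if m < 2:
        raise ValidationError(f"pooling requires m >= 2 successful fits, got {m}")
    qbar = float(q.mean())
    U = float(u.mean())
    B = float(q.var(ddof=1))
    T = U + (1.0 + 1.0 / m) * B
    if B == 0.0:
        logger.info("between-imputation variance is zero; using the normal quantile")
        df = np.inf
        quant = stats.norm.ppf(1 - alpha / 2)
    else:
        df = (m - 1) * (1.0 + U / ((1.0 + 1.0 / m) * B)) ** 2
        quant = stats.t.ppf(1 - alpha / 2, df)
    half = quant * np.sqrt(T)
    return PooledEstimate(
        qbar=qbar,
        U=U,
        B=B,
        T=T,
        df=float(df),
        m=m,
        odds_ratio=float(np.exp(qbar)),
        ci_low=float(np.exp(qbar - half)),
        ci_high=float(np.exp(qbar + half)),
    )


@dataclass
class KappaResult:
    """Cohen's kappa from a 2x2 agreement table."""

    kappa: float
    p_observed: float
    p_expected: float
    n: int


def cohens_kappa(truth, imputed) -> KappaResult:
    """Chance-corrected agreement between two equal-length binary vectors.

    For the stacked multiple-imputation comparison, pass the true outcomes
    tiled m times against the m completed copies concatenated.  When both
    vectors are constant and equal (p_e = 1) kappa is defined as 1.
    """
    a = np.asarray(truth).astype(int)
    b = np.asarray(imputed).astype(int)
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.shape} vs {b.shape}")
    n = len(a)
    if n == 0:
        raise ValidationError("empty vectors")
    p_o = float(np.mean(a == b))
    pa1, pb1 = float(np.mean(a)), float(np.mean(b))
    p_e = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if p_e >= 1.0:
        logger.info("degenerate agreement table (p_e = 1); kappa defined as 1")
        return KappaResult(kappa=1.0, p_observed=p_o, p_expected=1.0, n=n)
    return KappaResult(kappa=(p_o - p_e) / (1.0 - p_e), p_observed=p_o, p_expected=p_e, n=n)


def mi_kappa(mi_data, truth: np.ndarray, missing_only: bool = False) -> KappaResult:
    """Kappa of a MultiplyImputedData object against the true outcomes,
    stacking all m completed copies (the default compares all rows, where
    observed rows agree by construction; ``missing_only`` restricts to the
    imputed rows)."""
    if mi_data.failed:
        raise RuntimeError(f"strategy {mi_data.strategy} failed: {mi_data.failure_reason}")
    truth = np.asarray(truth).astype(int)
    mask = mi_data.base["missing"].to_numpy() == 1
    if missing_only:
        stacked_truth = np.tile(truth[mask], len(mi_data.outcomes))
        stacked_imp = np.concatenate([np.asarray(o)[mask] for o in mi_data.outcomes])
    else:
        stacked_truth = np.tile(truth, len(mi_data.outcomes))
        stacked_imp = mi_data.stacked_outcomes()
    return cohens_kappa(stacked_truth, stacked_imp)


def estimate_icc(refit) -> float:
    """Latent-scale ICC from a fitted random-intercept logistic model;
    boundary fits (sigma_b2 at 0) return 0."""
    s2 = refit.sigma_b2 if hasattr(refit, "sigma_b2") else float(refit)
    if s2 is None:
        raise ValidationError("fit carries no between-cluster variance")
    if getattr(refit, "boundary", False) or s2 <= 0:
        return 0.0
    return s2 / (s2 + np.pi**2 / 3.0)
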