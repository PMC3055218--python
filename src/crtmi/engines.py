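"""Core imputation primitives.

Four engine families, each a pure function over numpy arrays with explicit
seeding:

* logistic predictive model: ML fit on observed rows, one draw from the
  asymptotic-normal posterior of the coefficients, Bernoulli imputation from
  the simulated model;
* propensity-score method: logistic model of the missingness indicator,
  quantile stratification, approximate Bayesian bootstrap (ABB) within strata;
* multivariate-normal MCMC (data augmentation): EM to the ML start, then a
  single chain alternating imputation (I) and posterior (P) steps under a
  Jeffreys prior, with final continuous outcome draws rounded at 0.5;
* random-intercept logistic model: ML by adaptive Gauss-Hermite quadrature
  over the cluster effect, posterior draws of (beta, sigma_b2), Bernoulli
  imputation with fresh (or per-cluster) normal deviates.

The tiny per-cluster logistic fits use a hand-written Newton/IRLS solver for
speed; it is cross-checked against statsmodels in the test suite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from ._errors import (
    ConvergenceError,
    NumericalError,
    SeparationError,
    EmptyStratumError,
    ValidationError,
)

logger = logging.getLogger(__name__)

# Quasi-separation thresholds: a fitted probability numerically at 0/1 on
# observed data, or a diverging coefficient, marks the fit as separated.
_PROB_EPS = 1e-8
_COEF_LIMIT = 15.0


# ---------------------------------------------------------------------------
# Logistic predictive model
# ---------------------------------------------------------------------------


@dataclass
class LogisticFit:
    params: np.ndarray
    cov: np.ndarray
    converged: bool
    separated: bool
    names: list = field(default_factory=list)


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    names=None,
    stratum=None,
    ridge: float = 0.0,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by Newton/IRLS.

    Raises SeparationError (carrying ``stratum``) when the outcome is
    one-class; flags quasi-complete separation via fitted probabilities at the
    numerical boundary or runaway coefficients.  An optional L2 ``ridge``
    penalty (excluded from the separation diagnostics) stabilises degenerate
    designs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValidationError("X must be 2-D with one row per element of y")
    if len(y) == 0:
        raise SeparationError(f"no observed outcomes in stratum {stratum!r}", stratum=stratum)
    if np.all(y == y[0]):
        raise SeparationError(
            f"all observed outcomes are {int(y[0])} in stratum {stratum!r} (one-class)",
            stratum=stratum,
        )

    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - ridge * beta
        hess = (X * w[:, None]).T @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            hess = hess + 1e-8 * np.eye(p)
            step = np.linalg.solve(hess, grad)
        # Dampen huge steps to keep divergence detectable but finite.
        norm = np.linalg.norm(step)
        if norm > 50.0:
            step *= 50.0 / norm
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    mu = expit(X @ beta)
    separated = bool(np.any(mu < _PROB_EPS) or np.any(mu > 1 - _PROB_EPS) or np.any(np.abs(beta) > _COEF_LIMIT))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = (X * w[:, None]).T @ X + ridge * np.eye(p)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    if names is None:
        names = [f"x{i}" for i in range(p)]
    return LogisticFit(params=beta, cov=cov, converged=converged, separated=separated, names=list(names))


def _ridge_repair_cholesky(cov: np.ndarray) -> np.ndarray:
    """Cholesky factor of a covariance, adding an escalating diagonal ridge."""
    cov = np.asarray(cov, dtype=float)
    cov = 0.5 * (cov + cov.T)
    if not cov.any():  # degenerate: a point mass at the estimate
        return np.zeros_like(cov)
    for ridge in (0.0, 1e-10, 1e-8, 1e-6, 1e-4):
        try:
            return np.linalg.cholesky(cov + ridge * np.eye(len(cov)))
        except np.linalg.LinAlgError:
            continue
    raise NumericalError("covariance not positive definite after ridge repair")


def draw_posterior_params(fit, rng: np.random.Generator):
    """One draw from the asymptotic Normal(point estimate, covariance)
    posterior of a LogisticFit or REFit.

    For an REFit the draw covers (beta, sigma_b2) jointly; negative sigma_b2
    draws are rejected and redrawn (up to 100 times, then clamped at 0).
    """
    if isinstance(fit, REFit):
        mean = np.concatenate([fit.params, [fit.sigma_b2]])
        L = _ridge_repair_cholesky(fit.cov)
        for _ in range(100):
            draw = mean + L @ rng.standard_normal(len(mean))
            if draw[-1] >= 0:
                return draw[:-1], float(draw[-1])
        logger.warning("sigma_b2 posterior draw clamped at 0 after 100 rejections")
        return draw[:-1], 0.0
    if not fit.converged:
        raise ConvergenceError("cannot draw posterior parameters from an unconverged fit")
    L = _ridge_repair_cholesky(fit.cov)
    return fit.params + L @ rng.standard_normal(len(fit.params))


def impute_from_logistic(beta: np.ndarray, X_mis: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli(expit(x'beta)) draws for the missing rows."""
    X_mis = np.asarray(X_mis, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if X_mis.shape[1] != len(beta):
        raise ValidationError(f"design has {X_mis.shape[1]} columns but beta has {len(beta)}")
    p = expit(X_mis @ beta)
    return (rng.random(len(X_mis)) < p).astype(int)


# ---------------------------------------------------------------------------
# Propensity score + approximate Bayesian bootstrap
# ---------------------------------------------------------------------------


def compute_propensity(
    X: np.ndarray,
    missing: np.ndarray,
    ridge_fallback: float = 1e-2,
) -> np.ndarray:
    """Fitted probabilities of being missing from a logistic model.

    The propensity model only ranks observations for stratification, so a
    separated or one-class fit falls back to a ridge-penalised fit (or the
    constant empirical fraction when the indicator is one-class).
    """
    missing = np.asarray(missing, dtype=float)
    try:
        fit = fit_logistic(X, missing)
        if fit.separated or not fit.converged:
            fit = fit_logistic(X, missing, ridge=ridge_fallback)
    except SeparationError:
        return np.full(len(missing), float(missing.mean()))
    return np.asarray(expit(np.asarray(X, dtype=float) @ fit.params))


def stratify_propensity(propensities: np.ndarray, n_strata: int = 5) -> np.ndarray:
    """Quantile strata of near-equal size; ties broken by stable row order.

    Collapses (with a warning) when there are fewer distinct propensity values
    than requested strata.
    """
    if n_strata < 1:
        raise ValidationError(f"n_strata must be >= 1, got {n_strata}")
    propensities = np.asarray(propensities, dtype=float)
    n = len(propensities)
    n_distinct = len(np.unique(propensities))
    if n_distinct < n_strata:
        warnings.warn(
            f"only {n_distinct} distinct propensity values; collapsing to {n_distinct} strata",
            stacklevel=2,
        )
        _, labels = np.unique(propensities, return_inverse=True)
        return labels
    order = np.argsort(propensities, kind="stable")
    labels = np.empty(n, dtype=int)
    # Near-equal contiguous chunks of the sorted order.
    bounds = np.linspace(0, n, n_strata + 1).round().astype(int)
    for s in range(n_strata):
        labels[order[bounds[s] : bounds[s + 1]]] = s
    return labels


def abb_draw(pool: np.ndarray, n_missing: int, rng: np.random.Generator, stratum=None) -> np.ndarray:
    """Approximate Bayesian bootstrap: resample the observed pool to its own
    size with replacement, then draw the imputations with replacement from
    that resample."""
    pool = np.asarray(pool)
    if len(pool) == 0:
        raise EmptyStratumError(f"no observed outcomes to resample in stratum {stratum!r}", stratum=stratum)
    stage1 = pool[rng.integers(0, len(pool), size=len(pool))]
    return stage1[rng.integers(0, len(pool), size=n_missing)]


# ---------------------------------------------------------------------------
# Multivariate-normal EM + MCMC (data augmentation)
# ---------------------------------------------------------------------------


@dataclass
class MVNState:
    """State of the normal data-augmentation chain.

    ``data`` holds the current completed matrix (missing entries filled with
    the running imputations); ``miss`` marks the originally missing cells.
    """

    mean: np.ndarray
    cov: np.ndarray
    data: np.ndarray
    miss: np.ndarray
    iteration: int = 0
    em_converged: bool = False
    em_iterations: int = 0


def _patterns(miss: np.ndarray):
    """Group row indices by missingness pattern."""
    if not miss.any():
        return []
    uniq, inverse = np.unique(miss, axis=0, return_inverse=True)
    groups = []
    for k, pat in enumerate(uniq):
        if pat.any():
            groups.append((pat.astype(bool), np.where(inverse == k)[0]))
    return groups


def em_mvn(data: np.ndarray, tol: float = 1e-4, max_iter: int = 500) -> MVNState:
    """EM for the mean and covariance of a multivariate normal with missing
    entries (NaN).  Iterates until the largest absolute change in any
    parameter is below ``tol``."""
    data = np.asarray(data, dtype=float)
    miss = np.isnan(data)
    if miss.all(axis=0).any():
        raise ValidationError("a column is entirely missing")
    n, p = data.shape

    filled = data.copy()
    col_means = np.nanmean(data, axis=0)
    for j in range(p):
        filled[miss[:, j], j] = col_means[j]
    mean = filled.mean(axis=0)
    cov = np.atleast_2d(np.cov(filled, rowvar=False, bias=True))
    groups = _patterns(miss)

    if not groups:
        return MVNState(mean=mean, cov=cov, data=filled, miss=miss, em_converged=True, em_iterations=0)

    last_delta = np.inf
    for it in range(1, max_iter + 1):
        ex = data.copy()
        extra = np.zeros((p, p))
        for pat, idx in groups:
            obs = ~pat
            S_oo = cov[np.ix_(obs, obs)]
            S_mo = cov[np.ix_(pat, obs)]
            solve = np.linalg.solve(S_oo + 1e-12 * np.eye(obs.sum()), S_mo.T).T
            cond_mean = mean[pat] + (data[np.ix_(idx, obs)] - mean[obs]) @ solve.T
            ex[np.ix_(idx, pat)] = cond_mean
            cond_cov = cov[np.ix_(pat, pat)] - solve @ S_mo.T
            extra[np.ix_(pat, pat)] += len(idx) * cond_cov
        new_mean = ex.mean(axis=0)
        centered = ex - new_mean
        new_cov = (centered.T @ centered + extra) / n
        last_delta = max(np.max(np.abs(new_mean - mean)), np.max(np.abs(new_cov - cov)))
        mean, cov = new_mean, new_cov
        if last_delta < tol:
            return MVNState(mean=mean, cov=cov, data=ex, miss=miss, em_converged=True, em_iterations=it)
    raise ConvergenceError(f"EM did not converge in {max_iter} iterations (last delta {last_delta:.3g})")


def round_binary(x: np.ndarray) -> np.ndarray:
    """Rounding rule for continuous imputations of a binary variable:
    values below 0.5 become 0, values at or above 0.5 become 1."""
    return (np.asarray(x, dtype=float) >= 0.5).astype(float)


def _draw_inverse_wishart(df: int, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sigma ~ InvWishart(df, scale) via the Bartlett decomposition."""
    p = len(scale)
    scale = 0.5 * (scale + scale.T)
    try:
        L_inv = np.linalg.cholesky(np.linalg.inv(scale + 1e-10 * np.eye(p)))
    except np.linalg.LinAlgError:
        logger.info("ridge repair of MVN scale matrix during chain")
        L_inv = np.linalg.cholesky(np.linalg.inv(scale + 1e-6 * np.eye(p)))
    T = np.zeros((p, p))
    diag = np.sqrt(rng.chisquare(df - np.arange(p)))
    T[np.diag_indices(p)] = diag
    T[np.tril_indices(p, -1)] = rng.standard_normal(p * (p - 1) // 2)
    W_chol = L_inv @ T  # W = W_chol W_chol' ~ Wishart(df, scale^{-1})
    W = W_chol @ W_chol.T
    return np.linalg.inv(W + 1e-12 * np.eye(p))


def _chain_step(state: MVNState, rng: np.random.Generator) -> None:
    """One I-step (draw missing entries) + P-step (draw mean/cov under the
    Jeffreys prior) of the data-augmentation chain; mutates state in place."""
    data, miss, mean, cov = state.data, state.miss, state.mean, state.cov
    n, p = data.shape
    for pat, idx in state._groups:
        obs = ~pat
        S_oo = cov[np.ix_(obs, obs)]
        S_mo = cov[np.ix_(pat, obs)]
        solve = np.linalg.solve(S_oo + 1e-12 * np.eye(obs.sum()), S_mo.T).T
        cond_mean = mean[pat] + (data[np.ix_(idx, obs)] - mean[obs]) @ solve.T
        cond_cov = cov[np.ix_(pat, pat)] - solve @ S_mo.T
        L = _ridge_repair_cholesky(cond_cov)
        draws = cond_mean + rng.standard_normal((len(idx), pat.sum())) @ L.T
        data[np.ix_(idx, pat)] = draws
    xbar = data.mean(axis=0)
    centered = data - xbar
    A = centered.T @ centered
    new_cov = _draw_inverse_wishart(n - 1, A, rng)
    L = _ridge_repair_cholesky(new_cov / n)
    state.mean = xbar + L @ rng.standard_normal(p)
    state.cov = new_cov
    state.iteration += 1


def mcmc_impute(
    state: MVNState,
    n_iterations: int,
    rng: np.random.Generator,
    outcome_col: int = 0,
) -> np.ndarray:
    """Advance the single data-augmentation chain ``n_iterations`` steps and
    return the full outcome column with the current continuous imputations
    rounded (< 0.5 -> 0, otherwise 1).

    Successive calls continue the same chain, so m imputations spaced by k
    iterations come from one chain as m calls with ``n_iterations=k``.
    """
    if not hasattr(state, "_groups"):
        state._groups = _patterns(state.miss)
    if not state.miss.any():
        return state.data[:, outcome_col].copy()
    for _ in range(n_iterations):
        _chain_step(state, rng)
    out = state.data[:, outcome_col].copy()
    mis = state.miss[:, outcome_col]
    out[mis] = round_binary(out[mis])
    return out


class BatchedMVNChain:
    """Data-augmentation chains for several same-shaped groups at once.

    Each group is an (n, p) matrix whose first column (the 0/1 outcome,
    treated as continuous) may contain NaN; all groups share n and p, so the
    per-iteration conditional draws and Jeffreys-posterior parameter draws
    run as batched linear algebra over the group axis.  Statistically each
    group's chain is identical to running :func:`mcmc_impute` on it alone.
    """

    def __init__(self, matrices, states):
        self.X = np.stack([s.data for s in states])  # (G, n, p)
        self.miss = np.stack([np.isnan(m[:, 0]) for m in matrices])  # (G, n)
        self.mean = np.stack([s.mean for s in states])
        self.cov = np.stack([s.cov for s in states])
        G, n, p = self.X.shape
        if n - 1 <= p - 1:
            raise ValidationError("too few rows per group for the inverse-Wishart draw")
        self.G, self.n, self.p = G, n, p

    def advance(self, n_iterations: int, rng: np.random.Generator) -> None:
        G, n, p = self.G, self.n, self.p
        eye = 1e-10 * np.eye(p)
        for _ in range(n_iterations):
            # I-step: outcome | covariates is univariate normal per group.
            S_oo = self.cov[:, 1:, 1:]
            S_yo = self.cov[:, 0, 1:]
            beta = np.linalg.solve(S_oo + eye[1:, 1:], S_yo[:, :, None])[:, :, 0]  # (G, p-1)
            cond_var = np.clip(self.cov[:, 0, 0] - np.einsum("gj,gj->g", S_yo, beta), 1e-12, None)
            cond_mean = self.mean[:, 0, None] + np.einsum(
                "gnj,gj->gn", self.X[:, :, 1:] - self.mean[:, None, 1:], beta
            )
            draws = cond_mean + np.sqrt(cond_var)[:, None] * rng.standard_normal((G, n))
            self.X[:, :, 0] = np.where(self.miss, draws, self.X[:, :, 0])

            # P-step: Sigma ~ InvWishart(n-1, A), mu ~ N(xbar, Sigma/n).
            xbar = self.X.mean(axis=1)
            C = self.X - xbar[:, None, :]
            A = np.einsum("gni,gnj->gij", C, C)
            L_A = np.linalg.cholesky(A + 1e-8 * np.eye(p))
            F = np.linalg.inv(L_A).transpose(0, 2, 1)  # F F' = A^{-1}
            T = np.zeros((G, p, p))
            idx = np.arange(p)
            T[:, idx, idx] = np.sqrt(rng.chisquare((n - 1) - idx, size=(G, p)))
            tril = np.tril_indices(p, -1)
            T[:, tril[0], tril[1]] = rng.standard_normal((G, p * (p - 1) // 2))
            M = F @ T  # W = M M' ~ Wishart(n-1, A^{-1})
            self.cov = np.linalg.inv(M @ M.transpose(0, 2, 1) + eye)
            L_mu = np.linalg.cholesky(self.cov / n + eye)
            self.mean = xbar + np.einsum("gij,gj->gi", L_mu, rng.standard_normal((G, p)))

    def outcomes(self) -> np.ndarray:
        """Current full outcome columns, imputations rounded at 0.5 -> (G, n)."""
        out = self.X[:, :, 0].copy()
        out[self.miss] = round_binary(out[self.miss])
        return out


# ---------------------------------------------------------------------------
# Random-intercept logistic regression (adaptive Gauss-Hermite ML)
# ---------------------------------------------------------------------------


@dataclass
class REFit:
    params: np.ndarray  # fixed effects
    sigma_b2: float
    cov: np.ndarray  # joint covariance of (beta, sigma_b2)
    n_nodes: int
    converged: bool
    boundary: bool
    loglik: float
    names: list = field(default_factory=list)
    cluster_labels: np.ndarray | None = None


def _cluster_slices(cluster_ids: np.ndarray):
    """Stable ordering of rows by cluster plus reduceat boundaries."""
    order = np.argsort(cluster_ids, kind="stable")
    sorted_ids = cluster_ids[order]
    starts = np.r_[0, np.where(np.diff(sorted_ids) != 0)[0] + 1]
    labels = sorted_ids[starts]
    return order, starts, labels


def _re_loglik_parts(eta0, y, starts, sigma2, nodes, weights, u0=None):
    """Per-cluster marginal log-likelihoods by adaptive Gauss-Hermite.

    eta0/y must be ordered by cluster; starts are reduceat boundaries.
    ``u0`` warm-starts the per-cluster mode search.
    """
    n_clusters = len(starts)
    u = np.zeros(n_clusters) if u0 is None else u0.copy()
    # Mode of the integrand per cluster (concave in u): Newton iterations.
    for _ in range(25):
        mu = expit(eta0 + np.repeat(u, np.diff(np.r_[starts, len(y)])))
        g = np.add.reduceat(y - mu, starts) - u / sigma2
        h = -np.add.reduceat(mu * (1 - mu), starts) - 1.0 / sigma2
        step = g / h
        u = u - step
        if np.max(np.abs(step)) < 1e-9:
            break
    mu = expit(eta0 + np.repeat(u, np.diff(np.r_[starts, len(y)])))
    h = -np.add.reduceat(mu * (1 - mu), starts) - 1.0 / sigma2
    tau = 1.0 / np.sqrt(-h)

    # Adaptive GH: integral = sqrt(2)*tau * sum_k w_k exp(h(u + sqrt2 tau z_k) + z_k^2)
    z = nodes[None, :]
    u_nodes = u[:, None] + np.sqrt(2.0) * tau[:, None] * z  # (clusters, nodes)
    counts = np.diff(np.r_[starts, len(y)])
    eta = eta0[:, None] + np.repeat(u_nodes, counts, axis=0)
    # Bernoulli log-likelihood: y*eta - log(1+exp(eta)), summed within cluster.
    cll = np.add.reduceat(y[:, None] * eta - np.logaddexp(0.0, eta), starts, axis=0)
    log_density = cll - u_nodes**2 / (2 * sigma2) - 0.5 * np.log(2 * np.pi * sigma2)
    log_integrand = log_density + z**2 + np.log(weights)[None, :]
    return np.log(np.sqrt(2.0) * tau) + logsumexp(log_integrand, axis=1), u


def fit_re_logistic(
    X: np.ndarray,
    y: np.ndarray,
    cluster_ids: np.ndarray,
    n_nodes: int = 11,
    names=None,
    start=None,
) -> REFit:
    """ML random-intercept logistic regression via adaptive Gauss-Hermite
    quadrature; covariance of (beta, sigma_b2) from the numerical observed
    information at the optimum."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    cluster_ids = np.asarray(cluster_ids)
    if len(np.unique(cluster_ids)) < 2:
        raise ValidationError("fit_re_logistic requires >= 2 clusters")
    order, starts, labels = _cluster_slices(cluster_ids)
    Xs, ys = X[order], y[order]
    nodes, weights = hermgauss(n_nodes)

    p = X.shape[1]
    if start is None:
        base = fit_logistic(Xs, ys)
        start = np.concatenate([base.params, [np.log(0.4)]])

    u_cache = {"u": None}

    def nll(theta):
        beta, log_sigma = theta[:p], theta[p]
        log_sigma = np.clip(log_sigma, -8.0, 4.0)
        sigma2 = np.exp(2 * log_sigma)
        eta0 = Xs @ beta
        parts, u_cache["u"] = _re_loglik_parts(eta0, ys, starts, sigma2, nodes, weights, u_cache["u"])
        return -float(np.sum(parts))

    res = minimize(nll, start, method="BFGS", options={"gtol": 1e-6, "maxiter": 300})
    converged = bool(res.success or np.max(np.abs(res.jac)) < 1e-3)
    if not converged:
        raise ConvergenceError(f"random-effects logistic fit did not converge: {res.message}")
    beta_hat = res.x[:p]
    sigma2_hat = float(np.exp(2 * np.clip(res.x[p], -8.0, 4.0)))
    boundary = sigma2_hat < 1e-5

    # Observed information in the (beta, sigma_b2) parameterisation.
    def nll_natural(theta):
        beta, s2 = theta[:p], max(theta[p], 1e-10)
        eta0 = Xs @ beta
        parts, u_cache["u"] = _re_loglik_parts(eta0, ys, starts, s2, nodes, weights, u_cache["u"])
        return -float(np.sum(parts))

    theta_hat = np.concatenate([beta_hat, [sigma2_hat]])
    cov = _numeric_covariance(nll_natural, theta_hat, boundary_last=boundary)

    if names is None:
        names = [f"x{i}" for i in range(p)]
    return REFit(
        params=beta_hat,
        sigma_b2=sigma2_hat,
        cov=cov,
        n_nodes=n_nodes,
        converged=converged,
        boundary=boundary,
        loglik=-float(res.fun),
        names=list(names),
        cluster_labels=labels,
    )


def _numeric_covariance(f, x, boundary_last=False, rel_step=1e-4):
    """Inverse of a central-difference Hessian; if the last coordinate sits at
    its boundary its row/column are zeroed (variance unavailable there)."""
    k = len(x)
    hs = rel_step * np.maximum(np.abs(x), 1.0)
    if boundary_last:
        k_eff = k - 1
    else:
        k_eff = k
    H = np.zeros((k_eff, k_eff))
    f0 = f(x)
    for i in range(k_eff):
        for j in range(i, k_eff):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = hs[i]
            ej[j] = hs[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / hs[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * hs[i] * hs[j])
    try:
        cov_eff = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_eff = np.linalg.pinv(H)
    # Repair tiny negative eigenvalues from finite differencing.
    w, V = np.linalg.eigh(0.5 * (cov_eff + cov_eff.T))
    cov_eff = (V * np.clip(w, 1e-12, None)) @ V.T
    if boundary_last:
        cov = np.zeros((k, k))
        cov[:-1, :-1] = cov_eff
        return cov
    return cov_eff


def impute_from_re_model(
    beta: np.ndarray,
    sigma_b2: float,
    X_mis: np.ndarray,
    cluster_ids_mis: np.ndarray,
    rng: np.random.Generator,
    mode: str = "per_record",
) -> np.ndarray:
    """Bernoulli imputation from a simulated random-intercept logistic model.

    mode="per_record" draws a fresh N(0, sigma_b2) deviate for every missing
    record; mode="per_cluster" shares one deviate per cluster.
    """
    if mode not in ("per_record", "per_cluster"):
        raise ValidationError(f"mode must be 'per_record' or 'per_cluster', got {mode!r}")
    X_mis = np.asarray(X_mis, dtype=float)
    cluster_ids_mis = np.asarray(cluster_ids_mis)
    sd = np.sqrt(max(float(sigma_b2), 0.0))
    if mode == "per_record":
        u = rng.normal(0.0, sd, size=len(X_mis))
    else:
        labels, inverse = np.unique(cluster_ids_mis, return_inverse=True)
        u = rng.normal(0.0, sd, size=len(labels))[inverse]
    p = expit(X_mis @ np.asarray(beta, dtype=float) + u)
    return (rng.random(len(X_mis)) < p).astype(int)


def modified_abb(*args, **kwargs):
    """Small-sample corrected ABB; intentionally not implemented."""
    raise NotImplementedError(
        "the modified (small-sample corrected) approximate Bayesian bootstrap is not implemented"
    )
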