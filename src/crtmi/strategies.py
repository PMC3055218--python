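"""The nine named imputation strategies plus complete-case analysis.

Levels:

* ``ignore_cluster`` -- standard MI run separately per treatment arm
  (logistic, propensity/ABB, MCMC), blind to clustering;
* ``within_cluster`` -- the same engines run separately inside every cluster;
* ``across_cluster`` -- clustering modelled explicitly: propensity with the
  cluster indicator among the covariates, the three-step random-intercept
  logistic procedure, or a predictive logistic model with cluster fixed
  effects;
* ``complete_case`` -- no imputation; observed rows only.

Any engine failure in any cluster/stratum (one-class outcomes, quasi-complete
separation, an empty ABB pool, EM non-convergence) marks the whole strategy
run as failed, with a reason naming the offending unit; failed runs are meant
to be excluded from downstream averaging, mirroring how such cells are left
blank in reported simulation tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engines
from ._errors import (
    ConvergenceError,
    EmptyStratumError,
    NumericalError,
    SeparationError,
    ValidationError,
)
from .cohort import COVARIATES

_VALID_COMBOS = {
    ("ignore_cluster", "logistic"),
    ("ignore_cluster", "propensity"),
    ("ignore_cluster", "mcmc"),
    ("within_cluster", "logistic"),
    ("within_cluster", "propensity"),
    ("within_cluster", "mcmc"),
    ("across_cluster", "propensity"),
    ("across_cluster", "re_logistic"),
    ("across_cluster", "fe_logistic"),
    ("complete_case", "none"),
}


@dataclass(frozen=True)
class StrategyID:
    level: str
    method: str

    def __post_init__(self):
        if (self.level, self.method) not in _VALID_COMBOS:
            raise ValidationError(f"invalid strategy combination {self.level}:{self.method}")

    def __str__(self) -> str:
        return f"{self.level}:{self.method}"

    @classmethod
    def parse(cls, text: str) -> "StrategyID":
        level, _, method = text.partition(":")
        return cls(level, method or "none")


def all_strategies(include_complete_case: bool = True) -> list[StrategyID]:
    """The nine imputation strategies (and optionally complete-case), in the
    order they are reported."""
    order = [
        ("within_cluster", "logistic"),
        ("within_cluster", "propensity"),
        ("within_cluster", "mcmc"),
        ("across_cluster", "propensity"),
        ("across_cluster", "re_logistic"),
        ("across_cluster", "fe_logistic"),
        ("ignore_cluster", "logistic"),
        ("ignore_cluster", "propensity"),
        ("ignore_cluster", "mcmc"),
    ]
    out = [StrategyID(*pair) for pair in order]
    if include_complete_case:
        out.append(StrategyID("complete_case", "none"))
    return out


@dataclass
class MultiplyImputedData:
    """m completed copies of a masked cohort plus provenance."""

    strategy: StrategyID
    base: pd.DataFrame  # masked cohort (outcome NaN where missing=1)
    outcomes: list = field(default_factory=list)  # m full outcome arrays
    m: int = 5
    seed: int | None = None
    failed: bool = False
    failure_reason: str | None = None
    failure_stratum: object = None

    def completed(self, i: int) -> pd.DataFrame:
        """The i-th completed dataset (0-based)."""
        if self.failed:
            raise RuntimeError(f"strategy {self.strategy} failed: {self.failure_reason}")
        df = self.base.copy()
        df["outcome"] = np.asarray(self.outcomes[i], dtype=int)
        return df

    def stacked(self) -> pd.DataFrame:
        """All completed copies concatenated with an `_imputation_` column (1..m)."""
        frames = []
        for i in range(len(self.outcomes)):
            df = self.completed(i)
            df["_imputation_"] = i + 1
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def stacked_outcomes(self) -> np.ndarray:
        return np.concatenate([np.asarray(o) for o in self.outcomes])


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


def _design(df: pd.DataFrame, covariates, age_center: float, cluster_levels=None, add_arm=False):
    """Intercept + covariates (+ optional arm, + cluster indicators) design.

    Columns constant over the rows of ``df`` are dropped to keep the design
    full rank (e.g. arm within a cluster, an absent comorbidity in a small
    stratum); returns (matrix, names).
    """
    cols = [np.ones(len(df))]
    names = ["intercept"]
    if add_arm:
        cols.append(df["arm"].to_numpy(dtype=float))
        names.append("arm")
    for cov in covariates:
        v = df[cov].to_numpy(dtype=float)
        if cov == "age":
            v = v - age_center
        cols.append(v)
        names.append(cov)
    if cluster_levels is not None:
        cid = df["cluster_id"].to_numpy()
        for level in cluster_levels[1:]:  # first level absorbed by the intercept
            cols.append((cid == level).astype(float))
            names.append(f"cluster_{level}")
    X = np.column_stack(cols)
    keep = [i for i in range(X.shape[1]) if i == 0 or X[:, i].std() > 0]
    return X[:, keep], [names[i] for i in keep]


def _mvn_matrix(df: pd.DataFrame, age_center: float):
    """[outcome, covariates] matrix for the joint-normal engines; constant
    covariate columns are dropped."""
    cols = [df["outcome"].to_numpy(dtype=float)]
    for cov in COVARIATES:
        v = df[cov].to_numpy(dtype=float)
        if cov == "age":
            v = v - age_center
        if v.std() > 0:
            cols.append(v)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Engine drivers (each fills `out[imp][rows]` for one group of rows)
# ---------------------------------------------------------------------------


def _groups(df: pd.DataFrame, level: str):
    """Row-index groups the engines run over, with human-readable labels."""
    if level == "ignore_cluster":
        return [(f"arm={a}", np.flatnonzero(df["arm"].to_numpy() == a)) for a in (1, 0)]
    if level == "within_cluster":
        return [
            (f"cluster={c}", np.flatnonzero(df["cluster_id"].to_numpy() == c))
            for c in sorted(df["cluster_id"].unique())
        ]
    return [("all", np.arange(len(df)))]


def _check_observed(y_obs: np.ndarray, label: str, need_both_classes: bool):
    if len(y_obs) < 2:
        raise SeparationError(f"fewer than 2 observed outcomes in {label}", stratum=label)
    if need_both_classes and len(np.unique(y_obs)) < 2:
        raise SeparationError(
            f"all observed outcomes are {int(y_obs[0])} in {label} (one-class)", stratum=label
        )


def _run_logistic(df, groups, covariates, m, rng, age_center, cluster_levels=None, add_arm=False):
    imputed = [df["outcome"].to_numpy(dtype=float).copy() for _ in range(m)]
    for label, idx in groups:
        sub = df.iloc[idx]
        obs = sub["missing"].to_numpy() == 0
        mis = ~obs
        if not mis.any():
            continue
        X, names = _design(sub, covariates, age_center, cluster_levels, add_arm)
        y_obs = sub.loc[obs, "outcome"].to_numpy(dtype=float)
        _check_observed(y_obs, label, need_both_classes=True)
        fit = engines.fit_logistic(X[obs], y_obs, names=names, stratum=label)
        if fit.separated:
            culprit = _separated_column(fit, label)
            raise SeparationError(
                f"quasi-complete separation in {label} (diverging coefficient on {culprit})",
                stratum=label,
            )
        if not fit.converged:
            raise ConvergenceError(f"logistic fit did not converge in {label}")
        for i in range(m):
            beta_star = engines.draw_posterior_params(fit, rng)
            imputed[i][idx[mis]] = engines.impute_from_logistic(beta_star, X[mis], rng)
    return imputed


def _separated_column(fit: engines.LogisticFit, label: str) -> str:
    j = int(np.argmax(np.abs(fit.params)))
    return fit.names[j] if fit.names else f"column {j}"


def _run_propensity(df, groups, covariates, m, rng, age_center, n_strata, cluster_levels=None):
    imputed = [df["outcome"].to_numpy(dtype=float).copy() for _ in range(m)]
    for label, idx in groups:
        sub = df.iloc[idx]
        missing = sub["missing"].to_numpy()
        if not missing.any():
            continue
        y = sub["outcome"].to_numpy(dtype=float)
        _check_observed(y[missing == 0], label, need_both_classes=False)
        X, _ = _design(sub, covariates, age_center, cluster_levels)
        prop = engines.compute_propensity(X, missing)
        strata = engines.stratify_propensity(prop, n_strata)
        for s in np.unique(strata):
            in_s = strata == s
            mis_s = in_s & (missing == 1)
            if not mis_s.any():
                continue
            pool = y[in_s & (missing == 0)]
            if len(pool) == 0:
                raise EmptyStratumError(
                    f"no observed outcomes in propensity stratum {s} of {label}",
                    stratum=(label, int(s)),
                )
            rows = idx[mis_s]
            for i in range(m):
                imputed[i][rows] = engines.abb_draw(pool, int(mis_s.sum()), rng, stratum=(label, int(s)))
    return imputed


def _run_mcmc(df, groups, m, rng, age_center, burn_in, spacing, em_tol):
    imputed = [df["outcome"].to_numpy(dtype=float).copy() for _ in range(m)]
    # EM start per group, then same-shaped groups share a batched chain.
    prepared = []
    for label, idx in groups:
        sub = df.iloc[idx]
        missing = sub["missing"].to_numpy()
        if not missing.any():
            continue
        _check_observed(sub.loc[missing == 0, "outcome"].to_numpy(), label, need_both_classes=False)
        mat = _mvn_matrix(sub, age_center)
        try:
            state = engines.em_mvn(mat, tol=em_tol)
        except (ConvergenceError, NumericalError) as exc:
            raise ConvergenceError(f"MVN EM failed in {label}: {exc}") from exc
        prepared.append((label, idx, missing == 1, mat, state))

    by_shape = {}
    for item in prepared:
        by_shape.setdefault(item[3].shape, []).append(item)
    for items in by_shape.values():
        chain = engines.BatchedMVNChain([it[3] for it in items], [it[4] for it in items])
        for i in range(m):
            chain.advance(burn_in if i == 0 else spacing, rng)
            cols = chain.outcomes()
            for g, (label, idx, mis_rows, _, _) in enumerate(items):
                imputed[i][idx[mis_rows]] = cols[g][mis_rows]
    return imputed


def _run_re_logistic(df, m, rng, age_center, n_nodes, mode):
    imputed = [df["outcome"].to_numpy(dtype=float).copy() for _ in range(m)]
    missing = df["missing"].to_numpy()
    if not missing.any():
        return imputed
    obs = missing == 0
    X, names = _design(df, COVARIATES, age_center, add_arm=True)
    y_obs = df.loc[obs, "outcome"].to_numpy(dtype=float)
    _check_observed(y_obs, "observed data", need_both_classes=True)
    fit = engines.fit_re_logistic(
        X[obs], y_obs, df.loc[obs, "cluster_id"].to_numpy(), n_nodes=n_nodes, names=names
    )
    mis_idx = np.flatnonzero(missing)
    cluster_mis = df.loc[missing == 1, "cluster_id"].to_numpy()
    for i in range(m):
        beta_star, s2_star = engines.draw_posterior_params(fit, rng)
        imputed[i][mis_idx] = engines.impute_from_re_model(
            beta_star, s2_star, X[mis_idx], cluster_mis, rng, mode=mode
        )
    return imputed


def impute(
    data: pd.DataFrame,
    strategy: StrategyID | str,
    m: int = 5,
    seed: int = 0,
    n_strata: int = 5,
    mcmc_burn_in: int = 200,
    mcmc_spacing: int = 100,
    em_tol: float = 1e-4,
    re_nodes: int = 11,
    re_mode: str = "per_record",
) -> MultiplyImputedData:
    """Produce m completed copies of a masked cohort under one strategy.

    ``data`` must carry a 0/1 ``missing`` column with `outcome` NaN where
    missing=1 (see :func:`crtmi.missingness.apply_mask`).  Observed outcomes
    pass through untouched in every copy.
    """
    if isinstance(strategy, str):
        strategy = StrategyID.parse(strategy)
    if "missing" not in data.columns:
        raise ValidationError("data must carry a 'missing' column; see apply_mask")
    if strategy.level != "complete_case" and m < 2:
        raise ValidationError(f"m must be >= 2, got {m}")

    if strategy.level == "complete_case":
        kept = data[data["missing"] == 0].reset_index(drop=True)
        return MultiplyImputedData(
            strategy=strategy, base=kept, outcomes=[kept["outcome"].to_numpy(dtype=int)], m=1, seed=seed
        )

    rng = np.random.default_rng(seed)
    age_center = float(data["age"].mean())
    groups = _groups(data, strategy.level)
    cluster_levels = sorted(data["cluster_id"].unique())

    try:
        if strategy.method == "logistic":
            outcomes = _run_logistic(data, groups, COVARIATES, m, rng, age_center)
        elif strategy.method == "propensity":
            levels = cluster_levels if strategy.level == "across_cluster" else None
            outcomes = _run_propensity(data, groups, COVARIATES, m, rng, age_center, n_strata, levels)
        elif strategy.method == "mcmc":
            outcomes = _run_mcmc(data, groups, m, rng, age_center, mcmc_burn_in, mcmc_spacing, em_tol)
        elif strategy.method == "re_logistic":
            outcomes = _run_re_logistic(data, m, rng, age_center, re_nodes, re_mode)
        elif strategy.method == "fe_logistic":
            outcomes = _run_logistic(
                data, groups, COVARIATES, m, rng, age_center, cluster_levels=cluster_levels
            )
        else:  # pragma: no cover - guarded by StrategyID validation
            raise ValidationError(f"unknown method {strategy.method!r}")
    except (SeparationError, EmptyStratumError, ConvergenceError, NumericalError) as exc:
        return MultiplyImputedData(
            strategy=strategy,
            base=data,
            outcomes=[],
            m=m,
            seed=seed,
            failed=True,
            failure_reason=str(exc),
            failure_stratum=getattr(exc, "stratum", None),
        )

    return MultiplyImputedData(
        strategy=strategy,
        base=data,
        outcomes=[np.asarray(o, dtype=int) for o in outcomes],
        m=m,
        seed=seed,
    )
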