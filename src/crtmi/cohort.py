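"""Synthetic two-arm clustered cohorts with a random-intercept logistic outcome.

The generator emulates a community hypertension trial: 14 family practices per
arm, 55 elderly patients per practice, a binary end-of-trial blood-pressure
control outcome with marginal prevalence ~0.55 and latent-scale intra-cluster
correlation ~0.055.  The outcome model is

    logit Pr(Y_jl = 1) = x_jl' beta + u_j,   u_j ~ N(0, sigma_b2),

with covariates: treatment arm, diabetes, heart disease, (centered) age,
baseline BP control and sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit

from ._errors import CalibrationError, ValidationError

# Latent-scale residual variance of the logistic distribution.
LOGISTIC_VARIANCE = np.pi**2 / 3.0

#: Coefficient order used throughout the package.
BETA_NAMES = (
    "intercept",
    "arm",
    "diabetes",
    "heart_disease",
    "age",
    "bp_controlled_baseline",
    "sex",
)

#: Covariates available for imputation / analysis models (outcome excluded).
COVARIATES = ("age", "sex", "diabetes", "heart_disease", "bp_controlled_baseline")

# Intercept solved once with calibrate_intercept(target=0.55) under the
# default configuration below (10^6-draw marginal-prevalence root-finding);
# kept as a constant so the default config is self-contained.
DEFAULT_INTERCEPT = -0.47392

#: Slopes of the generative model: arm effect log(1.14) (adjusted OR of the
#: emulated trial); remaining slopes are the trial's model estimates for
#: diabetes, heart disease, age (per year, centered), baseline BP control, sex.
DEFAULT_BETA = {
    "intercept": DEFAULT_INTERCEPT,
    "arm": float(np.log(1.14)),
    "diabetes": -0.04,
    "heart_disease": 0.1224,
    "age": -0.0066,
    "bp_controlled_baseline": 1.1487,
    "sex": 0.0873,
}

#: Between-cluster variance giving a latent-scale ICC of 0.055.
DEFAULT_SIGMA_B2 = 0.1915

DEFAULT_COVARIATE_PARAMS = {
    "age_mean": 75.0,
    "age_sd": 6.0,
    "age_min": 65.0,
    "sex_rate": 0.5,
    "diabetes_rate": 0.2,
    "heart_disease_rate": 0.2,
    "bp_controlled_baseline_rate": 0.5,
}


def icc_from_sigma(sigma_b2: float) -> float:
    """Latent-scale ICC of a random-intercept logistic model.

    rho = sigma_b2 / (sigma_b2 + pi^2/3).
    """
    if sigma_b2 < 0:
        raise ValidationError(f"sigma_b2 must be >= 0, got {sigma_b2}")
    return sigma_b2 / (sigma_b2 + LOGISTIC_VARIANCE)


def sigma_from_icc(icc: float) -> float:
    """Between-cluster variance giving latent-scale ICC ``icc`` (inverse of
    :func:`icc_from_sigma`)."""
    if not 0 <= icc < 1:
        raise ValidationError(f"icc must be in [0, 1), got {icc}")
    return icc * LOGISTIC_VARIANCE / (1.0 - icc)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    beta is on the log-odds scale, ordered as BETA_NAMES; age enters centered
    at the mean of its (truncated-normal) distribution.
    """

    n_clusters_per_arm: int = 14
    cluster_size: int = 55
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    sigma_b2: float = DEFAULT_SIGMA_B2
    covariate_params: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_PARAMS))
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters_per_arm < 1:
            raise ValidationError(f"n_clusters_per_arm must be >= 1, got {self.n_clusters_per_arm}")
        if self.cluster_size < 2:
            raise ValidationError(f"cluster_size must be >= 2, got {self.cluster_size}")
        if self.sigma_b2 < 0:
            raise ValidationError(f"sigma_b2 must be >= 0, got {self.sigma_b2}")
        missing = set(BETA_NAMES) - set(self.beta)
        if missing:
            raise ValidationError(f"beta missing coefficients: {sorted(missing)}")
        cp = {**DEFAULT_COVARIATE_PARAMS, **self.covariate_params}
        for key in ("sex_rate", "diabetes_rate", "heart_disease_rate", "bp_controlled_baseline_rate"):
            if not 0 <= cp[key] <= 1:
                raise ValidationError(f"covariate_params[{key!r}] must be in [0, 1], got {cp[key]}")
        if cp["age_sd"] <= 0:
            raise ValidationError(f"covariate_params['age_sd'] must be > 0, got {cp['age_sd']}")
        object.__setattr__(self, "covariate_params", cp)

    @property
    def n_clusters(self) -> int:
        return 2 * self.n_clusters_per_arm

    @property
    def n_patients(self) -> int:
        return self.n_clusters * self.cluster_size

    @property
    def beta_vector(self) -> np.ndarray:
        return np.array([self.beta[name] for name in BETA_NAMES], dtype=float)

    @property
    def age_center(self) -> float:
        """Mean of the truncated-normal age distribution (centering constant)."""
        cp = self.covariate_params
        a = (cp["age_min"] - cp["age_mean"]) / cp["age_sd"]
        return float(stats.truncnorm.mean(a, np.inf, loc=cp["age_mean"], scale=cp["age_sd"]))

    def with_intercept(self, intercept: float) -> "CohortConfig":
        return replace(self, beta={**self.beta, "intercept": float(intercept)})


@dataclass
class Cohort:
    """A generated cohort: one row per patient plus realized cluster effects."""

    data: pd.DataFrame
    random_intercepts: np.ndarray  # indexed by cluster_id
    config: CohortConfig

    def __len__(self) -> int:
        return len(self.data)

    @property
    def outcome(self) -> np.ndarray:
        return self.data["outcome"].to_numpy()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


COHORT_COLUMNS = [
    "patient_id",
    "cluster_id",
    "arm",
    "age",
    "sex",
    "diabetes",
    "heart_disease",
    "bp_controlled_baseline",
    "outcome",
]


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV; an empty outcome field is parsed as NaN (missing)."""
    df = pd.read_csv(path)
    missing_cols = set(COHORT_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(f"cohort CSV missing columns: {sorted(missing_cols)}")
    return df


def _draw_covariates(n: int, cp: dict, rng: np.random.Generator) -> dict:
    a = (cp["age_min"] - cp["age_mean"]) / cp["age_sd"]
    age = stats.truncnorm.rvs(a, np.inf, loc=cp["age_mean"], scale=cp["age_sd"], size=n, random_state=rng)
    return {
        "age": age,
        "sex": (rng.random(n) < cp["sex_rate"]).astype(int),
        "diabetes": (rng.random(n) < cp["diabetes_rate"]).astype(int),
        "heart_disease": (rng.random(n) < cp["heart_disease_rate"]).astype(int),
        "bp_controlled_baseline": (rng.random(n) < cp["bp_controlled_baseline_rate"]).astype(int),
    }


def _linear_predictor(df: pd.DataFrame, beta: np.ndarray, age_center: float) -> np.ndarray:
    return (
        beta[0]
        + beta[1] * df["arm"].to_numpy()
        + beta[2] * df["diabetes"].to_numpy()
        + beta[3] * df["heart_disease"].to_numpy()
        + beta[4] * (df["age"].to_numpy() - age_center)
        + beta[5] * df["bp_controlled_baseline"].to_numpy()
        + beta[6] * df["sex"].to_numpy()
    )


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate a two-arm clustered cohort under the random-intercept model.

    Clusters 0..k-1 form the intervention arm (arm=1), clusters k..2k-1 the
    control arm. Bit-reproducible for a fixed seed.
    """
    config = config if config is not None else CohortConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    k, size = config.n_clusters_per_arm, config.cluster_size
    n = config.n_patients
    cluster_id = np.repeat(np.arange(2 * k), size)
    arm = (cluster_id < k).astype(int)

    cov = _draw_covariates(n, config.covariate_params, rng)
    u = rng.normal(0.0, np.sqrt(config.sigma_b2), size=2 * k)

    df = pd.DataFrame({"patient_id": np.arange(n), "cluster_id": cluster_id, "arm": arm, **cov})
    eta = _linear_predictor(df, config.beta_vector, config.age_center) + u[cluster_id]
    df["outcome"] = (rng.random(n) < expit(eta)).astype(int)
    df = df[COHORT_COLUMNS]
    return Cohort(data=df, random_intercepts=u, config=config)


def calibrate_intercept(
    config: CohortConfig | None = None,
    target_prevalence: float = 0.55,
    tol: float = 0.005,
    n_sample: int = 1_000_000,
    bracket: tuple = (-8.0, 8.0),
    seed: int = 20110218,
) -> float:
    """Solve for the intercept giving a marginal outcome prevalence of
    ``target_prevalence``.

    Draws one large fixed Monte-Carlo sample of the non-intercept part of the
    linear predictor (covariates + cluster effect) and root-finds the intercept
    on the resulting smooth deterministic prevalence curve.
    """
    config = config if config is not None else CohortConfig()
    if not 0 < target_prevalence < 1:
        raise ValidationError(f"target_prevalence must be in (0, 1), got {target_prevalence}")

    rng = np.random.default_rng(seed)
    cov = _draw_covariates(n_sample, config.covariate_params, rng)
    beta = config.beta_vector
    df = pd.DataFrame(cov)
    # Patients split evenly between arms marginally.
    df["arm"] = (rng.random(n_sample) < 0.5).astype(int)
    z = _linear_predictor(df, np.concatenate([[0.0], beta[1:]]), config.age_center)
    z = z + rng.normal(0.0, np.sqrt(config.sigma_b2), size=n_sample)

    def gap(b0: float) -> float:
        return float(np.mean(expit(b0 + z))) - target_prevalence

    lo, hi = bracket
    if gap(lo) > 0 or gap(hi) < 0:
        raise CalibrationError(
            f"target prevalence {target_prevalence} not attainable for intercept in [{lo}, {hi}]"
        )
    b0 = brentq(gap, lo, hi, xtol=1e-6, maxiter=200)
    if abs(gap(b0)) > tol:
        raise CalibrationError(f"calibration residual {gap(b0):.4g} exceeds tolerance {tol}")
    return float(b0)
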