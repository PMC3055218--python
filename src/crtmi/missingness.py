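"""Impose MCAR or covariate-dependent (CD) missingness on the outcome column.

Under CD missing, male patients, control-arm patients and patients whose BP was
uncontrolled at baseline are respectively 1.2, 1.3 and 1.4 times more likely to
have a missing outcome; the multipliers act on the odds of missingness inside a
logistic model whose intercept is solved so the expected overall missing
fraction equals the target f.  A risk-multiplier variant is available via
``interpretation="risk"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from ._errors import CalibrationError, ValidationError

DEFAULT_CD_MULTIPLIERS = {"male": 1.2, "control_arm": 1.3, "baseline_uncontrolled": 1.4}

#: Missing fractions studied in the simulation design.
STANDARD_FRACTIONS = (0.05, 0.10, 0.15, 0.20, 0.30, 0.50)


@dataclass(frozen=True)
class MissingnessSpec:
    """Mechanism and target overall missing fraction for the outcome."""

    mechanism: str = "MCAR"  # "MCAR" or "CD"
    fraction: float = 0.30
    cd_multipliers: dict = field(default_factory=lambda: dict(DEFAULT_CD_MULTIPLIERS))
    interpretation: str = "odds"  # "odds" or "risk" reading of the multipliers
    seed: int = 0

    def __post_init__(self):
        if self.mechanism not in ("MCAR", "CD"):
            raise ValidationError(f"mechanism must be 'MCAR' or 'CD', got {self.mechanism!r}")
        if not 0 < self.fraction < 1:
            raise ValidationError(f"fraction must be in (0, 1), got {self.fraction}")
        if any(v <= 0 for v in self.cd_multipliers.values()):
            raise ValidationError("cd_multipliers must be positive")
        if self.interpretation not in ("odds", "risk"):
            raise ValidationError(f"interpretation must be 'odds' or 'risk', got {self.interpretation!r}")


def apply_mcar(data: pd.DataFrame, f: float, seed=0) -> np.ndarray:
    """i.i.d. Bernoulli(f) mask on the outcome, independent of all columns."""
    if not 0 < f < 1:
        raise ValidationError(f"f must be in (0, 1), got {f}")
    rng = np.random.default_rng(seed)
    return rng.random(len(data)) < f


def _cd_log_odds_offsets(data: pd.DataFrame, multipliers: dict) -> np.ndarray:
    male = data["sex"].to_numpy()
    control = 1 - data["arm"].to_numpy()
    uncontrolled = 1 - data["bp_controlled_baseline"].to_numpy()
    return (
        np.log(multipliers["male"]) * male
        + np.log(multipliers["control_arm"]) * control
        + np.log(multipliers["baseline_uncontrolled"]) * uncontrolled
    )


def cd_probabilities(data: pd.DataFrame, spec: MissingnessSpec) -> np.ndarray:
    """Per-patient covariate-dependent missingness probabilities, calibrated so
    their mean equals spec.fraction."""
    f = spec.fraction
    offsets = _cd_log_odds_offsets(data, spec.cd_multipliers)

    if spec.interpretation == "odds":

        def gap(c):
            return float(np.mean(expit(c + offsets))) - f

        lo, hi = logit(f) - 5.0, logit(f) + 5.0
        if gap(lo) > 0 or gap(hi) < 0:
            raise CalibrationError("CD intercept root-finding failed: target fraction out of range")
        c = brentq(gap, lo, hi, xtol=1e-10, maxiter=200)
        p = expit(c + offsets)
    else:  # risk multipliers, capped at 1
        mult = np.exp(offsets)

        def gap(base):
            return float(np.mean(np.minimum(base * mult, 1.0))) - f

        if gap(0.0) > 0 or gap(1.0) < 0:
            raise CalibrationError("CD base-risk root-finding failed: target fraction out of range")
        base = brentq(gap, 0.0, 1.0, xtol=1e-10, maxiter=200)
        p = np.minimum(base * mult, 1.0)
    return np.asarray(p)


def apply_cd(data: pd.DataFrame, spec: MissingnessSpec, seed=None) -> np.ndarray:
    """Covariate-dependent mask: logistic in male / control-arm / baseline-
    uncontrolled status, independent of the outcome given those covariates."""
    if spec.mechanism != "CD":
        raise ValidationError(f"spec.mechanism must be 'CD', got {spec.mechanism!r}")
    p = cd_probabilities(data, spec)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    return rng.random(len(data)) < p


def make_mask(data: pd.DataFrame, spec: MissingnessSpec, seed=None) -> np.ndarray:
    """Dispatch on spec.mechanism."""
    if spec.mechanism == "MCAR":
        return apply_mcar(data, spec.fraction, spec.seed if seed is None else seed)
    return apply_cd(data, spec, seed)


def apply_mask(data: pd.DataFrame, mask: np.ndarray) -> pd.DataFrame:
    """Return a copy with `outcome` set to NaN where masked and a 0/1
    `missing` column appended."""
    mask = np.asarray(mask, dtype=bool)
    if len(mask) != len(data):
        raise ValidationError(f"mask length {len(mask)} != cohort size {len(data)}")
    out = data.copy()
    out["outcome"] = out["outcome"].astype(float)
    out.loc[mask, "outcome"] = np.nan
    out["missing"] = mask.astype(int)
    return out
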