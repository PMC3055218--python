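"""Shared fixtures.

The heavyweight Monte-Carlo evaluations (the MCAR kappa grid, the pooled-SE
ordering cells, the GEE/RE agreement cell and the complete-data recovery
replicates) are computed once per session and shared across tests.
"""

import numpy as np
import pytest

from crtmi.analysis import estimate_icc, fit_gee_exchangeable, fit_re_analysis
from crtmi.cohort import CohortConfig, generate_cohort
from crtmi.missingness import MissingnessSpec, apply_mask, make_mask
from crtmi.sim import run_cell

SESSION_SEED = 20110218  # fixed master seed for the session-level Monte Carlo


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig()


@pytest.fixture()
def small_config():
    return CohortConfig(n_clusters_per_arm=4, cluster_size=25)


@pytest.fixture()
def masked_cohort(default_config):
    """One default cohort with 30% MCAR missingness."""
    cohort = generate_cohort(default_config, seed=123)
    mask = make_mask(cohort.data, MissingnessSpec("MCAR", 0.30), seed=456)
    return cohort, apply_mask(cohort.data, mask)


@pytest.fixture(scope="session")
def mcar_kappa_grid():
    """Stacked-imputation kappa for all strategies, MCAR at the four benchmark
    fractions, 100 simulation runs each (m=5).  Maps fraction -> (cell summary,
    per-run records)."""
    return {
        f: run_cell("MCAR", f, models=(), n_runs=100, m=5, seed=SESSION_SEED, collect_runs=True)
        for f in (0.05, 0.20, 0.30, 0.50)
    }


@pytest.fixture(scope="session")
def variance_cells():
    """Pooled-SE cells for the variance-underestimation ordering: GEE pooling
    at 30% MCAR for the contrasted strategies, and the within- vs
    across-cluster CI comparison at 50%."""
    cell30 = run_cell(
        "MCAR",
        0.30,
        strategies=["ignore_cluster:logistic", "across_cluster:fe_logistic", "within_cluster:mcmc"],
        models=("GEE",),
        n_runs=100,
        m=5,
        seed=SESSION_SEED,
    )
    cell50 = run_cell(
        "MCAR",
        0.50,
        strategies=["within_cluster:propensity", "across_cluster:propensity"],
        models=("GEE",),
        n_runs=100,
        m=5,
        seed=SESSION_SEED,
    )
    return {0.30: cell30, 0.50: cell50}


@pytest.fixture(scope="session")
def model_agreement_cell():
    """GEE and RE pooled arm effects side by side at 30% MCAR."""
    return run_cell(
        "MCAR",
        0.30,
        strategies=["complete_case:none", "ignore_cluster:logistic"],
        models=("GEE", "RE"),
        n_runs=100,
        m=5,
        seed=SESSION_SEED,
    )


@pytest.fixture(scope="session")
def recovery_fits(default_config):
    """Complete-data GEE and RE fits on 200 replicate cohorts generated at the
    calibrated defaults (arm OR 1.14, latent ICC 0.055)."""
    rows = []
    for rep in range(200):
        cohort = generate_cohort(default_config, seed=SESSION_SEED + rep)
        gee = fit_gee_exchangeable(cohort.data)
        re = fit_re_analysis(cohort.data)
        rows.append(
            {
                "gee_arm": gee.coef("arm"),
                "re_arm": re.coef("arm"),
                "sigma_b2": re.sigma_b2,
                "icc": estimate_icc(re),
            }
        )
    return rows
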