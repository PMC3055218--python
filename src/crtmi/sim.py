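"""Simulation driver: mechanism x fraction x strategy x analysis-model grid.

Per run: generate a cohort, mask the outcome, impute with every strategy
(m copies), score stacked-imputation kappa against the truth, fit the analysis
models per copy and Rubin-pool the arm log odds ratio.  Per cell the run-level
results are averaged: mean kappa, mean pooled log-OR and mean pooled SE across
successful runs, with the displayed CI rebuilt from the averaged quantities
(normal quantile on the averaged SE).  Strategy failures are counted and
excluded from the averages; a cell with no successes stays blank in the
emitted tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ConvergenceError
from .analysis import fit_gee_exchangeable, fit_re_analysis, mi_kappa, pool_rubin
from .cohort import CohortConfig, generate_cohort
from .missingness import STANDARD_FRACTIONS, MissingnessSpec, apply_mask, make_mask
from .strategies import StrategyID, all_strategies, impute

RESULT_COLUMNS = [
    "mechanism",
    "fraction",
    "strategy",
    "model",
    "n_runs",
    "n_failed",
    "mean_kappa",
    "mean_log_or",
    "mean_se",
    "odds_ratio",
    "ci_low",
    "ci_high",
]


@dataclass
class ExperimentGrid:
    mechanisms: tuple = ("MCAR", "CD")
    fractions: tuple = STANDARD_FRACTIONS
    strategies: tuple = tuple(all_strategies())
    models: tuple = ("GEE", "RE")
    n_runs: int = 100
    m: int = 5
    seed: int = 0
    cohort_config: CohortConfig = field(default_factory=CohortConfig)


def _run_seed(master: int, run: int, *extra) -> np.random.SeedSequence:
    """Counter-based seed splitter: stable child seeds for (run, purpose)."""
    return np.random.SeedSequence(entropy=(int(master), int(run), *[int(e) for e in extra]))


_PURPOSE = {"cohort": 1, "mask": 2, "impute": 3}


def _fit_arm(model: str, data: pd.DataFrame):
    fit = fit_gee_exchangeable(data) if model == "GEE" else fit_re_analysis(data)
    return fit.coef("arm"), fit.var("arm")


def run_cell(
    mechanism: str,
    fraction: float,
    strategies=None,
    models: tuple = ("GEE", "RE"),
    n_runs: int = 100,
    m: int = 5,
    seed: int = 0,
    cohort_config: CohortConfig | None = None,
    collect_runs: bool = False,
):
    """Evaluate one (mechanism, fraction) cell for a set of strategies.

    Returns a DataFrame with one row per (strategy, model) plus a kappa-only
    row per strategy (model="-").  With ``collect_runs=True`` also returns the
    per-run records for downstream inspection.
    """
    strategies = list(strategies) if strategies is not None else all_strategies()
    strategies = [StrategyID.parse(s) if isinstance(s, str) else s for s in strategies]
    cohort_config = cohort_config if cohort_config is not None else CohortConfig()

    records = []
    for run in range(n_runs):
        cohort = generate_cohort(cohort_config, seed=_run_seed(seed, run, _PURPOSE["cohort"]))
        truth = cohort.outcome
        spec = MissingnessSpec(mechanism=mechanism, fraction=fraction)
        mask = make_mask(
            cohort.data, spec, seed=_run_seed(seed, run, _PURPOSE["mask"], round(fraction * 1000))
        )
        masked = apply_mask(cohort.data, mask)

        for s_idx, strategy in enumerate(strategies):
            imp_seed = _run_seed(seed, run, _PURPOSE["impute"], round(fraction * 1000), s_idx)
            mi = impute(masked, strategy, m=m, seed=imp_seed)
            rec = {
                "run": run,
                "strategy": str(strategy),
                "failed": mi.failed,
                "failure_reason": mi.failure_reason,
                "kappa": np.nan,
            }
            if mi.failed:
                records.append(rec)
                continue
            if strategy.level != "complete_case":
                rec["kappa"] = mi_kappa(mi, truth).kappa
            for model in models:
                try:
                    if strategy.level == "complete_case":
                        q, u = _fit_arm(model, mi.completed(0))
                        rec[f"logor_{model}"], rec[f"se_{model}"] = q, float(np.sqrt(u))
                    else:
                        pairs = [_fit_arm(model, mi.completed(i)) for i in range(m)]
                        pooled = pool_rubin(pairs)
                        rec[f"logor_{model}"], rec[f"se_{model}"] = pooled.qbar, pooled.se
                except ConvergenceError as exc:
                    rec["failed"] = True
                    rec["failure_reason"] = f"{model} analysis: {exc}"
            records.append(rec)

    runs_df = pd.DataFrame.from_records(records)
    rows = []
    for strategy in strategies:
        sub = runs_df[runs_df["strategy"] == str(strategy)]
        ok = sub[~sub["failed"]]
        base = {
            "mechanism": mechanism,
            "fraction": fraction,
            "strategy": str(strategy),
            "n_runs": n_runs,
            "n_failed": int(sub["failed"].sum()),
            "mean_kappa": float(ok["kappa"].mean()) if len(ok) else np.nan,
        }
        report_models = models if models else ("-",)
        for model in report_models:
            row = dict(base, model=model)
            col_q, col_se = f"logor_{model}", f"se_{model}"
            if model != "-" and len(ok) and col_q in ok:
                mean_q = float(ok[col_q].mean())
                mean_se = float(ok[col_se].mean())
                row["mean_log_or"] = mean_q
                row["mean_se"] = mean_se
                row["odds_ratio"] = float(np.exp(mean_q))
                row["ci_low"] = float(np.exp(mean_q - 1.96 * mean_se))
                row["ci_high"] = float(np.exp(mean_q + 1.96 * mean_se))
            else:
                row["mean_log_or"] = row["mean_se"] = np.nan
                row["odds_ratio"] = row["ci_low"] = row["ci_high"] = np.nan
            rows.append(row)
    result = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if collect_runs:
        return result, runs_df
    return result


def run_grid(grid: ExperimentGrid, out_dir=None) -> pd.DataFrame:
    """Run every (mechanism, fraction) cell of the grid; deterministic given
    the master seed.  With ``out_dir`` each finished cell is checkpointed to
    CSV and skipped on resume."""
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    for mechanism in grid.mechanisms:
        for fraction in grid.fractions:
            tag = f"cell_{mechanism}_{round(fraction * 1000):03d}.csv"
            if out_dir is not None and (out_dir / tag).exists():
                frames.append(pd.read_csv(out_dir / tag))
                continue
            cell = run_cell(
                mechanism,
                fraction,
                strategies=grid.strategies,
                models=grid.models,
                n_runs=grid.n_runs,
                m=grid.m,
                seed=grid.seed,
                cohort_config=grid.cohort_config,
            )
            if out_dir is not None:
                cell.to_csv(out_dir / tag, index=False)
            frames.append(cell)
    return pd.concat(frames, ignore_index=True)


def write_tables(results: pd.DataFrame, out_dir) -> list:
    """Emit per-mechanism kappa and treatment-effect tables as CSV.

    Kappa tables: strategy rows x missing-fraction columns (blank where every
    run failed).  Effect tables: strategy x model rows with "OR (low high)"
    strings per fraction.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    strategy_order = [str(s) for s in all_strategies()]
    for mechanism in results["mechanism"].unique():
        sub = results[results["mechanism"] == mechanism]
        fractions = sorted(sub["fraction"].unique())

        kap = sub.drop_duplicates(subset=["strategy", "fraction"])
        kap = kap[kap["strategy"] != "complete_case:none"]
        table = kap.pivot(index="strategy", columns="fraction", values="mean_kappa")
        table = table.reindex([s for s in strategy_order if s in table.index])
        table = table.reindex(columns=fractions)
        path = out_dir / f"kappa_{mechanism}.csv"
        table.round(3).to_csv(path, na_rep="")
        written.append(path)

        eff = sub[sub["model"].isin(["GEE", "RE"])].copy()
        if len(eff):
            def _fmt(r):
                if np.isnan(r["odds_ratio"]):
                    return ""
                return f"{r['odds_ratio']:.2f} ({r['ci_low']:.2f} {r['ci_high']:.2f})"

            eff["cell"] = eff.apply(_fmt, axis=1)
            table = eff.pivot(index=["strategy", "model"], columns="fraction", values="cell")
            table = table.reindex(
                [(s, mdl) for s in strategy_order for mdl in ("GEE", "RE") if (s, mdl) in table.index]
            )
            table = table.reindex(columns=fractions)
            path = out_dir / f"effects_{mechanism}.csv"
            table.to_csv(path, na_rep="")
            written.append(path)
    return written
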