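"""Scenario definitions, the Monte-Carlo replication engine and reporting.

Five one-at-a-time experimental scenarios vary, around a common set of
defaults, the between-individual SDs of birth length and growth rate,
their correlation, the height measurement-error SD and the outcome
residual SD.  For every grid value, replicate datasets are simulated and
each requested method's estimates of the unconditional birth-length
association (``alpha1``) and the conditional growth-rate association
(``alpha4``) are recorded together with their standard errors.  Summaries
are the mean relative bias in percent, ``mean((a_hat - a) / a) * 100``,
and the empirical coverage of the 1.96-SE Wald interval, each with its
Monte-Carlo standard error.

Replicate seeds are derived from ``(master_seed, scenario, grid index,
replicate index)``, so any single replicate can be reconstructed in
isolation and results do not depend on execution order.  One age-schedule
draw (derived from the master seed alone) is shared by every replicate
and scenario; ``redraw_ages`` switches to a fresh schedule per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .association import bootstrap_joint, joint_two_stage, second_stage
from .mixed_models import (
    blup_residuals,
    estimates_from_residuals,
    fit_univariate_lmm,
    inflate_residuals,
)
from .sem import fit_sem_conditional, fit_sem_unconditional
from .simulate import (
    DEFAULT_AGE_SDS,
    DEFAULT_MEAN_AGES,
    GrowthParams,
    OutcomeParams,
    draw_age_schedule,
    simulate_trajectories,
)
from .trajectory_summaries import ols_summaries, simple_summaries

__all__ = [
    "Scenario",
    "ScenarioResult",
    "SCENARIO_GRIDS",
    "ALL_METHODS",
    "make_scenario",
    "true_alpha1",
    "relative_bias",
    "coverage",
    "run_scenario",
    "run_bootstrap_coverage",
    "report",
]

#: Parameter grids of the experimental scenarios; defaults in the middle.
SCENARIO_GRIDS: dict[str, list[float]] = {
    "baseline": [],
    "sigma_u0": [1.5, 2.0, 2.5, 3.0, 3.5],
    "sigma_u1": [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
    "sigma_eh": [0.1, 1.0, 2.0, 3.0, 4.0, 5.0],
    "rho_u01": [-0.6, -0.4, -0.2, -0.1, 0.0, 0.1, 0.2, 0.4, 0.6],
    "sigma_ebp": [8.0, 9.0, 10.0, 11.0, 12.0],
}

ALL_METHODS = ("simple", "ols", "mlm_shrunken", "mlm_inflated", "bvm_inflated", "sem")

# stable scenario ids for seed derivation
_SCENARIO_IDS = {name: i for i, name in enumerate(SCENARIO_GRIDS)}
_AGE_STREAM = 424243


@dataclass(frozen=True)
class Scenario:
    """A named scenario: one varied parameter over its grid."""

    name: str
    grid: list = field(default_factory=list)
    growth: GrowthParams = GrowthParams()
    outcome: OutcomeParams = OutcomeParams()
    n_individuals: int = 1000
    n_replicates: int = 200
    master_seed: int = 0
    mean_ages: tuple = DEFAULT_MEAN_AGES
    age_sds: tuple = DEFAULT_AGE_SDS
    redraw_ages: bool = False

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_GRIDS:
            raise ValueError(
                f"unknown scenario {self.name!r}; expected one of {list(SCENARIO_GRIDS)}"
            )

    def params_at(self, value):
        """GrowthParams/OutcomeParams with the varied parameter set."""
        if self.name == "baseline":
            return self.growth, self.outcome
        if self.name == "sigma_ebp":
            return self.growth, replace(self.outcome, sigma_ebp=value)
        return replace(self.growth, **{self.name: value}), self.outcome


def make_scenario(name: str, n_replicates: int = 200, master_seed: int = 0,
                  **overrides) -> Scenario:
    """A scenario with its standard grid (baseline has a single point)."""
    grid = overrides.pop("grid", None)
    if grid is None:
        grid = list(SCENARIO_GRIDS[name]) or [None]
    return Scenario(name=name, grid=list(grid), n_replicates=n_replicates,
                    master_seed=master_seed, **overrides)


def true_alpha1(growth: GrowthParams, outcome: OutcomeParams) -> float:
    """Expected unconditional birth-length association,
    ``alpha3 + alpha4 * rho * sigma_u1 / sigma_u0``."""
    if growth.sigma_u0 <= 0:
        raise ValueError("sigma_u0 must be positive")
    return outcome.alpha3 + outcome.alpha4 * growth.rho_u01 * (
        growth.sigma_u1 / growth.sigma_u0
    )


def relative_bias(estimates, truth: float):
    """Mean per-replicate relative bias in percent, with its MC SE."""
    if truth == 0:
        raise ZeroDivisionError("relative bias is undefined for a zero truth")
    rel = (np.asarray(estimates, dtype=float) - truth) / truth * 100.0
    n = rel.size
    mc_se = float(rel.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    return float(rel.mean()), mc_se


def coverage(estimates, ses, truth: float):
    """Percent of replicates with ``|a_hat - a| <= 1.96 SE``, with
    binomial MC SE."""
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if np.any(se < 0):
        raise ValueError("standard errors must be non-negative")
    hit = np.abs(est - truth) <= 1.96 * se
    p = hit.mean()
    mc_se = float(np.sqrt(p * (1 - p) / hit.size) * 100.0)
    return float(p * 100.0), mc_se


@dataclass(frozen=True)
class ScenarioResult:
    """Aggregated scenario output plus the replicate-level table."""

    scenario: str
    summary: pd.DataFrame  # per (grid_value, method, parameter)
    replicates: pd.DataFrame  # per (grid_value, method, parameter, replicate)


def _replicate_estimates(data, methods, mean_ages):
    """One replicate: every requested method's (alpha1, alpha4[, alpha3])
    association estimates.  Returns list of dicts."""
    rows = []

    def push(assoc):
        for par in ("alpha1", "alpha4", "alpha3"):
            a = assoc[par]
            rows.append(
                {"method": a.method, "parameter": par,
                 "estimate": a.estimate, "se": a.se,
                 "ci_low": a.ci_low, "ci_high": a.ci_high,
                 "ci_kind": a.ci_kind}
            )

    if "simple" in methods:
        push(second_stage(simple_summaries(data), data.outcome))
    if "ols" in methods:
        push(second_stage(ols_summaries(data), data.outcome))
    if "mlm_shrunken" in methods or "mlm_inflated" in methods:
        fit = fit_univariate_lmm(data)
        if not fit.converged:
            raise np.linalg.LinAlgError("univariate fit did not converge")
        res = blup_residuals(fit, data)
        if "mlm_shrunken" in methods:
            push(second_stage(estimates_from_residuals(fit, res), data.outcome))
        if "mlm_inflated" in methods:
            infl = inflate_residuals(res, fit.omega)
            push(second_stage(estimates_from_residuals(fit, infl), data.outcome))
    if "bvm_inflated" in methods:
        fit, _, assoc = joint_two_stage(data)
        if not fit.converged:
            raise np.linalg.LinAlgError("bivariate fit did not converge")
        push(assoc)
    if "sem" in methods:
        cond = fit_sem_conditional(data, mean_ages=mean_ages)
        uncond = fit_sem_unconditional(data, mean_ages=mean_ages)
        for par, f in [("alpha1", uncond), ("alpha4", cond), ("alpha3", cond)]:
            est, se = f.coef[par], f.se[par]
            rows.append(
                {"method": "sem", "parameter": par, "estimate": est, "se": se,
                 "ci_low": est - 1.96 * se, "ci_high": est + 1.96 * se,
                 "ci_kind": "wald"}
            )
    return rows


def run_scenario(scenario: Scenario, methods=ALL_METHODS) -> ScenarioResult:
    """Run the Monte-Carlo study for one scenario.

    Non-converged replicates are dropped from a method's summary (each
    method uses its own converged set) and counted in ``n_converged``.
    """
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    scen_id = _SCENARIO_IDS[scenario.name]
    schedule = None
    if not scenario.redraw_ages:
        schedule = draw_age_schedule(
            scenario.mean_ages, scenario.age_sds, scenario.n_individuals,
            seed=np.random.SeedSequence([scenario.master_seed, _AGE_STREAM]),
        )
    rep_rows = []
    for gi, value in enumerate(scenario.grid):
        growth, outcome = scenario.params_at(value)
        truths = {"alpha1": true_alpha1(growth, outcome),
                  "alpha3": outcome.alpha3, "alpha4": outcome.alpha4}
        for rep in range(scenario.n_replicates):
            ss = np.random.SeedSequence(
                [scenario.master_seed, scen_id, gi, rep]
            )
            sched = schedule
            if sched is None:
                ss_age, ss = ss.spawn(2)
                sched = draw_age_schedule(
                    scenario.mean_ages, scenario.age_sds,
                    scenario.n_individuals, seed=ss_age,
                )
            data = simulate_trajectories(sched, growth, outcome, seed=ss)
            try:
                rows = _replicate_estimates(data, methods, scenario.mean_ages)
            except np.linalg.LinAlgError:
                continue
            for r in rows:
                r.update(
                    grid_value=np.nan if value is None else value,
                    replicate=rep,
                    truth=truths[r["parameter"]],
                    covered=abs(r["estimate"] - truths[r["parameter"]])
                    <= 1.96 * r["se"],
                )
            rep_rows.extend(rows)
    reps = pd.DataFrame(rep_rows)
    summary = _summarise(scenario, reps)
    return ScenarioResult(scenario=scenario.name, summary=summary, replicates=reps)


def _summarise(scenario: Scenario, reps: pd.DataFrame) -> pd.DataFrame:
    out = []
    for (gv, method, par), grp in reps.groupby(
        ["grid_value", "method", "parameter"], dropna=False
    ):
        truth = grp["truth"].iloc[0]
        rb, rb_se = relative_bias(grp["estimate"], truth)
        cov, cov_se = coverage(grp["estimate"], grp["se"], truth)
        out.append(
            {
                "scenario": scenario.name,
                "grid_value": gv,
                "method": method,
                "parameter": par,
                "truth": truth,
                "rel_bias_pct": rb,
                "mc_se_bias": rb_se,
                "coverage_pct": cov,
                "mc_se_cov": cov_se,
                "n_converged": len(grp),
            }
        )
    return pd.DataFrame(out).sort_values(
        ["grid_value", "method", "parameter"]
    ).reset_index(drop=True)


def run_bootstrap_coverage(
    n_replicates: int = 200,
    n_boot: int = 200,
    n_individuals: int = 1000,
    master_seed: int = 0,
    growth: GrowthParams = GrowthParams(),
    outcome: OutcomeParams = OutcomeParams(),
) -> pd.DataFrame:
    """Coverage of bootstrap CIs for the joint-model path at baseline.

    For each replicate the full bivariate pipeline provides the point
    estimates, and a ``n_boot``-resample cluster bootstrap the SEs; the
    returned replicate table records, for both parameters and both CI
    kinds, whether the interval covered the truth.
    """
    schedule = draw_age_schedule(
        n_individuals=n_individuals,
        seed=np.random.SeedSequence([master_seed, _AGE_STREAM]),
    )
    truths = {"alpha1": true_alpha1(growth, outcome), "alpha4": outcome.alpha4}
    rows = []
    for rep in range(n_replicates):
        ss = np.random.SeedSequence([master_seed, 99, 0, rep])
        ss_data, ss_boot = ss.spawn(2)
        data = simulate_trajectories(schedule, growth, outcome, seed=ss_data)
        boot = bootstrap_joint(data, n_boot=n_boot, seed=ss_boot)
        for par in ("alpha1", "alpha4"):
            for kind in ("bootstrap_normal", "bootstrap_percentile"):
                est = boot.estimate(par, kind)
                rows.append(
                    {
                        "replicate": rep,
                        "parameter": par,
                        "ci_kind": kind,
                        "estimate": est.estimate,
                        "se": est.se,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                        "truth": truths[par],
                        "covered": est.covers(truths[par]),
                        "flagged": boot.flagged,
                    }
                )
    return pd.DataFrame(rows)


def report(results, out_dir, plots: bool = False) -> None:
    """Write tidy CSVs and a text summary per scenario; optional figures."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not results:
        raise ValueError("no results to report")
    for res in results:
        res.summary.to_csv(out / f"{res.scenario}_summary.csv", index=False)
        res.replicates.to_csv(out / f"{res.scenario}_replicates.csv", index=False)
        with open(out / f"{res.scenario}_summary.txt", "w") as fh:
            fh.write(f"scenario: {res.scenario}\n\n")
            for par in ("alpha1", "alpha4"):
                sub = res.summary[res.summary.parameter == par]
                if sub.empty:
                    continue
                fh.write(f"--- {par} ---\n")
                fh.write(
                    sub.pivot_table(
                        index="grid_value",
                        columns="method",
                        values=["rel_bias_pct", "coverage_pct"],
                    ).round(1).to_string()
                )
                fh.write("\n\n")
        if plots:
            _plot_scenario(res, out)


def _plot_scenario(res: ScenarioResult, out_dir) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
    for col, par in enumerate(("alpha1", "alpha4")):
        sub = res.summary[res.summary.parameter == par]
        for method, grp in sub.groupby("method"):
            axes[0, col].plot(grp.grid_value, grp.rel_bias_pct, "o-", label=method)
            axes[1, col].plot(grp.grid_value, grp.coverage_pct, "o-", label=method)
        axes[0, col].set_title(f"relative bias (%) — {par}")
        axes[1, col].set_title(f"coverage (%) — {par}")
        axes[1, col].axhline(95, color="grey", ls=":")
        axes[0, col].axhline(0, color="grey", ls=":")
    axes[0, 0].legend(fontsize=7)
    for ax in axes[1]:
        ax.set_xlabel(res.scenario)
    fig.tight_layout()
    fig.savefig(f"{out_dir}/{res.scenario}.png", dpi=120)
    plt.close(fig)
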