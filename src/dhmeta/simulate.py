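"""Simulation engine and synthetic-data generator.

The design grid crosses the between-study gradient beta in {0, 0.4,
0.8}, the shared within-study correlation rho in {0, 0.4, 0.8}, the
between-study variance tau2 in {0, 0.5, 1} and the intercept alpha in
{0, 0.25} — 54 scenarios.  Every data set has n = 20 studies with true
surrogate effects gamma_i ~ U(-5, 5) drawn fresh per replicate and
fixed within-study variances sigma_i^2 = delta_i^2 = 0.05, 0.10, ...,
1.00 assigned one per study.  Observed pairs (theta_hat_i,
gamma_hat_i) are drawn from the marginal bivariate-normal model.

Seeding is counter-based: a master seed plus (scenario index,
replicate index) reproduces any single replicate in isolation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import McmcOptions, posterior_summary, sample_posterior
from .fit import FitOptions, fit_adjusted, fit_mle
from .model import ParameterState, StudyTable

BETA_GRID = (0.0, 0.4, 0.8)
RHO_GRID = (0.0, 0.4, 0.8)
TAU2_GRID = (0.0, 0.5, 1.0)
ALPHA_GRID = (0.0, 0.25)

DEFAULT_VARIANCE_GRID = tuple(0.05 * i for i in range(1, 21))


@dataclass
class SimulationScenario:
    """One cell of the simulation design."""

    beta: float
    rho: float
    tau2: float
    alpha: float
    index: int = 0
    n_studies: int = 20
    gamma_low: float = -5.0
    gamma_high: float = 5.0
    variance_grid: tuple = DEFAULT_VARIANCE_GRID
    replicates: int = 1000
    base_seed: int = 0
    fixed_gammas: bool = False

    def __post_init__(self) -> None:
        if len(self.variance_grid) != self.n_studies:
            raise ValueError(
                f"variance_grid has {len(self.variance_grid)} entries for "
                f"{self.n_studies} studies"
            )

    @property
    def label(self) -> str:
        return (
            f"beta={self.beta:g}_rho={self.rho:g}_tau2={self.tau2:g}"
            f"_alpha={self.alpha:g}"
        )


@dataclass
class SimulationSummary:
    """Bias/coverage metrics, one row per scenario x method x parameter."""

    table: pd.DataFrame = field(repr=False)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def make_scenarios(replicates: int = 1000, base_seed: int = 0) -> list[SimulationScenario]:
    """Enumerate the full 3 x 3 x 3 x 2 = 54-scenario grid.

    Each scenario carries a distinct index feeding the counter-based
    seeding scheme, so scenario streams never collide.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    scenarios = []
    for idx, (beta, rho, tau2, alpha) in enumerate(
        itertools.product(BETA_GRID, RHO_GRID, TAU2_GRID, ALPHA_GRID)
    ):
        scenarios.append(
            SimulationScenario(
                beta=beta,
                rho=rho,
                tau2=tau2,
                alpha=alpha,
                index=idx,
                replicates=replicates,
                base_seed=base_seed,
            )
        )
    return scenarios


def _replicate_rng(scenario: SimulationScenario, replicate_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(
            entropy=scenario.base_seed,
            spawn_key=(scenario.index, replicate_index),
        )
    )


def simulate_dataset(
    scenario: SimulationScenario, replicate_index: int = 0
) -> tuple[StudyTable, ParameterState]:
    """Draw one data set and return it with the generating truth.

    gamma_i ~ U(gamma_low, gamma_high); then gamma_hat_i = gamma_i +
    delta_i Z and theta_hat_i from the conditional normal of the
    marginal model, which reproduces the joint bivariate-normal law
    with covariance [[sigma^2 + tau2, rho sigma delta], [., delta^2]].
    """
    rng = _replicate_rng(scenario, replicate_index)
    if scenario.fixed_gammas:
        # one gamma draw shared by every replicate of the scenario
        gamma_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=scenario.base_seed, spawn_key=(scenario.index,))
        )
        gammas = gamma_rng.uniform(scenario.gamma_low, scenario.gamma_high, scenario.n_studies)
    else:
        gammas = rng.uniform(scenario.gamma_low, scenario.gamma_high, scenario.n_studies)
    var = np.asarray(scenario.variance_grid, dtype=float)
    sigma = np.sqrt(var)
    delta = np.sqrt(var)
    rho = np.full(scenario.n_studies, scenario.rho)
    gamma_hat = gammas + delta * rng.standard_normal(scenario.n_studies)
    g = rho * sigma / delta
    v2 = sigma**2 * (1.0 - rho**2)
    mean_theta = scenario.alpha + scenario.beta * gammas + g * (gamma_hat - gammas)
    theta_hat = mean_theta + np.sqrt(v2 + scenario.tau2) * rng.standard_normal(
        scenario.n_studies
    )
    table = StudyTable.from_arrays(theta_hat, gamma_hat, sigma, delta, rho)
    truth = ParameterState(scenario.alpha, scenario.beta, scenario.tau2, gammas)
    return table, truth


def _covers(interval: tuple[float, float], truth: float) -> bool:
    return interval[0] <= truth <= interval[1]


def evaluate_methods(
    table: StudyTable,
    truth: ParameterState,
    methods: set[str] = frozenset({"mle", "adjusted"}),
    fit_options: FitOptions | None = None,
    mcmc_options: McmcOptions | None = None,
) -> list[dict]:
    """Apply the requested methods to one data set.

    Returns one record per method with point estimates of alpha, beta
    and tau2 (posterior mean and median for ``bayes``), 95%-interval
    coverage indicators for alpha and beta, and a convergence flag.  A
    non-converged replicate is recorded, never raised.
    """
    bad = set(methods) - {"mle", "adjusted", "bayes"}
    if bad:
        raise ValueError(f"unknown methods: {sorted(bad)}")
    records = []
    for method in sorted(methods):
        rec = {
            "method": method,
            "alpha_est": np.nan,
            "beta_est": np.nan,
            "tau2_est": np.nan,
            "tau2_median": np.nan,
            "cover_alpha": np.nan,
            "cover_beta": np.nan,
            "converged": False,
        }
        try:
            if method == "bayes":
                chains = sample_posterior(table, mcmc_options)
                summ = posterior_summary(chains)
                rec.update(
                    alpha_est=summ.params["alpha"].mean,
                    beta_est=summ.params["beta"].mean,
                    tau2_est=summ.params["tau2"].mean,
                    tau2_median=summ.params["tau2"].median,
                    cover_alpha=float(_covers(summ.params["alpha"].percentile, truth.alpha)),
                    cover_beta=float(_covers(summ.params["beta"].percentile, truth.beta)),
                    converged=not chains.warnings,
                )
            else:
                fitter = fit_mle if method == "mle" else fit_adjusted
                fit = fitter(table, fit_options)
                rec.update(
                    alpha_est=fit.estimates.alpha,
                    beta_est=fit.estimates.beta,
                    tau2_est=fit.estimates.tau2,
                    cover_alpha=float(_covers(fit.wald_intervals["alpha"], truth.alpha)),
                    cover_beta=float(_covers(fit.wald_intervals["beta"], truth.beta)),
                    converged=bool(fit.converged),
                )
        except Exception:  # noqa: BLE001 - a failed replicate is data, not a crash
            pass
        records.append(rec)
    return records


def run_scenario(
    scenario: SimulationScenario,
    methods: set[str] = frozenset({"mle", "adjusted"}),
    fit_options: FitOptions | None = None,
    mcmc_options: McmcOptions | None = None,
) -> pd.DataFrame:
    """Run all replicates of one scenario; returns replicate-level records."""
    rows = []
    for rep in range(scenario.replicates):
        table, truth = simulate_dataset(scenario, rep)
        mcmc = mcmc_options
        if mcmc is not None and "bayes" in methods:
            mcmc = McmcOptions(
                burn_in=mcmc.burn_in,
                kept_iterations=mcmc.kept_iterations,
                thinning=mcmc.thinning,
                seed=int(np.random.SeedSequence(
                    entropy=scenario.base_seed, spawn_key=(scenario.index, rep, 1)
                ).generate_state(1)[0] % (2**31)),
                prior_sd_regression=mcmc.prior_sd_regression,
                tau_upper=mcmc.tau_upper,
            )
        for rec in evaluate_methods(table, truth, methods, fit_options, mcmc):
            rec.update(
                scenario=scenario.label,
                replicate=rep,
                beta_true=scenario.beta,
                rho=scenario.rho,
                tau2_true=scenario.tau2,
                alpha_true=scenario.alpha,
            )
            rows.append(rec)
    return pd.DataFrame(rows)


def summarize(records: pd.DataFrame) -> SimulationSummary:
    """Bias, coverage and Monte-Carlo standard errors per cell.

    Non-converged replicates are excluded from the summaries but
    counted.  Coverage MC SE is the binomial sqrt(p(1-p)/R); bias MC SE
    is the sampling SD of the estimate divided by sqrt(R).
    """
    rows = []
    for (scenario, method), grp in records.groupby(["scenario", "method"], sort=False):
        ok = grp[grp["converged"]]
        n_total = len(grp)
        n_conv = len(ok)
        meta = grp.iloc[0]
        for param, est_col, truth_val in (
            ("alpha", "alpha_est", meta["alpha_true"]),
            ("beta", "beta_est", meta["beta_true"]),
            ("tau2", "tau2_est", meta["tau2_true"]),
        ):
            est = ok[est_col].to_numpy()
            bias = float(np.mean(est) - truth_val) if n_conv else np.nan
            bias_se = float(np.std(est, ddof=1) / np.sqrt(n_conv)) if n_conv > 1 else np.nan
            if param in ("alpha", "beta") and n_conv:
                p = float(ok[f"cover_{param}"].mean())
                cov_se = float(np.sqrt(p * (1 - p) / n_conv))
            else:
                p, cov_se = np.nan, np.nan
            rows.append(
                {
                    "scenario": scenario,
                    "method": method,
                    "parameter": param,
                    "beta_true": meta["beta_true"],
                    "rho": meta["rho"],
                    "tau2_true": meta["tau2_true"],
                    "alpha_true": meta["alpha_true"],
                    "bias": bias,
                    "bias_mc_se": bias_se,
                    "coverage": p,
                    "coverage_mc_se": cov_se,
                    "n_converged": n_conv,
                    "n_total": n_total,
                }
            )
    return SimulationSummary(table=pd.DataFrame(rows))
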