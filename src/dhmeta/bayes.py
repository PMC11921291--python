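"""Reference Bayesian analysis of the model by Metropolis-within-Gibbs.

Priors: independent N(0, 1000) on alpha, beta and each gamma_i, and a
uniform prior on the between-study standard deviation tau ~ U(0, 2).
The within-study correlations rho_i are fixed at their supplied values.

Under the factorized likelihood the full conditionals of alpha, beta
and each gamma_i are conjugate normals, so they are drawn exactly; tau
is updated on the standard-deviation scale by a reflecting random-walk
Metropolis step confined to (0, tau_upper).  The sampler is
hand-rolled: it keeps the package self-contained and exactly seedable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import StudyTable


@dataclass
class McmcOptions:
    """MCMC settings.

    Defaults follow the reference analysis: 1000 burn-in iterations,
    10,000 retained draws with a thinning frequency of two, N(0, 1000)
    priors on the regression parameters (``prior_sd_regression`` is the
    prior SD, sqrt(1000)), and tau ~ U(0, 2).
    """

    burn_in: int = 1000
    kept_iterations: int = 10000
    thinning: int = 2
    seed: int = 0
    prior_sd_regression: float = float(np.sqrt(1000.0))
    tau_upper: float = 2.0

    def __post_init__(self) -> None:
        if min(self.burn_in, self.kept_iterations, self.thinning) <= 0:
            raise ValueError("burn_in, kept_iterations and thinning must be positive")
        if self.tau_upper <= 0:
            raise ValueError("tau_upper must be > 0")


@dataclass
class McmcChains:
    """Kept, thinned posterior draws."""

    alpha: np.ndarray
    beta: np.ndarray
    tau2: np.ndarray
    gammas: np.ndarray  # shape (n_draws, n_studies)
    accept_rate_tau: float
    seed: int
    warnings: list = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.alpha.size


@dataclass
class ParamSummary:
    mean: float
    median: float
    percentile: tuple[float, float]
    hpd: tuple[float, float]


@dataclass
class PosteriorSummary:
    """Posterior summaries per parameter.

    ``params`` maps ``"alpha"``, ``"beta"``, ``"tau2"`` and
    ``"gamma_1"``.. to :class:`ParamSummary` (posterior mean, median,
    central 95% percentile interval, and 95% HPD interval).
    """

    params: dict
    n_draws: int
    seed: int


def _reflect(x: float, lo: float, hi: float) -> float:
    """Fold a proposal back into (lo, hi) by reflection at the bounds."""
    width = hi - lo
    y = (x - lo) % (2.0 * width)
    return lo + (y if y <= width else 2.0 * width - y)


def sample_posterior(
    table: StudyTable, options: McmcOptions | None = None, prior_only: bool = False
) -> McmcChains:
    """Draw from the posterior of (alpha, beta, tau2, gamma_1..gamma_n).

    Component-wise sampler: exact conjugate-normal draws for alpha,
    beta and the gammas (the latter vectorized across studies), and a
    reflecting random-walk Metropolis step of size 0.1 * tau_upper for
    tau on (0, tau_upper).  ``prior_only=True`` switches the likelihood
    off, so the chains target the prior — used for prior-predictive
    checks.  Bit-identical output for a given seed.
    """
    options = options or McmcOptions()
    rng = np.random.default_rng(options.seed)
    n = table.n
    s2 = options.prior_sd_regression**2
    g = table.within_gradient
    v2 = table.v2
    d2 = table.delta**2
    th = table.theta_hat
    gh = table.gamma_hat

    total = options.burn_in + options.kept_iterations * options.thinning
    keep = options.kept_iterations
    out_alpha = np.empty(keep)
    out_beta = np.empty(keep)
    out_tau2 = np.empty(keep)
    out_gammas = np.empty((keep, n))

    alpha, beta = 0.0, 0.0
    gammas = gh.copy()
    tau = 0.5 * options.tau_upper
    step = 0.1 * options.tau_upper
    n_acc = 0
    n_prop = 0
    kept = 0

    like = 0.0 if prior_only else 1.0
    for it in range(total):
        w = v2 + tau**2
        # alpha | rest
        e = th - beta * gammas - g * (gh - gammas)
        prec = like * np.sum(1.0 / w) + 1.0 / s2
        mean = like * np.sum(e / w) / prec
        alpha = rng.normal(mean, 1.0 / np.sqrt(prec))
        # beta | rest
        e = th - alpha - g * (gh - gammas)
        prec = like * np.sum(gammas**2 / w) + 1.0 / s2
        mean = like * np.sum(gammas * e / w) / prec
        beta = rng.normal(mean, 1.0 / np.sqrt(prec))
        # gammas | rest (vectorized: conjugate under both likelihood factors)
        k = beta - g
        prec_g = like * (1.0 / d2 + k**2 / w) + 1.0 / s2
        mean_g = like * (gh / d2 + k * (th - alpha - g * gh) / w) / prec_g
        gammas = rng.normal(mean_g, 1.0 / np.sqrt(prec_g))
        # tau | rest: reflecting random walk on (0, tau_upper)
        tau_prop = _reflect(tau + step * rng.normal(), 0.0, options.tau_upper)
        if prior_only:
            tau = tau_prop
        else:
            r = th - alpha - beta * gammas - g * (gh - gammas)
            w_prop = v2 + tau_prop**2
            log_ratio = -0.5 * float(
                np.sum(np.log(w_prop) + r**2 / w_prop) - np.sum(np.log(w) + r**2 / w)
            )
            n_prop += 1
            if np.log(rng.uniform()) < log_ratio:
                tau = tau_prop
                n_acc += 1
        if it >= options.burn_in and (it - options.burn_in) % options.thinning == 0:
            out_alpha[kept] = alpha
            out_beta[kept] = beta
            out_tau2[kept] = tau**2
            out_gammas[kept] = gammas
            kept += 1

    chains = McmcChains(
        alpha=out_alpha[:kept],
        beta=out_beta[:kept],
        tau2=out_tau2[:kept],
        gammas=out_gammas[:kept],
        accept_rate_tau=n_acc / n_prop if n_prop else 1.0,
        seed=options.seed,
    )
    tau_draws = np.sqrt(chains.tau2)
    edge = 1e-3 * options.tau_upper
    stuck = max(
        np.mean(tau_draws < edge), np.mean(tau_draws > options.tau_upper - edge)
    )
    if stuck > 0.5:
        chains.warnings.append(
            f"tau chain spent {stuck:.0%} of iterations at a prior boundary"
        )
    if not prior_only and chains.accept_rate_tau < 0.05:
        chains.warnings.append(
            f"low tau acceptance rate ({chains.accept_rate_tau:.2%})"
        )
    return chains


def hpd_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``level`` of the sorted draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    m = x.size
    k = int(np.ceil(level * m))
    k = min(max(k, 1), m)
    widths = x[k - 1 :] - x[: m - k + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k - 1])


def _summarize_draws(draws: np.ndarray, level: float = 0.95) -> ParamSummary:
    lo, hi = np.percentile(draws, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return ParamSummary(
        mean=float(np.mean(draws)),
        median=float(np.median(draws)),
        percentile=(float(lo), float(hi)),
        hpd=hpd_interval(draws, level),
    )


def posterior_summary(chains: McmcChains, level: float = 0.95) -> PosteriorSummary:
    """Means, medians, central percentile intervals and HPD intervals."""
    if chains.n_draws == 0:
        raise ValueError("empty chains")
    params = {
        "alpha": _summarize_draws(chains.alpha, level),
        "beta": _summarize_draws(chains.beta, level),
        "tau2": _summarize_draws(chains.tau2, level),
    }
    for i in range(chains.gammas.shape[1]):
        params[f"gamma_{i + 1}"] = _summarize_draws(chains.gammas[:, i], level)
    return PosteriorSummary(params=params, n_draws=chains.n_draws, seed=chains.seed)


def rhat(chain_list: list[np.ndarray]) -> float:
    """Gelman-Rubin potential scale reduction factor across chains."""
    chains = np.asarray(chain_list, dtype=float)
    m, length = chains.shape
    if m < 2:
        raise ValueError("rhat requires at least two chains")
    means = chains.mean(axis=1)
    between = length * np.var(means, ddof=1)
    within = np.mean(np.var(chains, axis=1, ddof=1))
    var_plus = (length - 1) / length * within + between / length
    return float(np.sqrt(var_plus / within))
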