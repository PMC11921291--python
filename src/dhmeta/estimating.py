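"""Maximum-likelihood estimating equations as pure single-step operators.

Each operator applies one estimating equation once, with all other
quantities held at their current values; iteration policy lives in
:mod:`dhmeta.fit`.  The equations are:

* ``gamma_update`` — the generalized-least-squares projection giving the
  model-based MLE of each study's true surrogate effect gamma_i;
* ``alpha_beta_update`` — the weighted-linear-regression-with-offset
  solution for (alpha, beta) under the conditional model of
  theta_hat given gamma_hat;
* ``tau2_update`` — the score equation for the between-study variance,
  rearranged into fixed-point form and truncated at zero;
* ``residuals`` — the signed discrepancies of all equations at a
  candidate parameter state, used to certify that a numerical optimizer
  has genuinely converged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ParameterState, StudyObservation, StudyTable


@dataclass
class EstimatingEquationResiduals:
    """Signed discrepancies of the estimating-equation system.

    ``max_abs`` is zero iff the parameter state is an exact simultaneous
    root (with the tau2 equation understood in its truncated fixed-point
    form tau2 = max(rhs, 0)).
    """

    gamma_residuals: np.ndarray
    alpha_residual: float
    beta_residual: float
    tau2_residual: float

    @property
    def max_abs(self) -> float:
        return float(
            max(
                np.max(np.abs(self.gamma_residuals)),
                abs(self.alpha_residual),
                abs(self.beta_residual),
                abs(self.tau2_residual),
            )
        )


def _gamma_update_arrays(
    table: StudyTable, alpha: float, beta: float, tau2: float
) -> np.ndarray:
    """Vectorized gamma updates for every study at once.

    With per-study marginal covariance [[a, c], [c, d]] (a = sigma^2 +
    tau2, c = rho sigma delta, d = delta^2) and design vector C =
    (beta, 1), the GLS projection of (theta_hat - alpha, gamma_hat) onto
    C reduces, after the determinant cancels in the adjoint form, to

        gamma_i <- [ (beta d - c) (theta_hat - alpha)
                     + (a - beta c) gamma_hat ]
                   / (beta^2 d - 2 beta c + a).
    """
    a = table.sigma**2 + tau2
    c = table.rho * table.sigma * table.delta
    d = table.delta**2
    num = (beta * d - c) * (table.theta_hat - alpha) + (a - beta * c) * table.gamma_hat
    den = beta**2 * d - 2.0 * beta * c + a
    return num / den


def gamma_update(study: StudyObservation, alpha: float, beta: float, tau2: float) -> float:
    """One application of the estimating equation for one study's gamma_i.

    Returns the model-based MLE of gamma_i given (alpha, beta, tau2):
    the GLS projection of (theta_hat_i - alpha, gamma_hat_i) onto the
    design vector (beta, 1) under the inverse marginal covariance,
    evaluated in closed form via the 2x2 adjoint.
    """
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    a = study.sigma**2 + tau2
    c = study.rho * study.sigma * study.delta
    d = study.delta**2
    num = (beta * d - c) * (study.theta_hat - alpha) + (a - beta * c) * study.gamma_hat
    den = beta**2 * d - 2.0 * beta * c + a
    return float(num / den)


def alpha_beta_update(
    table: StudyTable, gammas: np.ndarray, tau2: float
) -> tuple[float, float]:
    """Weighted-least-squares update for (alpha, beta).

    The conditional model of theta_hat_i given gamma_hat_i is a linear
    regression on gamma_i with offset (rho_i sigma_i/delta_i)(gamma_hat_i
    - gamma_i) and variance v_i^2 + tau2.  The update regresses the
    offset-corrected response on gamma_i with weights 1/(v_i^2 + tau2);
    this jointly zeroes the alpha- and beta-score equations.

    Raises
    ------
    ValueError
        If all gammas are identical (singular design).
    """
    gammas = np.asarray(gammas, dtype=float)
    y = table.theta_hat - table.within_gradient * (table.gamma_hat - gammas)
    w = 1.0 / (table.v2 + tau2)
    sw = w.sum()
    gbar = (w * gammas).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (gammas - gbar) ** 2).sum()
    if sxx <= 0:
        raise ValueError("all gamma values identical: singular design for (alpha, beta)")
    beta = (w * (gammas - gbar) * (y - ybar)).sum() / sxx
    alpha = ybar - beta * gbar
    return float(alpha), float(beta)


def tau2_update(table: StudyTable, params: ParameterState) -> tuple[float, float]:
    """One application of the fixed-point estimating equation for tau2.

    Evaluates the rearranged score equation

        tau2_raw = sum_i [ (theta_hat_i - mu_i)^2 - v_i^2 ] / (v_i^2 + tau2)^2
                   / sum_i 1 / (v_i^2 + tau2)^2

    with mu_i = alpha + beta*gamma_i + (rho_i sigma_i/delta_i)
    (gamma_hat_i - gamma_i) at the current parameter state (the current
    ``params.tau2`` supplies the weights on the right-hand side), and
    returns ``(tau2_raw, max(tau2_raw, 0))``.
    """
    params.check_aligned(table)
    g = table.within_gradient
    mu = params.alpha + params.beta * params.gammas + g * (table.gamma_hat - params.gammas)
    r2 = (table.theta_hat - mu) ** 2
    w2 = 1.0 / (table.v2 + params.tau2) ** 2
    raw = float(np.sum((r2 - table.v2) * w2) / np.sum(w2))
    return raw, max(raw, 0.0)


def residuals(table: StudyTable, params: ParameterState) -> EstimatingEquationResiduals:
    """Evaluate all estimating equations at ``params``.

    Returns the signed differences between the current values and one
    application of each estimating equation: gamma_i minus its GLS
    update, (alpha, beta) minus their WLS update, and tau2 minus the
    truncated fixed-point update max(rhs, 0).  A certified ML solution
    has ``max_abs`` below the convergence tolerance; substituting
    numerical optimizer output here removes any doubt about convergence.
    """
    params.check_aligned(table)
    gamma_res = params.gammas - _gamma_update_arrays(
        table, params.alpha, params.beta, params.tau2
    )
    alpha_new, beta_new = alpha_beta_update(table, params.gammas, params.tau2)
    _, tau2_new = tau2_update(table, params)
    return EstimatingEquationResiduals(
        gamma_residuals=gamma_res,
        alpha_residual=float(params.alpha - alpha_new),
        beta_residual=float(params.beta - beta_new),
        tau2_residual=float(params.tau2 - tau2_new),
    )
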