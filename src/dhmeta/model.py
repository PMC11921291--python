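"""Domain types and the exact likelihood of the Daniels-Hughes model.

Notation (per study i):

* ``theta_hat_i`` — estimated treatment effect on the clinical outcome,
  on the log (linear-predictor) scale, with within-study SD ``sigma_i``;
* ``gamma_hat_i`` — estimated effect on the candidate surrogate, with
  within-study SD ``delta_i``;
* ``rho_i`` — within-study correlation of the two estimates.

The within-study model is bivariate normal around the true effects
``(theta_i, gamma_i)`` with known covariance.  Between studies the true
clinical effect is a linear regression on the true surrogate effect,
``theta_i | gamma_i ~ N(alpha + beta * gamma_i, tau2)``.  Marginally,

    (theta_hat_i, gamma_hat_i) ~ N( (alpha + beta*gamma_i, gamma_i),
                                    [[sigma_i^2 + tau2, rho_i sigma_i delta_i],
                                     [rho_i sigma_i delta_i, delta_i^2]] ).

The likelihood admits an exact factorization into the marginal density
of ``gamma_hat_i ~ N(gamma_i, delta_i^2)`` and the conditional density

    theta_hat_i | gamma_hat_i ~ N(mu_i, v_i^2 + tau2),
    mu_i = alpha + beta*gamma_i + (rho_i sigma_i / delta_i)(gamma_hat_i - gamma_i),
    v_i^2 = sigma_i^2 (1 - rho_i^2).

``marginal_loglik`` and ``factorized_loglik`` implement the two routes
independently; their agreement to machine precision is a built-in
correctness oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

_LOG_2PI = float(np.log(2.0 * np.pi))

# Within-study correlations are kept strictly inside (-1, 1) so that the
# conditional variance v^2 = sigma^2 (1 - rho^2) stays positive.
RHO_MARGIN = 1e-6


class AlignmentError(ValueError):
    """Parameter vector and study table have incompatible lengths."""


@dataclass(frozen=True)
class StudyObservation:
    """Aggregate data contributed by one study.

    Parameters
    ----------
    theta_hat
        Estimated treatment effect on the clinical outcome (log scale).
    gamma_hat
        Estimated treatment effect on the surrogate (log scale).
    sigma
        Within-study standard deviation of ``theta_hat`` (> 0).
    delta
        Within-study standard deviation of ``gamma_hat`` (> 0).
    rho
        Within-study correlation between the two estimates, in (-1, 1).
    label
        Study identifier; must be unique within a table.
    """

    theta_hat: float
    gamma_hat: float
    sigma: float
    delta: float
    rho: float
    label: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite([self.theta_hat, self.gamma_hat, self.sigma, self.delta, self.rho]).all():
            raise ValueError(f"non-finite value in study {self.label!r}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0 in study {self.label!r}, got {self.sigma}")
        if self.delta <= 0:
            raise ValueError(f"delta must be > 0 in study {self.label!r}, got {self.delta}")
        if abs(self.rho) >= 1.0 - RHO_MARGIN:
            raise ValueError(
                f"rho must lie in (-1, 1) (margin {RHO_MARGIN}) in study {self.label!r}, got {self.rho}"
            )

    @property
    def v2(self) -> float:
        """Conditional within-study variance sigma^2 (1 - rho^2)."""
        return self.sigma**2 * (1.0 - self.rho**2)

    @property
    def within_gradient(self) -> float:
        """Within-study gradient rho * sigma / delta."""
        return self.rho * self.sigma / self.delta


class StudyTable:
    """Ordered collection of :class:`StudyObservation` records.

    Exposes the columns as numpy arrays (``theta_hat``, ``gamma_hat``,
    ``sigma``, ``delta``, ``rho``, ``v2``, ``within_gradient``) for
    vectorized computation.  Labels must be unique.  Model fits require
    at least three studies (the parameter count n+3 must not exceed the
    observation count 2n).
    """

    def __init__(self, studies: Iterable[StudyObservation]):
        studies = list(studies)
        if not studies:
            raise ValueError("StudyTable requires at least one study")
        labels = [s.label for s in studies]
        if len(set(labels)) != len(labels):
            raise ValueError("study labels must be unique")
        self._studies = studies
        self.theta_hat = np.array([s.theta_hat for s in studies], dtype=float)
        self.gamma_hat = np.array([s.gamma_hat for s in studies], dtype=float)
        self.sigma = np.array([s.sigma for s in studies], dtype=float)
        self.delta = np.array([s.delta for s in studies], dtype=float)
        self.rho = np.array([s.rho for s in studies], dtype=float)
        self.v2 = self.sigma**2 * (1.0 - self.rho**2)
        self.within_gradient = self.rho * self.sigma / self.delta
        self.labels = labels

    @classmethod
    def from_arrays(
        cls,
        theta_hat: Sequence[float],
        gamma_hat: Sequence[float],
        sigma: Sequence[float],
        delta: Sequence[float],
        rho: Sequence[float] | float,
        labels: Sequence[str] | None = None,
    ) -> "StudyTable":
        theta_hat = np.asarray(theta_hat, dtype=float)
        n = len(theta_hat)
        rho_arr = np.broadcast_to(np.asarray(rho, dtype=float), (n,))
        if labels is None:
            labels = [f"study_{i + 1}" for i in range(n)]
        return cls(
            StudyObservation(t, g, s, d, r, lab)
            for t, g, s, d, r, lab in zip(theta_hat, gamma_hat, sigma, delta, rho_arr, labels)
        )

    def __len__(self) -> int:
        return len(self._studies)

    def __iter__(self) -> Iterator[StudyObservation]:
        return iter(self._studies)

    def __getitem__(self, i: int) -> StudyObservation:
        return self._studies[i]

    @property
    def n(self) -> int:
        return len(self._studies)

    def require_fittable(self) -> None:
        """Raise unless n >= 3, the minimum for the n+3 parameter model."""
        if self.n < 3:
            raise ValueError(
                f"model is under-identified with n={self.n} studies: "
                f"{self.n + 3} parameters exceed {2 * self.n} observations"
            )


@dataclass
class ParameterState:
    """Full parameter vector (alpha, beta, tau2, gamma_1..gamma_n).

    ``tau2`` is the conditional between-study variance and is kept
    non-negative (truncation at zero is enforced by the estimators).
    ``gammas`` are the true surrogate effects, aligned with the study
    table order.
    """

    alpha: float
    beta: float
    tau2: float
    gammas: np.ndarray

    def __post_init__(self) -> None:
        self.gammas = np.asarray(self.gammas, dtype=float)
        if self.tau2 < 0:
            raise ValueError(f"tau2 must be >= 0, got {self.tau2}")

    def check_aligned(self, table: StudyTable) -> None:
        if self.gammas.shape != (table.n,):
            raise AlignmentError(
                f"gammas has shape {self.gammas.shape}, expected ({table.n},)"
            )

    def copy(self) -> "ParameterState":
        return ParameterState(self.alpha, self.beta, self.tau2, self.gammas.copy())


@dataclass
class DerivedQuantities:
    """Per-study derived terms of the model at a given parameter state.

    Attributes
    ----------
    v2 : conditional within-study variances sigma_i^2 (1 - rho_i^2).
    within_gradient : rho_i sigma_i / delta_i.
    mu : conditional means mu_i(gamma_hat_i).
    residual : theta_hat_i - mu_i(gamma_hat_i).
    weight_matrix : (n, 2, 2) inverses of the per-study marginal covariances.
    design_vector : the column vector C(beta, 1).
    w1 : first entry of (C' W_i C)^{-1} C' W_i for each study.
    b : bias-adjustment terms, each in [0, 1).
    """

    v2: np.ndarray
    within_gradient: np.ndarray
    mu: np.ndarray
    residual: np.ndarray
    weight_matrix: np.ndarray
    design_vector: np.ndarray
    w1: np.ndarray
    b: np.ndarray = field(repr=False)


def _marginal_cov_terms(table: StudyTable, tau2: float):
    """Entries (a, c, d) of the per-study marginal covariance [[a, c], [c, d]]."""
    a = table.sigma**2 + tau2
    c = table.rho * table.sigma * table.delta
    d = table.delta**2
    return a, c, d


def derive_quantities(table: StudyTable, params: ParameterState) -> DerivedQuantities:
    """Compute all per-study derived terms at ``params``.

    Pure and deterministic.  The weight matrices are the exact inverses
    of the 2x2 marginal covariances, computed by the closed-form adjoint
    (no generic matrix inversion).  ``w1`` uses the adjoint form in
    which the determinant cancels:

        w1_i = (beta d_i^2 - rho_i sigma_i delta_i)
               / (sigma_i^2 + tau2 + beta^2 delta_i^2 - 2 beta rho_i sigma_i delta_i)

    and ``b_i = (beta - rho_i sigma_i/delta_i) * w1_i``, which equals
    (beta delta_i - rho_i sigma_i)^2 / ((beta delta_i - rho_i sigma_i)^2
    + tau2 + v_i^2), hence lies in [0, 1).
    """
    params.check_aligned(table)
    a, c, d = _marginal_cov_terms(table, params.tau2)
    det = a * d - c**2
    n = table.n
    weight = np.empty((n, 2, 2))
    weight[:, 0, 0] = d / det
    weight[:, 0, 1] = -c / det
    weight[:, 1, 0] = -c / det
    weight[:, 1, 1] = a / det

    g = table.within_gradient
    mu = params.alpha + params.beta * params.gammas + g * (table.gamma_hat - params.gammas)
    beta = params.beta
    denom = a + beta**2 * d - 2.0 * beta * c  # sigma^2 + tau2 + beta^2 delta^2 - 2 beta rho sigma delta
    w1 = (beta * d - c) / denom
    b = (beta - g) * w1
    return DerivedQuantities(
        v2=table.v2.copy(),
        within_gradient=g.copy(),
        mu=mu,
        residual=table.theta_hat - mu,
        weight_matrix=weight,
        design_vector=np.array([params.beta, 1.0]),
        w1=w1,
        b=b,
    )


def marginal_loglik(table: StudyTable, params: ParameterState) -> float:
    """Exact log-likelihood under the marginal bivariate-normal model.

    Sum over studies of the bivariate normal log density of
    ``(theta_hat_i, gamma_hat_i)`` with mean ``(alpha + beta*gamma_i,
    gamma_i)`` and covariance ``[[sigma_i^2 + tau2, rho_i sigma_i
    delta_i], [., delta_i^2]]``.  The quadratic form uses the closed-form
    2x2 adjoint.
    """
    params.check_aligned(table)
    a, c, d = _marginal_cov_terms(table, params.tau2)
    det = a * d - c**2
    if np.any(det <= 0):
        raise FloatingPointError("non-positive-definite per-study covariance")
    e1 = table.theta_hat - (params.alpha + params.beta * params.gammas)
    e2 = table.gamma_hat - params.gammas
    quad = (d * e1**2 - 2.0 * c * e1 * e2 + a * e2**2) / det
    return float(np.sum(-_LOG_2PI - 0.5 * np.log(det) - 0.5 * quad))


def factorized_loglik(table: StudyTable, params: ParameterState) -> float:
    """Log-likelihood via the marginal-times-conditional factorization.

    Sum of the log density of ``gamma_hat_i ~ N(gamma_i, delta_i^2)``
    and of ``theta_hat_i | gamma_hat_i ~ N(mu_i, v_i^2 + tau2)``.
    Algebraically identical to :func:`marginal_loglik`; serves as its
    independent oracle.
    """
    params.check_aligned(table)
    g = table.within_gradient
    mu = params.alpha + params.beta * params.gammas + g * (table.gamma_hat - params.gammas)
    w = table.v2 + params.tau2
    d2 = table.delta**2
    ll_gamma = -0.5 * (_LOG_2PI + np.log(d2) + (table.gamma_hat - params.gammas) ** 2 / d2)
    ll_theta = -0.5 * (_LOG_2PI + np.log(w) + (table.theta_hat - mu) ** 2 / w)
    return float(np.sum(ll_gamma) + np.sum(ll_theta))
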