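"""CSV input/output, sensitivity analysis and synthetic fixtures.

Study tables are UTF-8 CSV files with header columns ``study``,
``theta_hat``, ``se_theta``, ``gamma_hat``, ``se_gamma`` and an
optional ``rho`` column.  Effects are required on the log
(linear-predictor) scale; hazard- or odds-ratio columns must be
log-transformed at read time (see the ``--hazard-ratio`` CLI flag).
A missing ``rho`` column with no shared value is an error — choosing
the within-study correlations is a modeling decision that must never
silently default to zero.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fit import FitOptions, FitResult, fit_adjusted, fit_mle
from .model import StudyTable
from .simulate import SimulationScenario, simulate_dataset

REQUIRED_COLUMNS = ("study", "theta_hat", "se_theta", "gamma_hat", "se_gamma")


class SchemaError(ValueError):
    """The input file does not match the study-table schema."""


def _check_numeric(df: pd.DataFrame, col: str) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1
        raise SchemaError(f"non-numeric value in column {col!r}, row {row}")
    return vals.to_numpy(dtype=float)


def read_study_table(
    path, shared_rho: float | None = None, log_transform: bool = False
) -> StudyTable:
    """Read and validate a study table from CSV.

    ``shared_rho``, when given, overrides or fills the within-study
    correlation for every study.  ``log_transform=True`` natural-logs
    the effect columns (for files reporting hazard/odds ratios); the
    standard errors are taken as already on the log scale.

    Raises
    ------
    SchemaError
        Missing column, non-numeric cell, non-positive standard error,
        correlation outside (-1, 1), or no correlation available at
        all; messages name the offending row and column.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    theta = _check_numeric(df, "theta_hat")
    se_theta = _check_numeric(df, "se_theta")
    gamma = _check_numeric(df, "gamma_hat")
    se_gamma = _check_numeric(df, "se_gamma")
    for col, se in (("se_theta", se_theta), ("se_gamma", se_gamma)):
        bad = se <= 0
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise SchemaError(f"{col} must be > 0, row {row}")
    if log_transform:
        if (theta <= 0).any() or (gamma <= 0).any():
            raise SchemaError("ratio columns must be positive to log-transform")
        theta = np.log(theta)
        gamma = np.log(gamma)
    if shared_rho is not None:
        rho = np.full(len(df), float(shared_rho))
    elif "rho" in df.columns:
        rho = _check_numeric(df, "rho")
    else:
        raise SchemaError(
            "no within-study correlation: provide a 'rho' column or a shared value"
        )
    bad = np.abs(rho) >= 1
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1
        raise SchemaError(f"rho must lie in (-1, 1), row {row}")
    labels = df["study"].astype(str).tolist()
    return StudyTable.from_arrays(theta, gamma, se_theta, se_gamma, rho, labels)


def write_study_table(table: StudyTable, path) -> None:
    """Write a study table as CSV at full precision (round-trip safe)."""
    df = pd.DataFrame(
        {
            "study": table.labels,
            "theta_hat": table.theta_hat,
            "se_theta": table.sigma,
            "gamma_hat": table.gamma_hat,
            "se_gamma": table.delta,
            "rho": table.rho,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def run_sensitivity(
    table: StudyTable,
    rho_values: list[float],
    method: str = "adjusted",
    options: FitOptions | None = None,
) -> tuple[pd.DataFrame, dict[float, FitResult]]:
    """Refit with the shared within-study correlation swapped per value.

    Returns a results grid (one row per rho: estimates, intervals, and
    the fitted range of within-study gradients rho*sigma_i/delta_i) and
    the underlying :class:`FitResult` objects.  Fit errors are
    annotated with the offending rho.
    """
    fitter = {"mle": fit_mle, "adjusted": fit_adjusted}[method]
    rows = []
    fits: dict[float, FitResult] = {}
    for rho in rho_values:
        if not -1 < rho < 1:
            raise ValueError(f"rho must lie in (-1, 1), got {rho}")
        refit_table = StudyTable.from_arrays(
            table.theta_hat, table.gamma_hat, table.sigma, table.delta, rho, table.labels
        )
        try:
            fit = fitter(refit_table, options)
        except Exception as exc:
            raise RuntimeError(f"fit failed at rho={rho}: {exc}") from exc
        fits[rho] = fit
        grad = refit_table.within_gradient
        rows.append(
            {
                "rho": rho,
                "method": method,
                "alpha": fit.estimates.alpha,
                "alpha_low": fit.wald_intervals["alpha"][0],
                "alpha_high": fit.wald_intervals["alpha"][1],
                "beta": fit.estimates.beta,
                "beta_low": fit.wald_intervals["beta"][0],
                "beta_high": fit.wald_intervals["beta"][1],
                "tau2": fit.estimates.tau2,
                "within_gradient_min": float(grad.min()),
                "within_gradient_max": float(grad.max()),
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows), fits


# Synthetic fixture shapes.  These emulate the scale of typical oncology
# surrogate-endpoint meta-analyses (a handful of trials reporting log
# hazard ratios with moderate standard errors, versus a large review of
# log odds/hazard ratio pairs); they are generated from the model and
# are not real trial data.
_FIXTURE_SHAPES = {
    # 6 studies, PFS/OS-like log hazard ratios, shared positive rho
    "example1_like": dict(
        n=6, alpha=0.1, beta=0.8, tau2=0.02, rho=0.513,
        gamma_center=-0.55, gamma_spread=0.25, se_low=0.1, se_high=0.3,
    ),
    # 42 studies, response-rate log OR vs OS log HR, negative rho
    "example2_like": dict(
        n=42, alpha=-0.09, beta=-0.2, tau2=0.005, rho=-0.5,
        gamma_center=0.45, gamma_spread=0.45, se_low=0.08, se_high=0.35,
    ),
}


def make_fixture(kind: str, seed: int = 0, path=None) -> StudyTable:
    """Generate a synthetic study table with a named shape.

    ``kind`` is ``example1_like`` (6 studies), ``example2_like`` (42
    studies) or ``scenario`` (one n=20 data set from the central
    simulation scenario).  Deterministic given ``seed``; written as CSV
    when ``path`` is given (byte-identical for identical seeds).
    """
    if kind == "scenario":
        scenario = SimulationScenario(
            beta=0.8, rho=0.0, tau2=1.0, alpha=0.0, base_seed=seed
        )
        table, _ = simulate_dataset(scenario, 0)
    else:
        try:
            shape = _FIXTURE_SHAPES[kind]
        except KeyError:
            raise ValueError(f"unknown fixture kind {kind!r}") from None
        rng = np.random.default_rng(seed)
        n = shape["n"]
        gammas = rng.normal(shape["gamma_center"], shape["gamma_spread"], n)
        sigma = rng.uniform(shape["se_low"], shape["se_high"], n)
        delta = rng.uniform(shape["se_low"], shape["se_high"], n)
        rho = np.full(n, shape["rho"])
        g = rho * sigma / delta
        v2 = sigma**2 * (1 - rho**2)
        gamma_hat = gammas + delta * rng.standard_normal(n)
        theta_hat = (
            shape["alpha"]
            + shape["beta"] * gammas
            + g * (gamma_hat - gammas)
            + np.sqrt(v2 + shape["tau2"]) * rng.standard_normal(n)
        )
        table = StudyTable.from_arrays(theta_hat, gamma_hat, sigma, delta, rho)
    if path is not None:
        write_study_table(table, Path(path))
    return table
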