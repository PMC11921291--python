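"""Full fits, bias adjustment, standard errors and Wald intervals."""

import numpy as np
import pytest

from dhmeta.estimating import residuals, tau2_update
from dhmeta.fit import (
    FitOptions,
    bias_terms,
    fit_adjusted,
    fit_mle,
    numerical_hessian,
    standard_errors,
    tau2_adjusted_update,
    wald_interval,
)
from dhmeta.model import ParameterState, StudyTable, derive_quantities
from dhmeta.simulate import SimulationScenario, simulate_dataset

from conftest import random_table


class TestBiasTerms:
    def test_zero_when_gradients_match(self, rng):
        table = random_table(rng, n=5)
        # per-study beta = within gradient would zero each b; use a shared-rho
        # table where the gradient is constant across studies
        n = 4
        shared = StudyTable.from_arrays(
            rng.normal(size=n), rng.normal(size=n), [0.8] * n, [0.4] * n, 0.6
        )
        beta = 0.6 * 0.8 / 0.4  # rho * sigma / delta
        np.testing.assert_allclose(bias_terms(shared, beta, tau2=0.7), 0.0, atol=1e-14)

    def test_half_for_unit_mismatch(self):
        table = StudyTable.from_arrays([0.0], [0.0], [1.0], [1.0], 0.0)
        assert bias_terms(table, beta=1.0, tau2=0.0)[0] == pytest.approx(0.5)

    def test_two_formula_cross_check_and_range(self, rng):
        # closed form (beta*delta - rho*sigma)^2 / (... + tau2 + v^2) must equal
        # (beta - rho*sigma/delta) * w1 with w1 from the explicit adjoint formula
        for _ in range(200):
            n = 5
            table = random_table(rng, n=n)
            beta = rng.normal()
            tau2 = rng.uniform(0, 3)
            b = bias_terms(table, beta, tau2)
            dq = derive_quantities(
                table, ParameterState(0.0, beta, tau2, np.zeros(n))
            )
            np.testing.assert_allclose(b, (beta - table.within_gradient) * dq.w1, atol=1e-12)
            assert np.all(b >= 0) and np.all(b < 1)


class TestTau2AdjustedUpdate:
    def test_reduces_to_unadjusted_when_b_zero(self, rng):
        n = 4
        table = StudyTable.from_arrays(
            rng.normal(size=n), rng.normal(size=n), [0.5] * n, [0.5] * n, 0.4
        )
        params = ParameterState(0.1, 0.4, 0.3, rng.normal(size=n))  # beta = rho*sigma/delta
        raw_adj, _ = tau2_adjusted_update(table, params)
        raw, _ = tau2_update(table, params)
        assert raw_adj == pytest.approx(raw, abs=1e-12)

    def test_never_below_unadjusted(self, rng):
        for _ in range(100):
            table = random_table(rng, n=6)
            params = ParameterState(
                rng.normal(), rng.normal(), rng.uniform(0, 2), rng.normal(0, 2, 6)
            )
            raw_adj, _ = tau2_adjusted_update(table, params)
            raw, _ = tau2_update(table, params)
            assert raw_adj >= raw - 1e-12

    def test_single_study_inflation(self):
        # b = 0.5, v^2 = 1: default power 1 gives 2 r^2 - 1; power 2 gives 4 r^2 - 1
        table = StudyTable.from_arrays([1.3], [0.0], [1.0], [1.0], 0.0)
        params = ParameterState(0.0, 1.0, 0.0, np.zeros(1))
        r2 = 1.3**2  # mu = 0 at these parameters
        raw, _ = tau2_adjusted_update(table, params)
        assert raw == pytest.approx(2.0 * r2 - 1.0)
        raw2, _ = tau2_adjusted_update(table, params, power=2.0)
        assert raw2 == pytest.approx(4.0 * r2 - 1.0)


class TestFitMle:
    def test_certified_on_simulated_data(self, scenario_table):
        table, _ = scenario_table
        fit = fit_mle(table)
        assert fit.converged
        assert fit.ee_max_abs < 1e-6
        assert residuals(table, fit.estimates).max_abs < 1e-6

    def test_under_identified_raises(self):
        table = StudyTable.from_arrays([0.1, 0.2], [0.3, 0.4], [1, 1], [1, 1], 0.0)
        with pytest.raises(ValueError, match="under-identified"):
            fit_mle(table)

    def test_truncation_to_zero(self):
        # tau2 = 0 truth with tight within-study variances often truncates
        scenario = SimulationScenario(beta=0.4, rho=0.4, tau2=0.0, alpha=0.0, base_seed=5)
        hits = 0
        for rep in range(5):
            table, _ = simulate_dataset(scenario, rep)
            fit = fit_mle(table)
            assert fit.converged
            assert fit.estimates.tau2 >= 0
            hits += fit.tau2_truncated
        assert hits > 0  # at least one boundary solution among the replicates

    def test_interval_contains_estimate(self, scenario_table):
        table, _ = scenario_table
        fit = fit_mle(table)
        for name in ("alpha", "beta"):
            lo, hi = fit.wald_intervals[name]
            assert lo <= getattr(fit.estimates, name) <= hi


class TestFitAdjusted:
    def test_matches_mle_when_gradients_match(self):
        # beta = rho = 0.8 with sigma=delta: within and between gradients agree,
        # so b ~ 0 and the adjustment changes little; contrast with the
        # mismatched beta=0.8, rho=0 case at the same seed
        matched = SimulationScenario(beta=0.8, rho=0.8, tau2=0.5, alpha=0.0, base_seed=11)
        mismatched = SimulationScenario(beta=0.8, rho=0.0, tau2=0.5, alpha=0.0, base_seed=11)
        diffs = {}
        for name, scen in (("matched", matched), ("mismatched", mismatched)):
            gaps = []
            for rep in range(5):
                table, _ = simulate_dataset(scen, rep)
                mle = fit_mle(table)
                adj = fit_adjusted(table)
                gaps.append(abs(adj.estimates.tau2 - mle.estimates.tau2))
            diffs[name] = np.mean(gaps)
        assert diffs["matched"] < diffs["mismatched"]
        assert diffs["matched"] < 0.05

    def test_single_pass_mode(self, scenario_table):
        table, _ = scenario_table
        it = fit_adjusted(table, FitOptions(method="adjusted", adjusted_mode="iterate"))
        sp = fit_adjusted(table, FitOptions(method="adjusted", adjusted_mode="single_pass"))
        assert it.converged and sp.converged
        # single pass stops after one update, so it adjusts no further than the fixed point
        assert sp.estimates.tau2 <= it.estimates.tau2 + 1e-8

    def test_adjusted_never_smaller_than_mle_tau2(self, rng):
        for rep in range(4):
            scenario = SimulationScenario(beta=0.8, rho=0.0, tau2=1.0, alpha=0.25, base_seed=3)
            table, _ = simulate_dataset(scenario, rep)
            mle = fit_mle(table)
            adj = fit_adjusted(table)
            assert adj.estimates.tau2 >= mle.estimates.tau2 - 1e-8


class TestStandardErrors:
    def test_known_variance_normal_mean(self):
        # NLL of n iid N(mu, sigma^2) observations: SE of the mean is sigma/sqrt(n)
        rng = np.random.default_rng(1)
        sigma, n = 0.7, 40
        x = rng.normal(2.0, sigma, n)

        def nll(mu):
            return float(np.sum((x - mu[0]) ** 2) / (2 * sigma**2))

        hess = numerical_hessian(nll, np.array([x.mean()]))
        se = 1.0 / np.sqrt(hess[0, 0])
        assert se == pytest.approx(sigma / np.sqrt(n), abs=1e-4)

    def test_boundary_equivalence_of_generalized_inverse(self):
        # when tau2_hat = 0, dropping the log tau2 coordinate must agree with
        # the eigen-truncated pinv of the full Hessian at log tau2 -> -inf
        scenario = SimulationScenario(beta=0.4, rho=0.4, tau2=0.0, alpha=0.0, base_seed=5)
        table = None
        for rep in range(10):
            cand, _ = simulate_dataset(scenario, rep)
            fit = fit_mle(cand)
            if fit.tau2_truncated:
                table = cand
                break
        assert table is not None
        fit = fit_mle(table)
        ses = fit.standard_errors
        assert ses["log_tau2"] is None

        from dhmeta.fit import _eigen_pinv, _nll_and_grad

        x = np.concatenate(
            ([fit.estimates.alpha, fit.estimates.beta, -40.0], fit.estimates.gammas)
        )

        def f(z):
            return _nll_and_grad(z, table)[0]

        hess = numerical_hessian(f, x)
        cov = _eigen_pinv(hess)
        assert np.sqrt(cov[0, 0]) == pytest.approx(ses["alpha"], abs=1e-6)
        assert np.sqrt(cov[1, 1]) == pytest.approx(ses["beta"], abs=1e-6)

    def test_se_calibration_against_empirical_sd(self):
        # With the design held fixed across replicates (same gammas) and the
        # within- and between-study gradients matched (beta = rho, sigma =
        # delta, so the tau2 estimate is nearly unbiased), the inverse-Hessian
        # SE(beta_hat) must track the sampling SD of beta_hat.  Redrawing the
        # design or mismatching the gradients breaks this on purpose: the
        # latter is the undercoverage phenomenon tested in test_acceptance.
        scenario = SimulationScenario(
            beta=0.4, rho=0.4, tau2=0.5, alpha=0.0, base_seed=17, fixed_gammas=True
        )
        betas, ses = [], []
        for rep in range(200):
            table, _ = simulate_dataset(scenario, rep)
            fit = fit_mle(table)
            if fit.converged:
                betas.append(fit.estimates.beta)
                ses.append(fit.standard_errors["beta"])
        assert len(betas) >= 190
        emp_sd = np.std(betas, ddof=1)
        assert np.mean(ses) == pytest.approx(emp_sd, rel=0.1)

    def test_rejects_non_optimum(self, scenario_table):
        table, _ = scenario_table
        fit = fit_mle(table)
        bad = fit.estimates.copy()
        bad.gammas = bad.gammas + np.linspace(-3, 3, table.n)
        # far from the optimum the Hessian need not be PSD; either a diagnostic
        # error or a PSD Hessian is acceptable, but no silent nonsense
        try:
            standard_errors(table, bad)
        except FloatingPointError:
            pass


class TestWaldInterval:
    def test_standard_normal_quantile(self):
        lo, hi = wald_interval(0.0, 1.0, 0.95)
        assert lo == pytest.approx(-1.959964, abs=1e-6)
        assert hi == pytest.approx(1.959964, abs=1e-6)

    def test_level_collapse(self):
        lo, hi = wald_interval(0.7, 2.0, 1e-12)
        assert lo == pytest.approx(0.7, abs=1e-9)
        assert hi == pytest.approx(0.7, abs=1e-9)

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            wald_interval(0.0, -1.0, 0.95)
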