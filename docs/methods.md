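# Methods

This note records the statistical model, the estimation procedures, the
numerical choices behind them, and what the simulation-backed tests do and
do not establish.

## Model and likelihood

Per study *i*, the observed pair (θ̂ᵢ, γ̂ᵢ) — effect on the clinical
outcome and on the surrogate, both on the log (linear-predictor) scale —
is bivariate normal around the true effects (θᵢ, γᵢ) with known
within-study covariance (variances σᵢ², δᵢ², correlation ρᵢ).  Across
studies, θᵢ | γᵢ ~ N(α + βγᵢ, τ²).  The marginal model is

    (θ̂ᵢ, γ̂ᵢ) ~ N₂( (α + βγᵢ, γᵢ), [[σᵢ² + τ², ρᵢσᵢδᵢ], [ρᵢσᵢδᵢ, δᵢ²]] ),

with free parameters (α, β, τ², γ₁…γₙ): n + 3 parameters against 2n
observations, so fits require n ≥ 3.  The likelihood factorizes exactly
into γ̂ᵢ ~ N(γᵢ, δᵢ²) times

    θ̂ᵢ | γ̂ᵢ ~ N(μᵢ, vᵢ² + τ²),
    μᵢ = α + βγᵢ + gᵢ(γ̂ᵢ − γᵢ),  gᵢ = ρᵢσᵢ/δᵢ,  vᵢ² = σᵢ²(1 − ρᵢ²).

Both routes are implemented independently (`marginal_loglik`,
`factorized_loglik`) and their agreement to 1e−10 is asserted on random
instances; all 2×2 inversions use the closed-form adjoint, in which the
determinant cancels wherever ratios are formed.  gᵢ is the
**within-study gradient** (the slope of E[θ̂ᵢ | γ̂ᵢ] in study *i*) and β
the **between-study gradient**; their mismatch drives everything below.

## Estimating equations and certified ML

Setting the score to zero gives, per study, a GLS projection for γᵢ onto
the design vector (β, 1); a weighted linear regression with offset
gᵢ(γ̂ᵢ − γᵢ) and weights 1/(vᵢ² + τ²) for (α, β); and the fixed-point
equation

    τ̂² = Σᵢ[(θ̂ᵢ − μ̂ᵢ)² − vᵢ²]/(vᵢ² + τ̂²)² ÷ Σᵢ 1/(vᵢ² + τ̂²)²,

truncated at zero when negative.  `fit_mle` runs L-BFGS with the analytic
gradient over (α, β, log τ², γ₁…γₙ), then *polishes* by cycling the three
estimating-equation updates until the maximum absolute residual of the
system falls below tolerance (default 1e−8).  The polishing step matters
at the τ̂² = 0 boundary, where log τ² drifts to large negative values on a
flat likelihood and a quasi-Newton stop alone cannot certify the root; a
solution truncated at zero is accepted once the τ² update returns zero
twice consecutively and the remaining residuals are below tolerance.
Certification failure triggers up to three jittered restarts and is
reported, never silently accepted.  Fitted τ² below 1e−8 is declared
exactly zero.

Standard errors come from the central-difference Hessian (relative step
1e−5) of the negative log-likelihood in the (α, β, log τ², γ)
parameterization, inverted by eigen-truncated generalized inverse
(relative tolerance 1e−10).  When τ̂² = 0 — or in the adjusted analysis,
which treats τ² as known — the log τ² coordinate is dropped, which is
numerically equivalent to constraining τ² at its fitted value.  Wald
intervals use exact normal quantiles.  No interval is produced for τ²:
Wald theory is unreliable for variance components and a defensible
interval construction for this model is an open problem.

## The bias-adjusted τ² estimator

Because each γᵢ must be estimated from data that carry a fixed amount of
information about it, the ML estimator of τ² is biased downward
(an incidental-parameters / Neyman–Scott effect).  Writing the plug-in
MLE of γᵢ at fixed (α, β, τ²), a short calculation gives

    θ̂ᵢ − μ̂ᵢ = (1 − bᵢ)(θ̂ᵢ − α − βγ̂ᵢ),
    bᵢ = (βδᵢ − ρᵢσᵢ)² / ((βδᵢ − ρᵢσᵢ)² + τ² + vᵢ²) ∈ [0, 1),

so the residual entering the τ² equation is shrunk by (1 − bᵢ).  The
squared shrunk residual has expectation

    E[(θ̂ᵢ − μ̂ᵢ)²] = (1 − bᵢ)² [vᵢ² + τ² + (βδᵢ − ρᵢσᵢ)²] = (1 − bᵢ)(vᵢ² + τ²):

one power of (1 − bᵢ) survives because θ̂ᵢ − α − βγ̂ᵢ itself has variance
inflated by the gradient mismatch, by exactly (βδᵢ − ρᵢσᵢ)².  The
adjusted estimating equation therefore inflates each squared residual by
**(1 − bᵢ)⁻¹**, which makes it exactly unbiased when evaluated at the true
(α, β, τ²); the Monte-Carlo tests verify this identity, and also that the
superficially natural (1 − bᵢ)⁻² inflation (undoing the residual
shrinkage factor squared) overshoots by (βδᵢ − ρᵢσᵢ)² per study.  The
exponent is exposed as `tau2_adjusted_update(..., power=...)` with default
1; `power=2` is retained only for comparison.  Since (1 − bᵢ)⁻ᵖ ≥ 1, the
adjusted estimate can never fall below the unadjusted one at the same
parameter values, and bᵢ = 0 — no adjustment — exactly when β = gᵢ, i.e.
when the dependence of the clinical outcome on the surrogate is the same
within and between studies.

`fit_adjusted` starts at the MLE and alternates (a) the adjusted τ²
update with (b) constrained ML for (α, β, γ) at the updated τ² (exact
block coordinate ascent: both updates are closed-form conditional
maximizers) until the τ² change falls below tolerance; truncation at zero
is terminal after two consecutive zero updates.  This joint fixed point
is the default because the adjusted equation carries τ̂² on its own
right-hand side; a `single_pass` mode (one evaluation at the MLE, one
constrained refit) is provided since the two readings are equally
defensible.  Standard errors for (α, β) treat τ̂²_adjusted as known — the
usual meta-analytic approximation.

## Bayesian comparator

Priors: α, β, γᵢ ~ N(0, 1000) and τ ~ U(0, 2) (a uniform prior on the
between-study SD), with ρᵢ fixed at their supplied values.  Under the
factorized likelihood the full conditionals of α, β and each γᵢ are
normal, so they are drawn exactly; τ uses a reflecting random-walk
Metropolis step of size 0.1·(upper bound) on (0, 2).  Defaults: burn-in
1000, 10,000 retained draws at thinning 2, single chain (a split-chain
R-hat helper is provided).  Summaries report posterior means, medians,
central 95% percentile intervals and shortest-window HPD intervals —
means and percentile intervals for bias/coverage comparisons, medians and
HPD intervals because the τ² marginal is right-skewed in small meta-
analyses.  A `prior_only` switch disables the likelihood for
prior-predictive checks.  The sampler is deliberately dependency-free and
bit-reproducible given a seed.

## Simulation engine and what green tests establish

The design grid crosses β ∈ {0, 0.4, 0.8}, shared ρ ∈ {0, 0.4, 0.8},
τ² ∈ {0, 0.5, 1} and α ∈ {0, 0.25} (54 cells); every data set has n = 20
studies, γᵢ ~ U(−5, 5) redrawn each replicate (a `fixed_gammas` option
freezes the design for conditional checks), and within-study variances
σᵢ² = δᵢ² = 0.05·i for study i = 1…20, fixed across replicates.  The
20-value variance grid is assigned one value per study within every data
set; this is an interpretation of a genuinely ambiguous design sentence,
adopted because it is the only reading consistent with a 54-cell grid.
Seeding is counter-based (master seed × scenario index × replicate
index), so any replicate is reproducible in isolation.

The generator emulates the stated simulation world, not real data: known
within-study covariances, exactly normal errors, a shared ρ, and no
selective reporting, missingness or correlation between effect size and
precision.  A green simulation test therefore establishes internal
correctness of the estimators under the model's own assumptions — not
robustness to the ways real meta-analytic data violate them.

Reduced-scale findings the tests assert (300 replicates, fixed seeds):
at τ² = 1, β = 0.8, ρ = 0 the ML τ̂² is biased downward and the adjusted
estimator's absolute bias is strictly smaller, with higher Wald coverage
for β; across the positive-τ² subgrid the minimum ML Wald coverage for α
and β (nominal 0.95) falls below 0.8, with the worst cells at the largest
gradient mismatch (β = 0 against gᵢ = 0.8).  The acceptance script
recomputes that minimum over the full 36-cell positive-τ² subgrid.
Monte-Carlo identity checks (10,000 replicates) verify known-parameter
unbiasedness of the τ² equation at τ² ∈ {0.5, 1} and the shrinkage
expectation identity above, at 3 MC standard errors on study-averaged
quantities (per-study checks use a Bonferroni-safe 4.5 SE band).

## Known limitations

* Within-study correlations are inputs; the package neither estimates
  them from individual patient data nor places priors on them.  The
  sensitivity-analysis verb is the intended workflow when they are
  unknown.
* No confidence interval for τ²; no prediction intervals, I² or Bayes
  factors; single surrogate and single treatment class only.
* Wald intervals for (α, β) remain anti-conservative when τ² > 0 even
  after adjustment (coverage ≈ 0.9 in the hardest cells): the adjustment
  removes most, not all, of the incidental-parameter bias, and the
  adjusted SEs treat τ̂² as known.
* The inverse-Hessian standard errors are calibrated conditionally on the
  study design (verified to 2% with a fixed design and matched
  gradients); unconditional sampling SDs over redrawn designs are larger.
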