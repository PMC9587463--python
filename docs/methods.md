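# Methods

## Performance curve model

Expected performance of one genotype (full-sib family) at daytime
temperature x is a mode-normalized Kumaraswamy curve on the interval
between the critical thermal minimum L and maximum U:

    t      = (x − L) / (U − L)
    g(t)   = a·b·t^(a−1)·(1 − t^a)^(b−1)
    t*     = ((a − 1)/(a·b − 1))^(1/a)
    P(x)   = h·g(t)/g(t*)  on (L, U),  0 otherwise.

Both shapes are constrained > 1, which is exactly the condition for an
interior mode, so every curve is unimodal with peak value h (directly
interpretable as maximal expected RGR) at T_opt = L + t*·(U − L). The
normalization makes h orthogonal to the shape parameters; the widely used
zero-inflated Kumaraswamy performance model that inspired this choice is
parameterized differently, so fitted shape values are not directly
transferable between implementations, though T_opt and breadth — the
quantities all downstream analysis uses — are defined identically.

Thermal breadth (B50) is the span over which P(x) ≥ 0.5·h. The two
crossings, one on each side of T_opt, are unique by unimodality and are
found by bisection (bracketed by (L, T_opt) and (T_opt, U), tolerance
1e-6 °C). Each bound is clipped independently to the nearest measured
temperature (15 or 50 °C by default) so breadth never extrapolates beyond
the experiment; the fraction of clipped family×draw bounds is reported as
`truncation_rate`.

## Observation model

RGR is continuous, non-negative, and shows excess exact zeros near the
thermal limits. An observation y at temperature x with expected value
μ = P(x) is modeled as

    y = 0                         with prob. π = inv_logit(γ0 + γ1·μ)
    y ~ Normal(μ, σ) trunc (0,∞)  otherwise,

with γ1 ≤ 0 so zeros concentrate where expected performance is low. σ has
a hard floor of 1e-3 (scaled units) to guard the degenerate density spike
at σ → 0. Truncated-normal residuals were chosen because mid-range RGR is
approximately symmetric; the simulator exposes the same observation model
so fits can be checked against generating truth.

## Hierarchy, priors, preprocessing

One model per population; families are exchangeable draws from
population-level distributions on the unconstrained scale
z = (L, log(U−L), log(a−1), log(b−1), log h):

    z_f = μ_pop + s_pop ⊙ η_f,    η_f ~ N(0, I)   (non-centered).

Any real z maps to a valid curve, which keeps both simulated families and
MCMC proposals in-domain.

Before fitting, temperatures are centered on the grand mean of the regime
temperatures (32.5 °C for the default 15–50 ladder, the same center for
every population) and RGR is divided by the population mean of its
positive values. All reported parameters are back-transformed to °C and
raw RGR units.

Priors (on the centered/scaled space): population CT_min ~ Normal(16 °C,
3) and CT_max ~ Normal(51 °C, 3) — weakly informative anchors just outside
the measured window; Normal(0.5, 1) on the population log-shape and
log-height means; half-normal on among-family scales, with SD 5 for the
location scale (which is in °C — observed among-family SDs of T_opt reach
~3.5 °C, and a unit-scale prior there would shrink genuine variation) and
SD 1 for the log-scale span/shape/height scales; σ ~ HalfNormal(1),
γ0 ~ Normal(−2, 2), log(−γ1) ~ Normal(1, 1.5).

## Sampler

The posterior is sampled with differential-evolution ensemble MCMC
(emcee; 80% DE moves, 20% snooker), 3 walkers per dimension, initialized
by jittering an L-BFGS posterior mode. `FitConfig` defaults to 6000
iterations (first half warmup) and subsamples the retained ensemble to
exactly `chains × (iterations − warmup)` draws; the reduced profile (3000
iterations, 2 chains) is used by the test suite and the `--reduced` CLI
flag. HMC-style controls (`adapt_delta`, `max_tree_depth`) are accepted
for configuration compatibility and logged as not applicable to this
backend.

Convergence is summarized by split-R-hat and bulk ESS (arviz) over
walkers-as-chains, for all population-level parameters and per-family
T_opt chains. R-hat > 1.01 or family-level ESS < 700 triggers a warning —
never a silent pass and never a hard failure, since ensemble walkers mix
slowly by HMC standards while posterior means and intervals of the
data-dominated family-level quantities stabilize much earlier (parameter
recovery and CI coverage are verified directly in the acceptance tests).

Model adequacy uses a posterior-predictive p-value with a chi-square-type
discrepancy: the sum of squared Pearson residuals of the positive
observations plus the squared gap between observed and expected zero
counts. Ties count toward the replicate. The discrepancy is one of several
defensible choices; it is isolated in one function so alternatives can be
compared.

## Derived quantities

Per draw and family: T_opt (analytic mode) and B50 bounds (clipped).
Population breadth is the envelope: max family upper bound − min family
lower bound, per draw. Genetic variation is the among-family sample
variance (denominator n−1) of T_opt and of B50 within each draw. The
family-breadth table column is the per-draw across-family mean, so it
carries one credible interval per population, matching how the summary
table is printed. All summaries are posterior means with central 2.5/97.5
percentile intervals ("range within which 95% of values fell"). With a
single family the among-family variances are undefined and reported
missing with a warning.

## Hypothesis tests

Three linear mixed models of population breadth with a Normal random
intercept per species pair (REML): predictors are (1) family-level B50
(one observation per family, unweighted, with its population's breadth as
response), (2) among-family variance in T_opt, (3) among-family variance
in B50. Variance components come from statsmodels' MixedLM; the
fixed-effect covariance is then recomputed as (X'V⁻¹X)⁻¹ at the REML
components — the standard mixed-model form, which reproduces the reference
R implementation (lme4) exactly, including near-singular fits where
statsmodels' profiled approximation diverges from it. p-values are
two-sided Wald t with Satterthwaite degrees of freedom obtained from the
curvature of a closed-form REML log-likelihood in (τ², σ²); the
directional decision rule applied on top is slope > 0 with p/2 < α = .1.
Marginal and conditional R² follow the Nakagawa variance partition:
var(Xβ)/(var(Xβ)+τ²+σ²) and (var(Xβ)+τ²)/(same). Standardized fits
z-score response and predictor across all observations, making slopes
comparable across the three predictors.

## Synthetic data

The generator reproduces the study design: 5 pairs × 2 populations, 11–50
families per population (uniform), 8 regimes at 15–50 °C, and 3–6
replicates per family × temperature drawn uniformly to emulate unbalanced
real data (the defaults yield > 5000 individuals per study). Baseline
generating curve: L = 10 °C, U = 47 °C, shapes 2.5, peak RGR 0.2/day,
σ = 0.05, zero-inflation γ0 = −2, γ1 = −25 (per raw RGR unit), giving
~12% zeros at the limits and < 1% at the optimum. Scenarios vary one
generating quantity across the 10 populations: mean span (generalist),
among-family location SD 0.8–3.6 °C (divergent-optima), among-family
log-span SD (variable-breadth), or nothing (null). Deviations are applied
on the unconstrained scale, so every simulated family is valid.

What the simulator does **not** emulate: maternal effects, day/night
temperature cycling, ontogenetic change in breadth, per-family dropout,
or different RGR metrics across pairs. Passing recovery tests therefore
show the estimator is correct under the stated model, not that the model
is correct for any particular greenhouse dataset.

## Problem sizes and numerical choices

The test suite fits reduced problems chosen to exercise every contract
while keeping runs quick: recovery uses 2 pairs × 8 families × 8
temperatures × 3 replicates with the reduced sampler profile; the
null-scenario type-I check uses 50 truth-level replicates (no MCMC, since
the property under test is the mixed-model stage). Bisection tolerance is
1e-6 °C; the dense-grid and Brent-root oracles in the tests are
independent of the production bisection path. Ties in the
posterior-predictive indicator count as exceedances. Degenerate inputs
(σ → 0, single family, constant predictor, empty tables) raise typed
errors or warn, as documented per function.

## Known limitations

- The envelope definition of population breadth (highest family upper B50
  bound minus lowest lower bound) is a monotone functional of the same
  family draws that produce the among-family variance of T_opt. Under
  exchangeable simulations — identical generating parameters for every
  population — realized variance and realized envelope therefore share
  sampling noise, and the variance-in-T_opt regression shows a systematic
  positive slope even with no biological signal (the package's null-
  scenario simulations demonstrate this directly). Observed positive
  envelope-on-variance slopes should be interpreted with this mechanical
  component in mind; contrasts that vary the generating variance (the
  divergent-optima scenario) remain well-behaved because there the signal
  is the estimand.

- The ensemble sampler's walkers-as-chains R-hat is conservative; at
  reduced settings the diagnostic warning is expected even when derived
  summaries have stabilized.
- The exact likelihood and transforms of the reference zero-inflated
  Kumaraswamy implementation are not reproduced; shape-parameter
  posteriors are not comparable across implementations (T_opt and breadth
  are).
- Satterthwaite df relies on finite-difference curvature of the REML
  surface; at the τ² = 0 boundary it falls back to the residual df.
- With 10 populations and 5 pairs the hypothesis models have little power;
  standard errors are honest about this.
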