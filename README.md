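# nichebreadth

How does a population achieve a broad thermal niche? Three non-exclusive
routes are possible: it may consist of general-purpose genotypes that each
tolerate a wide temperature range; of specialized genotypes whose thermal
optima diverge; or of genotypes that vary in how generalized they are.
`nichebreadth` implements a complete, tested pipeline for distinguishing
these routes in family-structured thermal performance experiments — the
kind of growth-chamber study where full-sib seed families from each of
several populations are grown across a ladder of temperature regimes and a
performance metric (here relative growth rate, RGR) is recorded per plant.

The pipeline has four stages, each usable on its own:

1. **Thermal performance curves** (`nichebreadth.tpc`). Each genotype's
   expected performance is a mode-normalized Kumaraswamy curve on
   (CT_min, CT_max): with t = (x − L)/(U − L),

       P(x) = h · g(t)/g(t*),   g(t) = a·b·t^(a−1)·(1 − t^a)^(b−1),

   which is unimodal with maximum h at the thermal optimum
   T_opt = L + t*·(U − L), t* = ((a−1)/(ab−1))^(1/a). Thermal breadth
   (B50) is the temperature span over which P ≥ 0.5·h, with bounds clipped
   to the measured 15–50 °C window to avoid extrapolation.
2. **Hierarchical Bayesian fitting** (`nichebreadth.fit`). One model per
   population, family as the grouping factor; observations are
   zero-inflated (exact zeros concentrate near the thermal limits) with
   truncated-normal residuals. Sampling is ensemble MCMC with R-hat/ESS
   diagnostics and a posterior-predictive p-value as a model-fit check.
3. **Breadth summaries** (`nichebreadth.derived`). Per posterior draw:
   family T_opt and B50, the population *envelope* breadth (highest family
   upper bound minus lowest family lower bound), and among-family variances
   of T_opt and B50 — each summarized as a posterior mean with a central
   95% credible interval.
4. **Hypothesis tests** (`nichebreadth.lmm`). Three linear mixed models of
   population breadth (REML, random intercept per species pair to absorb
   shared ancestry): predictors are family-level breadth, among-family
   variance in T_opt, and among-family variance in B50. Each fit reports
   the slope with a GLS standard error, a Satterthwaite-df Wald p-value,
   Nakagawa marginal/conditional R², and a standardized (z-scored) slope
   for comparing predictors.

A synthetic-data generator (`nichebreadth.simulate`) emulates the full
study design — 5 species pairs × 2 populations, 11–50 families per
population, 8 temperature regimes, zero-inflated non-negative RGR — under
four scenarios (`generalist`, `divergent-optima`, `variable-breadth`,
`null`) with known generating truth, so every stage is testable end to end.

## Worked example

The package ships a summary table of 10 western North American
monkeyflower (*Mimulus*) populations (five closely related species pairs)
with population breadth, mean family breadth, and among-family variances.
Running the two population-level hypothesis models on it:

```python
import nichebreadth as nb

t1 = nb.load_mimulus_table().rename(columns={"species": "population"})
r = nb.fit_pair_lmm(t1.pop_tbreadth, t1.var_topt, t1.pair)
s = nb.standardize_and_fit(t1.pop_tbreadth, t1.var_topt, t1.pair)
print(f"slope={r.slope:.3f} +- {r.slope_se:.3f}, p={r.p_value:.3f}")
print(f"standardized slope={s.slope:.3f}, R2m={r.marginal_r2:.3f}, R2c={r.conditional_r2:.3f}")
```

prints

```
slope=0.508 +- 0.213, p=0.070
standardized slope=0.291, R2m=0.087, R2c=0.931
```

i.e. every unit of among-family variance in T_opt adds about half a degree
of population-level breadth (one-sided p < .1), and this predictor carries
the largest standardized slope of the three — populations appear to accrue
thermal breadth primarily through genotypes with divergent optima. The low
marginal vs high conditional R² says most remaining variation lies between
species pairs. The same models with among-family variance in breadth as
predictor give slope 0.275 ± 0.485 (p = .597): no support for the
variable-breadth route.

A full synthetic run, from simulation through fitting to hypothesis tests
(at the full 10-population, 11–50-families-per-population design this takes
a while even with `--reduced`; shrink the design via a YAML config for a
quick look):

```bash
nichebreadth run --scenario divergent-optima --seed 1 --out results/demo --reduced
nichebreadth report --results results/demo   # per-population curve plots
```

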