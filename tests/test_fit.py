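"""Hierarchical fit: preprocessing, likelihood, sampler contracts, model check."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

import nichebreadth as nb
from nichebreadth.fit import FitConfig, _SIGMA_FLOOR, log_likelihood, preprocess
from nichebreadth.tpc import ParameterError


class TestPreprocess:
    def test_centered_temps_sum_to_zero_per_regime_set(self):
        obs, _ = nb.simulate_population(
            nb.CurveParams(lower=10, upper=47, shape_a=2.5, shape_b=2.5, height=0.2),
            np.zeros(5), seed=0, n_families=3,
        )
        scaled, record = preprocess(obs)
        regime_means = scaled.groupby(obs["temp_c"])["temp_c"].first()
        assert regime_means.sum() == pytest.approx(0.0, abs=1e-9)
        assert record.temp_center == pytest.approx(32.5)

    def test_constant_rgr_scales_to_one(self):
        obs = pd.DataFrame({
            "population": "p", "pair": "a",
            "family": ["f1"] * 4 + ["f2"] * 4,
            "temp_c": [15.0, 25.0, 35.0, 45.0] * 2,
            "rgr": 0.37,
        })
        scaled, record = preprocess(obs)
        np.testing.assert_allclose(scaled["rgr"], 1.0)
        assert record.rgr_scale == pytest.approx(0.37)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            obs = pd.DataFrame({
                "population": "p", "pair": "a",
                "family": rng.choice(["f1", "f2", "f3"], size=40),
                "temp_c": rng.uniform(15, 50, size=40),
                "rgr": rng.exponential(0.2, size=40),
            })
            scaled, rec = preprocess(obs)
            np.testing.assert_allclose(
                rec.back_transform_temp(scaled["temp_c"]), obs["temp_c"], atol=1e-12
            )
            np.testing.assert_allclose(
                rec.back_transform_rgr(scaled["rgr"]), obs["rgr"], atol=1e-12
            )

    def test_degenerate_inputs_rejected(self):
        empty = pd.DataFrame(columns=["population", "pair", "family", "temp_c", "rgr"])
        with pytest.raises(ParameterError):
            preprocess(empty)
        all_zero = pd.DataFrame({
            "population": "p", "pair": "a", "family": ["f1", "f2"],
            "temp_c": [20.0, 30.0], "rgr": [0.0, 0.0],
        })
        with pytest.raises(ParameterError):
            preprocess(all_zero)


def literal_loglik(family_params, obs):
    """Term-by-term transcription of the zero-inflated truncated-normal density."""
    total = 0.0
    for _, row in obs.iterrows():
        p = family_params[row["family"]]
        mu = float(nb.evaluate_curve(p, row["temp_c"]))
        pi = 1.0 / (1.0 + np.exp(-(p.zi_intercept + p.zi_slope * mu)))
        sigma = max(p.noise_sd, _SIGMA_FLOOR)
        if row["rgr"] == 0.0:
            total += np.log(pi)
        else:
            dens = sp_stats.norm.pdf(row["rgr"], mu, sigma) / sp_stats.norm.cdf(mu / sigma)
            total += np.log((1.0 - pi) * dens)
    return total


class TestLogLikelihood:
    def test_matches_literal_transcription(self, small_population):
        obs, truth = small_population
        assert log_likelihood(truth.families, obs) == pytest.approx(
            literal_loglik(truth.families, obs), abs=1e-10
        )

    def test_zero_outside_limits_contributes_log_pi(self):
        p = nb.CurveParams(lower=20, upper=40, shape_a=2, shape_b=2, height=0.2,
                           zi_intercept=-1.0, zi_slope=-5.0)
        obs = pd.DataFrame({
            "population": "p", "pair": "a", "family": ["f"],
            "temp_c": [10.0],  # outside (L, U): mu = 0
            "rgr": [0.0],
        })
        expected = np.log(1.0 / (1.0 + np.exp(1.0)))  # log inv_logit(gamma0)
        assert log_likelihood({"f": p}, obs) == pytest.approx(expected, abs=1e-12)

    def test_sigma_floor_guards_degenerate_spike(self):
        p = nb.CurveParams(lower=20, upper=40, shape_a=2, shape_b=2, height=0.2,
                           noise_sd=1e-12)
        obs = pd.DataFrame({
            "population": "p", "pair": "a", "family": ["f"],
            "temp_c": [30.0], "rgr": [0.2],
        })
        assert np.isfinite(log_likelihood({"f": p}, obs))

    def test_invalid_rgr_rejected(self, small_population):
        obs, truth = small_population
        bad = obs.copy()
        bad.loc[bad.index[0], "rgr"] = np.nan
        with pytest.raises(ParameterError):
            log_likelihood(truth.families, bad)

    def test_family_relabeling_invariance(self, small_population):
        obs, truth = small_population
        mapping = {f: f"renamed_{i}" for i, f in enumerate(truth.families)}
        obs2 = obs.assign(family=obs["family"].map(mapping))
        params2 = {mapping[f]: p for f, p in truth.families.items()}
        assert log_likelihood(params2, obs2) == pytest.approx(
            log_likelihood(truth.families, obs), abs=1e-10
        )


class TestFitPopulation:
    def test_draw_count_contract_and_finite_params(self, fitted_population):
        _, _, draws = fitted_population
        cfg = draws.config
        assert draws.n_draws == cfg.chains * (cfg.iterations - cfg.n_warmup)
        assert np.all(np.isfinite(draws.lower))
        assert np.all(draws.upper > draws.lower)
        assert np.all(draws.shape_a > 1) and np.all(draws.shape_b > 1)
        assert np.all(draws.height > 0) and np.all(draws.sigma > 0)
        assert np.all(draws.gamma1 <= 0)

    def test_diagnostics_reported_for_all_parameters(self, fitted_population):
        _, _, draws = fitted_population
        diag = draws.diagnostics
        assert set(diag["rhat"]) == set(diag["ess"])
        for fam in draws.families:
            assert f"topt_{fam}" in diag["rhat"]
        assert all(np.isfinite(v) for v in diag["rhat"].values())

    def test_posterior_centered_on_truth_smoke(self, fitted_population):
        # smoke-scale sanity: posterior-mean T_opt within a few degC of truth
        _, truth, draws = fitted_population
        st = nb.draw_stats(draws)
        post = st.topt.mean(axis=0)
        true = truth.true_topt().reindex(draws.families).to_numpy()
        assert np.all(np.abs(post - true) < 5.0)

    def test_input_contracts(self):
        obs, _ = nb.simulate_population(
            nb.CurveParams(lower=10, upper=47, shape_a=2.5, shape_b=2.5, height=0.2),
            np.zeros(5), seed=0, n_families=1,
        )
        with pytest.raises(ParameterError, match="families"):
            nb.fit_population(obs, FitConfig(iterations=10, warmup=5))
        obs2, _ = nb.simulate_population(
            nb.CurveParams(lower=10, upper=47, shape_a=2.5, shape_b=2.5, height=0.2),
            np.zeros(5), nb.ExperimentDesign(regime_temps=(20.0, 35.0)),
            seed=0, n_families=3,
        )
        with pytest.raises(ParameterError, match="temperatures"):
            nb.fit_population(obs2, FitConfig(iterations=10, warmup=5))

    def test_fit_config_validation(self):
        with pytest.raises(ParameterError):
            FitConfig(iterations=100, warmup=100)
        with pytest.raises(ParameterError):
            FitConfig(adapt_delta=1.5)


class TestBayesianP:
    def test_self_simulated_data_is_calibrated(self, fitted_population):
        obs, _, draws = fitted_population
        p = nb.bayesian_p(draws, obs, max_draws=300, seed=0)
        assert 0.0 <= p <= 1.0
        assert 0.02 < p < 0.98  # well-specified data should not sit in a tail

    def test_misspecified_data_flagged(self, fitted_population):
        # constant RGR at every temperature, no zeros: grossly unlike the model
        obs, _, draws = fitted_population
        flat = obs.copy()
        flat["rgr"] = 0.2
        p = nb.bayesian_p(draws, flat, max_draws=200, seed=0)
        assert p < 0.05 or p > 0.95

    def test_empty_draws_rejected(self, fitted_population):
        obs, _, draws = fitted_population
        import dataclasses as dc
        empty = dc.replace(draws, lower=draws.lower[:0], upper=draws.upper[:0],
                           shape_a=draws.shape_a[:0], shape_b=draws.shape_b[:0],
                           height=draws.height[:0], sigma=draws.sigma[:0],
                           gamma0=draws.gamma0[:0], gamma1=draws.gamma1[:0])
        with pytest.raises(ParameterError):
            nb.bayesian_p(empty, obs)
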