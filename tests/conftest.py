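import pytest
from hypothesis import settings

import nichebreadth as nb

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from nichebreadth.fit import FitConfig


@pytest.fixture(scope="session")
def mimulus_table():
    """Packaged population summary table (10 monkeyflower populations)."""
    return nb.load_mimulus_table()


@pytest.fixture(scope="session")
def mimulus_model_frame(mimulus_table):
    df = mimulus_table.rename(columns={"species": "population"})
    return df[["population", "pair", "pop_tbreadth", "var_topt", "var_tbreadth"]]


@pytest.fixture(scope="session")
def small_population():
    """One simulated population, small enough for quick likelihood checks."""
    means = nb.CurveParams(
        lower=10.0, upper=47.0, shape_a=2.5, shape_b=2.5, height=0.2,
        noise_sd=0.05, zi_intercept=-2.0, zi_slope=-25.0,
    )
    sds = {"lower": 2.0, "log_span": 0.03, "log_am1": 0.05, "log_bm1": 0.05, "log_height": 0.1}
    obs, truth = nb.simulate_population(
        means, sds, nb.ExperimentDesign(reps_min=2, reps_max=2),
        seed=7, n_families=3, population="p1",
    )
    return obs, truth


@pytest.fixture(scope="session")
def fitted_population():
    """A fast (smoke-scale) hierarchical fit shared across tests.

    Deliberately tiny sampler settings: contracts and invariants are
    exercised here, statistical recovery is covered by the acceptance
    suite at larger settings.
    """
    means = nb.CurveParams(
        lower=10.0, upper=47.0, shape_a=2.5, shape_b=2.5, height=0.2,
        noise_sd=0.05, zi_intercept=-2.0, zi_slope=-25.0,
    )
    sds = {"lower": 2.0, "log_span": 0.03, "log_am1": 0.05, "log_bm1": 0.05, "log_height": 0.1}
    obs, truth = nb.simulate_population(
        means, sds, nb.ExperimentDesign(reps_min=3, reps_max=3),
        seed=7, n_families=5, population="p1",
    )
    cfg = FitConfig(iterations=600, warmup=300, chains=2, seed=11)
    with pytest.warns(RuntimeWarning):  # smoke-scale run cannot meet ESS floor
        draws = nb.fit_population(obs, cfg)
    return obs, truth, draws


def random_valid_params(rng, with_obs_model=False):
    """Random CurveParams satisfying all domain constraints."""
    lower = rng.uniform(-5.0, 25.0)
    span = rng.uniform(8.0, 45.0)
    kwargs = {}
    if with_obs_model:
        kwargs = dict(noise_sd=rng.uniform(0.01, 0.2), zi_intercept=rng.uniform(-4, 0),
                      zi_slope=-rng.uniform(0, 30))
    return nb.CurveParams(
        lower=lower,
        upper=lower + span,
        shape_a=1.0 + rng.uniform(0.2, 6.0),
        shape_b=1.0 + rng.uniform(0.2, 6.0),
        height=rng.uniform(0.05, 2.0),
        **kwargs,
    )
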