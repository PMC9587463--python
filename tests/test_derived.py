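"""Posterior-derived quantities: envelope breadth, variances, summary table."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import nichebreadth as nb
from nichebreadth.derived import (
    DrawStats,
    population_breadth_per_draw,
    read_summary_table,
    write_summary_table,
)
from nichebreadth.fit import FitConfig, PosteriorDraws, ScalingRecord
from nichebreadth.tpc import ParameterError


def make_draws(lower, upper, shape_a=None, shape_b=None, population="p"):
    """Hand-built PosteriorDraws from explicit (n_draws, F) limit arrays."""
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    n, F = lower.shape
    a = np.full((n, F), 2.0) if shape_a is None else np.asarray(shape_a, float)
    b = np.full((n, F), 2.0) if shape_b is None else np.asarray(shape_b, float)
    return PosteriorDraws(
        population=population,
        families=[f"f{i}" for i in range(F)],
        lower=lower,
        upper=upper,
        shape_a=a,
        shape_b=b,
        height=np.full((n, F), 1.0),
        sigma=np.full(n, 0.05),
        gamma0=np.full(n, -2.0),
        gamma1=np.full(n, -10.0),
        pop_mean=np.zeros((n, 5)),
        pop_scale=np.zeros((n, 5)),
        diagnostics={},
        scaling=ScalingRecord(32.5, 1.0),
        config=FitConfig(iterations=10, warmup=5, chains=1),
    )


class TestEnvelopeBreadth:
    def test_single_family_equals_family_breadth(self):
        draws = make_draws(lower=[[18.0]], upper=[[42.0]])
        st = nb.draw_stats(draws)
        env = population_breadth_per_draw(st)
        assert env[0] == pytest.approx(st.family_breadth[0, 0], abs=1e-12)

    def test_two_family_envelope_arithmetic(self):
        st = DrawStats(
            families=["f0", "f1"],
            topt=np.array([[25.0, 30.0]]),
            b50_lower=np.array([[20.0, 25.0]]),
            b50_upper=np.array([[30.0, 35.0]]),
            lower_truncated=np.zeros((1, 2), bool),
            upper_truncated=np.zeros((1, 2), bool),
        )
        assert population_breadth_per_draw(st)[0] == 15.0

    def test_envelope_dominates_family_breadths(self):
        rng = np.random.default_rng(0)
        lower = rng.uniform(16, 28, size=(50, 6))
        upper = lower + rng.uniform(5, 20, size=(50, 6))
        draws = make_draws(lower, upper)
        st = nb.draw_stats(draws)
        env = population_breadth_per_draw(st)
        assert np.all(env >= st.family_breadth.max(axis=1) - 1e-12)
        assert np.all(env <= 35.0 + 1e-12)
        # brute-force check per draw
        brute = st.b50_upper.max(axis=1) - st.b50_lower.min(axis=1)
        np.testing.assert_allclose(env, brute)

    def test_adding_a_family_never_shrinks_envelope(self):
        rng = np.random.default_rng(1)
        lower = rng.uniform(16, 28, size=(20, 5))
        upper = lower + rng.uniform(5, 18, size=(20, 5))
        full = population_breadth_per_draw(nb.draw_stats(make_draws(lower, upper)))
        partial = population_breadth_per_draw(
            nb.draw_stats(make_draws(lower[:, :4], upper[:, :4]))
        )
        assert np.all(full >= partial - 1e-12)


class TestSummarize:
    def test_identical_families_have_zero_variance(self):
        lower = np.tile([[20.0]], (8, 3))
        upper = np.tile([[40.0]], (8, 3))
        s = nb.summarize(make_draws(lower, upper))
        np.testing.assert_allclose(s.var_topt, 0.0, atol=1e-20)
        np.testing.assert_allclose(s.var_tbreadth, 0.0, atol=1e-20)
        assert s.pop_tbreadth[0] == pytest.approx(s.family_tbreadth[0])

    def test_variances_match_manual_calculation(self):
        # 2 families x 3 draws with hand-checkable numbers
        lower = np.array([[20.0, 22.0], [21.0, 23.0], [19.0, 25.0]])
        upper = lower + np.array([[20.0, 16.0], [18.0, 14.0], [22.0, 12.0]])
        draws = make_draws(lower, upper)
        st = nb.draw_stats(draws)
        s = nb.summarize(draws)
        manual_var_topt = [np.var(st.topt[d], ddof=1) for d in range(3)]
        assert s.var_topt[0] == pytest.approx(np.mean(manual_var_topt), abs=1e-12)
        manual_var_b = [np.var(st.family_breadth[d], ddof=1) for d in range(3)]
        assert s.var_tbreadth[0] == pytest.approx(np.mean(manual_var_b), abs=1e-12)
        # family column: per-draw across-family mean, then mean over draws
        assert s.family_tbreadth[0] == pytest.approx(st.family_breadth.mean(), abs=1e-12)

    def test_ci_brackets_mean_and_linearity(self):
        rng = np.random.default_rng(2)
        lower = rng.uniform(16, 28, size=(200, 4))
        upper = lower + rng.uniform(5, 18, size=(200, 4))
        draws = make_draws(lower, upper)
        s = nb.summarize(draws)
        for triple in (s.pop_tbreadth, s.family_tbreadth, s.var_topt, s.var_tbreadth):
            m, lo, hi = triple
            assert lo <= m <= hi
        # posterior mean of per-draw mean == mean of per-family means
        st = nb.draw_stats(draws)
        assert s.family_tbreadth[0] == pytest.approx(
            st.family_breadth.mean(axis=0).mean(), abs=1e-12
        )

    def test_single_family_variance_missing_with_warning(self):
        draws = make_draws([[20.0]] * 4, [[40.0]] * 4)
        with pytest.warns(RuntimeWarning, match="single family"):
            s = nb.summarize(draws)
        assert s.var_topt is None

    def test_family_relabeling_leaves_summaries_unchanged(self):
        rng = np.random.default_rng(3)
        lower = rng.uniform(16, 28, size=(30, 5))
        upper = lower + rng.uniform(5, 18, size=(30, 5))
        draws = make_draws(lower, upper)
        perm = [3, 0, 4, 1, 2]
        s1, s2 = nb.summarize(draws), nb.summarize(draws.permuted(perm))
        assert s1.pop_tbreadth == s2.pop_tbreadth
        assert s1.var_topt == s2.var_topt


class TestPackagedTableFixture:
    def test_shape_and_pairs(self, mimulus_table):
        assert len(mimulus_table) == 10
        assert sorted(mimulus_table["pair"].unique()) == list("abcde")
        assert (mimulus_table.groupby("pair").size() == 2).all()
        assert mimulus_table["n_families"].between(11, 50).all()

    def test_round_trip_bit_exact(self, mimulus_table, tmp_path):
        path = tmp_path / "t1.csv"
        mimulus_table.to_csv(path, index=False)
        again = pd.read_csv(path)
        pd.testing.assert_frame_equal(mimulus_table, again)

    def test_reference_row_values(self, mimulus_table):
        row = mimulus_table.set_index("species").loc["M. cardinalis"]
        assert row.pop_tbreadth == 34.74
        assert (row.pop_tbreadth_lo, row.pop_tbreadth_hi) == (33.61, 35.00)
        assert row.family_tbreadth == 29.97

    def test_summary_table_io(self, mimulus_table, tmp_path):
        df = mimulus_table.rename(columns={"species": "population"})
        path = tmp_path / "summary.csv"
        write_summary_table(df, path)
        back = read_summary_table(path)
        np.testing.assert_allclose(back["pop_tbreadth"], df["pop_tbreadth"])

    def test_summary_table_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"population": ["x"], "pair": ["a"]}).to_csv(path, index=False)
        with pytest.raises(ParameterError, match="missing columns"):
            read_summary_table(path)


class TestRatiosAndSd:
    def test_breadth_ratio_identity_and_errors(self):
        s = nb.summarize(make_draws([[20.0, 20.0]] * 3, [[40.0, 40.0]] * 3))
        assert nb.breadth_ratio(s) == pytest.approx(1.0)
        bad = dataclasses.replace(s, pop_tbreadth=(0.0, 0.0, 0.0))
        with pytest.raises(ParameterError):
            nb.breadth_ratio(bad)

    def test_breadth_ratio_range_on_fixture(self, mimulus_table):
        ratios = mimulus_table.apply(
            lambda r: nb.breadth_ratio(r[["family_tbreadth", "pop_tbreadth"]]), axis=1
        )
        assert ratios.max() == pytest.approx(0.86, abs=0.005)
        assert mimulus_table.species[ratios.idxmax()] == "M. cardinalis"
        assert ratios.min() == pytest.approx(0.60, abs=0.005)
        assert mimulus_table.species[ratios.idxmin()] == "M. bicolor"

    def test_sd_from_variance(self, mimulus_table):
        assert nb.sd_from_variance(0.0) == 0.0
        assert nb.sd_from_variance(3.96) == pytest.approx(1.99, abs=0.005)
        assert nb.sd_from_variance(12.14) == pytest.approx(3.48, abs=0.005)
        sds = nb.sd_from_variance(mimulus_table["var_topt"])
        assert sds.min() == pytest.approx(1.99, abs=0.005)
        assert sds.max() == pytest.approx(3.48, abs=0.005)
        with pytest.raises(ParameterError):
            nb.sd_from_variance(-1.0)
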