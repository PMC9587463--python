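"""Posterior draws -> niche-breadth summaries.

For every retained draw and family the thermal optimum and B50 interval are
computed analytically from the curve parameters (bounds clipped to the
measurement window). Population breadth follows the envelope model: per
draw, the highest family upper bound minus the smallest family lower bound.
Genetic variation is the among-family sample variance (denominator n-1) of
T_opt and T_breadth within each draw. Every quantity is summarized as its
posterior mean with a central (equal-tailed) 95% credible interval,
yielding one table row per population in the layout of the study's
population summary table.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .fit import PosteriorDraws
from .tpc import MeasurementWindow, ParameterError, breadth_bounds_arrays

__all__ = [
    "DrawStats",
    "BreadthSummary",
    "draw_stats",
    "population_breadth_per_draw",
    "summarize",
    "breadth_ratio",
    "sd_from_variance",
    "load_mimulus_table",
    "write_summary_table",
    "read_summary_table",
    "SUMMARY_COLUMNS",
]

CI_LEVEL = 0.95

SUMMARY_COLUMNS = [
    "population",
    "pair",
    "n_families",
    "n_individuals",
    "pop_tbreadth",
    "pop_tbreadth_lo",
    "pop_tbreadth_hi",
    "family_tbreadth",
    "family_tbreadth_lo",
    "family_tbreadth_hi",
    "var_topt",
    "var_topt_lo",
    "var_topt_hi",
    "var_tbreadth",
    "var_tbreadth_lo",
    "var_tbreadth_hi",
    "bayesian_p",
    "truncation_rate",
]


@dataclass
class DrawStats:
    """Per-draw, per-family derived quantities for one population."""

    families: list
    topt: np.ndarray  # (n_draws, F)
    b50_lower: np.ndarray
    b50_upper: np.ndarray
    lower_truncated: np.ndarray  # boolean (n_draws, F)
    upper_truncated: np.ndarray

    @property
    def family_breadth(self) -> np.ndarray:
        return self.b50_upper - self.b50_lower

    @property
    def truncation_rate(self) -> float:
        """Fraction of family x draw B50 bounds clipped to the window."""
        clipped = self.lower_truncated.sum() + self.upper_truncated.sum()
        return float(clipped) / (2.0 * self.topt.size)


def draw_stats(
    draws: PosteriorDraws,
    window: MeasurementWindow | None = None,
    threshold: float = 0.5,
) -> DrawStats:
    """Analytic T_opt and clipped B50 bounds for every draw x family."""
    window = window or MeasurementWindow()
    L, U, a, b = draws.lower, draws.upper, draws.shape_a, draws.shape_b
    t_star = ((a - 1.0) / (a * b - 1.0)) ** (1.0 / a)
    topt = L + t_star * (U - L)
    lo, hi, lt, ht = breadth_bounds_arrays(L, U, a, b, threshold, window)
    return DrawStats(
        families=list(draws.families),
        topt=topt,
        b50_lower=lo,
        b50_upper=hi,
        lower_truncated=lt,
        upper_truncated=ht,
    )


def population_breadth_per_draw(stats: DrawStats) -> np.ndarray:
    """Envelope breadth per draw: max family upper bound - min lower bound."""
    return stats.b50_upper.max(axis=1) - stats.b50_lower.min(axis=1)


def _mean_ci(values: np.ndarray) -> tuple[float, float, float]:
    alpha = (1.0 - CI_LEVEL) / 2.0
    return (
        float(np.mean(values)),
        float(np.quantile(values, alpha)),
        float(np.quantile(values, 1.0 - alpha)),
    )


@dataclass
class BreadthSummary:
    """One population's derived quantities (posterior mean + 95% CI)."""

    population: str
    pair: str
    n_families: int
    n_individuals: int | None
    pop_tbreadth: tuple[float, float, float]
    family_tbreadth: tuple[float, float, float]
    var_topt: tuple[float, float, float] | None
    var_tbreadth: tuple[float, float, float] | None
    bayesian_p: float | None = None
    truncation_rate: float | None = None

    def to_row(self) -> dict:
        def unpack(name, triple):
            if triple is None:
                return {name: np.nan, f"{name}_lo": np.nan, f"{name}_hi": np.nan}
            m, lo, hi = triple
            return {name: m, f"{name}_lo": lo, f"{name}_hi": hi}

        row = {
            "population": self.population,
            "pair": self.pair,
            "n_families": self.n_families,
            "n_individuals": self.n_individuals,
        }
        row |= unpack("pop_tbreadth", self.pop_tbreadth)
        row |= unpack("family_tbreadth", self.family_tbreadth)
        row |= unpack("var_topt", self.var_topt)
        row |= unpack("var_tbreadth", self.var_tbreadth)
        row["bayesian_p"] = self.bayesian_p
        row["truncation_rate"] = self.truncation_rate
        return row


def summarize(
    draws: PosteriorDraws,
    window: MeasurementWindow | None = None,
    threshold: float = 0.5,
    n_individuals: int | None = None,
    pair: str | None = None,
) -> BreadthSummary:
    """Collapse one population's posterior draws into a summary-table row.

    The family column is the per-draw across-family mean of family B50
    breadths (so it carries one credible interval per population); the
    variance columns are per-draw among-family sample variances. With a
    single family the variances are undefined and reported missing.
    """
    stats = draw_stats(draws, window, threshold)
    pop_b = population_breadth_per_draw(stats)
    fam_mean_b = stats.family_breadth.mean(axis=1)
    if stats.topt.shape[1] >= 2:
        var_topt = _mean_ci(stats.topt.var(axis=1, ddof=1))
        var_breadth = _mean_ci(stats.family_breadth.var(axis=1, ddof=1))
    else:
        warnings.warn(
            f"{draws.population}: single family; among-family variances undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        var_topt = var_breadth = None
    return BreadthSummary(
        population=draws.population,
        pair=pair if pair is not None else "",
        n_families=stats.topt.shape[1],
        n_individuals=n_individuals,
        pop_tbreadth=_mean_ci(pop_b),
        family_tbreadth=_mean_ci(fam_mean_b),
        var_topt=var_topt,
        var_tbreadth=var_breadth,
        bayesian_p=draws.bayesian_p_value,
        truncation_rate=stats.truncation_rate,
    )


def breadth_ratio(summary: BreadthSummary | pd.Series) -> float:
    """Mean family breadth as a fraction of population envelope breadth."""
    if isinstance(summary, BreadthSummary):
        fam, pop = summary.family_tbreadth[0], summary.pop_tbreadth[0]
    else:
        fam, pop = float(summary["family_tbreadth"]), float(summary["pop_tbreadth"])
    if pop <= 0:
        raise ParameterError("population breadth must be > 0")
    return fam / pop


def sd_from_variance(variance) -> np.ndarray | float:
    """Among-family SD (degC) from among-family variance (degC^2)."""
    v = np.asarray(variance, dtype=float)
    if np.any(v < 0):
        raise ParameterError("variance must be >= 0")
    out = np.sqrt(v)
    return float(out) if out.ndim == 0 else out


def load_mimulus_table() -> pd.DataFrame:
    """Packaged population summary table of the 10 monkeyflower populations.

    Columns: species, pair (a-e), family/individual counts, population and
    mean family B50 breadth with 95% CIs, among-family variances in T_opt
    and T_breadth with 95% CIs, and the posterior-predictive p-value of the
    population's curve fit.
    """
    path = importlib.resources.files("nichebreadth.data") / "mimulus_populations.csv"
    with importlib.resources.as_file(path) as p:
        return pd.read_csv(p)


def write_summary_table(rows: Iterable[BreadthSummary] | pd.DataFrame, path) -> None:
    """Write summary rows to CSV in the canonical column order."""
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame([r.to_row() for r in rows])
    cols = [c for c in SUMMARY_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


def read_summary_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"population", "pair", "pop_tbreadth"} - set(df.columns)
    if missing:
        raise ParameterError(f"summary table missing columns: {sorted(missing)}")
    return df
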