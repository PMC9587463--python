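"""Observation-table I/O, run configuration, and pipeline orchestration.

The pipeline ties the stages together: simulate (optional) -> fit one
hierarchical model per population -> derive breadth summaries -> run the
three hypothesis mixed models -> report. Every run serializes its full
configuration (YAML) and a config hash into the output directory so results
are traceable; deterministic stages are byte-identical across re-runs with
the same config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import derived, lmm
from .fit import FitConfig, PosteriorDraws, bayesian_p, fit_population
from .simulate import OBS_COLUMNS, SCENARIOS, ExperimentDesign, simulate_study
from .tpc import MeasurementWindow, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_observations",
    "write_observations",
    "run_pipeline",
]

_TEMP_SANITY = (-20.0, 70.0)  # degC; outside this range a row is rejected


def read_observations(path) -> pd.DataFrame:
    """Read and validate a long-format observation CSV.

    Required columns: population, pair, family, temp_c, rgr. Rejects
    negative RGR, temperatures outside a generous sanity range, and
    families mapped to more than one population (or populations to more
    than one pair), reporting the offending rows.
    """
    df = pd.read_csv(path)
    missing = set(OBS_COLUMNS) - set(df.columns)
    if missing:
        raise ParameterError(f"{path}: missing columns {sorted(missing)}")
    df = df[OBS_COLUMNS].copy()
    problems = []
    bad_rgr = df.index[~np.isfinite(df["rgr"]) | (df["rgr"] < 0)]
    problems += [f"row {i}: invalid rgr {df.at[i, 'rgr']!r}" for i in bad_rgr[:10]]
    bad_t = df.index[
        ~np.isfinite(df["temp_c"])
        | (df["temp_c"] < _TEMP_SANITY[0])
        | (df["temp_c"] > _TEMP_SANITY[1])
    ]
    problems += [f"row {i}: temp_c {df.at[i, 'temp_c']!r} outside sanity range" for i in bad_t[:10]]
    for fam, pops in df.groupby("family")["population"].nunique().items():
        if pops > 1:
            problems.append(f"family {fam!r} appears in multiple populations")
    for pop, pairs in df.groupby("population")["pair"].nunique().items():
        if pairs > 1:
            problems.append(f"population {pop!r} mapped to multiple pairs")
    if problems:
        raise ParameterError(f"{path}: invalid observations:\n  " + "\n  ".join(problems))
    return df


def write_observations(obs: pd.DataFrame, path) -> None:
    obs[OBS_COLUMNS].to_csv(path, index=False)


@dataclass
class RunConfig:
    """Everything one pipeline run depends on; fully serializable to YAML."""

    outdir: str = "results"
    observations: str | None = None  # path; None -> simulate
    scenario: str = "divergent-optima"
    seed: int = 0
    threshold: float = 0.5
    alpha: float = 0.1
    regime_temps: tuple = (15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0)
    fit: FitConfig = field(default_factory=FitConfig)
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    populations: tuple | None = None  # subset to fit; None -> all

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ParameterError("threshold must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must lie in (0, 1)")
        if self.scenario not in SCENARIOS:
            raise ParameterError(f"unknown scenario {self.scenario!r}")

    @property
    def window(self) -> MeasurementWindow:
        return MeasurementWindow(tuple(self.regime_temps))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("regime_temps",):
            d[key] = list(d[key])
        d["fit"] = dataclasses.asdict(self.fit)
        d["design"] = dataclasses.asdict(self.design)
        d["design"]["regime_temps"] = list(self.design.regime_temps)
        d["populations"] = list(self.populations) if self.populations else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "fit" in d and isinstance(d["fit"], dict):
            d["fit"] = FitConfig(**d["fit"])
        if "design" in d and isinstance(d["design"], dict):
            dd = dict(d["design"])
            if "regime_temps" in dd:
                dd["regime_temps"] = tuple(dd["regime_temps"])
            d["design"] = ExperimentDesign(**dd)
        if d.get("regime_temps") is not None:
            d["regime_temps"] = tuple(d["regime_temps"])
        if d.get("populations") is not None:
            d["populations"] = tuple(d["populations"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _draws_to_frame(draws: PosteriorDraws) -> pd.DataFrame:
    rows = []
    for f, fam in enumerate(draws.families):
        rows.append(
            pd.DataFrame(
                {
                    "draw": np.arange(draws.n_draws),
                    "family": fam,
                    "lower": draws.lower[:, f],
                    "upper": draws.upper[:, f],
                    "shape_a": draws.shape_a[:, f],
                    "shape_b": draws.shape_b[:, f],
                    "height": draws.height[:, f],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _save_population(draws: PosteriorDraws, pop_dir: Path, config_hash: str) -> None:
    pop_dir.mkdir(parents=True, exist_ok=True)
    _draws_to_frame(draws).to_csv(pop_dir / "draws.csv", index=False)
    diag = {
        "config_hash": config_hash,
        "population": draws.population,
        "n_draws": draws.n_draws,
        "bayesian_p": draws.bayesian_p_value,
        "scaling": dataclasses.asdict(draws.scaling),
        "diagnostics": draws.diagnostics,
    }
    (pop_dir / "diagnostics.json").write_text(json.dumps(diag, indent=2, default=float))


def run_pipeline(config: RunConfig) -> Path:
    """Run simulate -> fit -> derive -> test and write all results.

    Returns the output directory. Any stage failure raises with the stage
    name and population id in the message; sampler warnings are surfaced in
    the log and the per-population diagnostics files, never swallowed.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    chash = config.config_hash()
    logging.basicConfig(level=logging.INFO)
    logger.info("pipeline start: config hash %s, seed %s", chash, config.seed)

    # --- stage: observations (load or simulate) ---
    truth = None
    if config.observations:
        obs = read_observations(config.observations)
    else:
        obs, truth = simulate_study(config.design, config.scenario, seed=config.seed)
        write_observations(obs, out / "observations.csv")
        truth.summary(config.window).to_csv(out / "truth_summary.csv", index=False)

    populations = list(config.populations or sorted(obs["population"].unique()))

    # --- stage: per-population hierarchical fits ---
    summaries = []
    fam_rows = []
    for i, pop in enumerate(populations):
        sub = obs[obs["population"] == pop]
        if len(sub) == 0:
            raise ParameterError(f"stage fit, population {pop}: no observations")
        pair = str(sub["pair"].iloc[0])
        try:
            cfg = dataclasses.replace(config.fit, seed=config.fit.seed + i)
            draws = fit_population(sub, cfg, config.window, population=pop)
            draws.bayesian_p_value = bayesian_p(draws, sub)
        except ParameterError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
            raise RuntimeError(f"stage fit failed for population {pop}: {exc}") from exc
        _save_population(draws, out / "fits" / pop, chash)
        summary = derived.summarize(
            draws, config.window, config.threshold, n_individuals=len(sub), pair=pair
        )
        summaries.append(summary)
        stats = derived.draw_stats(draws, config.window, config.threshold)
        fam_breadth_mean = stats.family_breadth.mean(axis=0)
        for fam, fb in zip(stats.families, fam_breadth_mean):
            fam_rows.append(
                {"population": pop, "pair": pair, "family": fam, "family_tbreadth": float(fb)}
            )
        logger.info("fitted %s (%d families, %d obs)", pop, draws.n_families, len(sub))

    derived.write_summary_table(summaries, out / "summary.csv")
    family_breadths = pd.DataFrame(fam_rows)
    family_breadths.to_csv(out / "family_breadths.csv", index=False)

    # --- stage: hypothesis tests ---
    summary_df = pd.DataFrame([s.to_row() for s in summaries])
    results = lmm.run_all_models(summary_df, family_breadths, alpha=config.alpha)
    res_rows = []
    for model, r in results.items():
        row = dataclasses.asdict(r)
        row["significant"] = r.significant(config.alpha)
        res_rows.append(row)
    pd.DataFrame(res_rows).to_csv(out / "hypothesis_tests.csv", index=False)
    (out / "hypothesis_tests.json").write_text(
        json.dumps({"config_hash": chash, "models": res_rows}, indent=2, default=float)
    )
    logger.info("pipeline done: %s", out)
    return out
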