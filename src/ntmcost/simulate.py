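"""Weighted Monte-Carlo over the discrete option space.

The "random walk" of the cost model is plain categorical sampling: each of
the 10,000 runs draws one treatment option with its probability weight and
records its cost.  Summaries follow the published convention — sample SD
with the n-1 denominator and a normal-approximation confidence interval
with z = 1.96 — so the printed interval identity
(upper - mean = 1.96 x sd / sqrt(n)) holds exactly on every result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .catalog import ConfigurationError
from .options import OptionSet

__all__ = ["SimulationConfig", "SimulationResult", "sample_options", "summarize",
           "run_simulation", "run_two_stage"]


@dataclass(frozen=True)
class SimulationConfig:
    n_runs: int = 10_000
    seed: int = 0
    confidence_level: float = 0.95
    z_value: float = 1.96

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0 < self.confidence_level < 1:
            raise ValueError("confidence_level must lie in (0, 1)")


@dataclass(frozen=True)
class SimulationResult:
    """Sample summary of one Monte-Carlo pass (the published table layout)."""

    mean: float
    sd: float
    variance: float
    ci_low: float
    ci_high: float
    median: float
    min: float
    max: float
    n: int
    standard_error: float
    seed: int
    mode: str = ""


def sample_options(options: OptionSet, config: SimulationConfig,
                   field: str = "total_cost",
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n_runs`` option costs with the configured weights.

    Reproducible given the seed; an explicit generator may be passed to
    chain several stages on one stream.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    values = np.asarray(options.values(field), dtype=float)
    weights = np.asarray(options.weights(), dtype=float)
    weights = weights / weights.sum()          # remove float round-off before draw
    idx = rng.choice(len(values), size=config.n_runs, p=weights)
    return values[idx]


def summarize(draws: np.ndarray, config: SimulationConfig, mode: str = "") -> SimulationResult:
    """Summarize draws: mean, n-1 SD, z-interval, median and extremes."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("no draws to summarize")
    n = int(draws.size)
    mean = float(draws.mean())
    sd = float(draws.std(ddof=1)) if n > 1 else 0.0
    se = sd / math.sqrt(n)
    half = config.z_value * se
    return SimulationResult(
        mean=mean, sd=sd, variance=sd * sd,
        ci_low=mean - half, ci_high=mean + half,
        median=float(np.median(draws)),
        min=float(draws.min()), max=float(draws.max()),
        n=n, standard_error=se, seed=config.seed, mode=mode,
    )


def run_simulation(options: OptionSet, config: SimulationConfig,
                   field: str = "total_cost",
                   rng: np.random.Generator | None = None) -> SimulationResult:
    """Sample and summarize in one call."""
    draws = sample_options(options, config, field=field, rng=rng)
    return summarize(draws, config, mode=options.mode)


def run_two_stage(drugs_stage: OptionSet, totals_stage: OptionSet,
                  config: SimulationConfig) -> tuple[SimulationResult, SimulationResult]:
    """The two published passes: drug costs first, then total costs.

    Stage 1 draws from the drug-cost column of the option table, stage 2
    from the total-cost column; both stages share the weight structure and
    run on independent sub-streams spawned from one seed.  Raises
    :class:`ConfigurationError` if the two sets' weights differ.
    """
    if len(drugs_stage) != len(totals_stage) or not np.allclose(
            drugs_stage.weights(), totals_stage.weights(), rtol=0, atol=1e-12):
        raise ConfigurationError("stages must share the same weight structure")
    seq = np.random.SeedSequence(config.seed)
    rng_drug, rng_total = (np.random.default_rng(s) for s in seq.spawn(2))
    drug_draws = sample_options(drugs_stage, config, field="drug_cost", rng=rng_drug)
    total_draws = sample_options(totals_stage, config, field="total_cost", rng=rng_total)
    return (summarize(drug_draws, config, mode=drugs_stage.mode),
            summarize(total_draws, config, mode=totals_stage.mode))
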