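"""Scenario grids, replicated runs, seed management and aggregation.

The case-study grid crosses 2 strategies x 3 genetic models x 3 family-mean
heritabilities x 3 parental population sizes = 54 scenarios, each replicated
with fresh QTL effects and a fresh founder population per run.  Per-run
random generators are derived from (base seed, scenario index, run index)
through a counter-based seed sequence, so runs are reproducible and
independent of execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .genetic_system import (
    GENETIC_MODELS,
    GeneticSystem,
    build_synthetic_map,
    sample_qtl_effects,
)
from .metrics import RunResult, write_outputs
from .phenotyping import TrialDesign
from .strategy import StrategyConfig, run_strategy

__all__ = [
    "Scenario",
    "ScenarioGrid",
    "GridConfig",
    "CASE_STUDY_GRID",
    "build_scenario_grid",
    "run_scenario",
    "run_experiment",
    "summarize_runs",
]

logger = logging.getLogger(__name__)

# Synthetic stand-in for the unpublished ryegrass map: 7 linkage groups of
# 100 cM carrying 63 QTL and 194 markers.
DEFAULT_MAP = dict(n_groups=7, n_qtl=63, n_markers=194, group_length_cM=100.0)


@dataclass(frozen=True)
class Scenario:
    index: int
    strategy: str
    model: str
    heritability: float
    n_parents: int

    @property
    def label(self) -> str:
        return f"{self.strategy}_{self.model}_h{self.heritability:g}_N{self.n_parents}"


@dataclass(frozen=True)
class GridConfig:
    """Factor levels of a factorial scenario grid."""

    strategies: tuple[str, ...] = ("AHS", "AWHS")
    models: tuple[str, ...] = GENETIC_MODELS
    heritabilities: tuple[float, ...] = (0.1, 0.5, 0.9)
    population_sizes: tuple[int, ...] = (10, 50, 100)
    runs: int = 100
    base_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("strategies", "models", "heritabilities", "population_sizes"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"factor {name} must have at least one level")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


CASE_STUDY_GRID = GridConfig()


@dataclass
class ScenarioGrid:
    config: GridConfig
    scenarios: list[Scenario]

    @property
    def n_scenarios(self) -> int:
        return len(self.scenarios)

    def run_rng(self, scenario: Scenario, run: int) -> np.random.Generator:
        """Reproducible, order-insensitive generator for one (scenario, run)."""
        return np.random.default_rng(
            np.random.SeedSequence([self.config.base_seed, scenario.index, run])
        )

    def scenario_rng(self, scenario: Scenario) -> np.random.Generator:
        """Generator for scenario-level draws (the shared synthetic map)."""
        return np.random.default_rng(
            np.random.SeedSequence([self.config.base_seed, scenario.index])
        )


def build_scenario_grid(config: GridConfig) -> ScenarioGrid:
    """Full factorial grid in deterministic order (strategy-major)."""
    combos = product(
        config.strategies, config.models, config.heritabilities,
        config.population_sizes,
    )
    scenarios = [
        Scenario(i, s, m, h, n) for i, (s, m, h, n) in enumerate(combos)
    ]
    return ScenarioGrid(config, scenarios)


def _system_for_run(
    scenario: Scenario,
    grid: ScenarioGrid,
    rng: np.random.Generator,
    map_mode: str,
    map_kwargs: dict,
) -> GeneticSystem:
    if map_mode == "per_run":
        gmap = build_synthetic_map(rng=rng, **map_kwargs)
    else:  # one fixed map per scenario, shared by all of its runs
        gmap = build_synthetic_map(rng=grid.scenario_rng(scenario), **map_kwargs)
    effects = sample_qtl_effects(scenario.model, gmap.n_qtl, rng)
    return GeneticSystem(map=gmap, effects=effects, model=scenario.model)


def run_scenario(
    scenario: Scenario,
    grid: ScenarioGrid,
    design: TrialDesign,
    runs: int,
    *,
    cycles: int = 50,
    map_mode: str = "fixed",
    map_kwargs: dict | None = None,
    out_dir=None,
) -> list[RunResult]:
    """Execute all replicate runs of one scenario.

    Each run draws fresh QTL effects and founders; the synthetic map is
    shared across runs (``map_mode='fixed'``) or redrawn per run
    (``'per_run'``).
    """
    if map_mode not in ("fixed", "per_run"):
        raise ValueError(f"unknown map_mode {map_mode!r}")
    map_kwargs = dict(DEFAULT_MAP if map_kwargs is None else map_kwargs)
    config = StrategyConfig(kind=scenario.strategy, cycles=cycles)
    results = []
    for r in range(runs):
        rng = grid.run_rng(scenario, r)
        system = _system_for_run(scenario, grid, rng, map_mode, map_kwargs)
        result = run_strategy(
            system, config, design, scenario.n_parents, scenario.heritability, rng
        )
        if out_dir is not None:
            write_outputs(result, Path(out_dir) / scenario.label, run=r)
        results.append(result)
        logger.debug("scenario %s run %d done", scenario.label, r)
    return results


def summarize_runs(scenario: Scenario, results: list[RunResult]) -> dict:
    """Replicate means and standard errors of the headline run statistics."""
    summaries = [res.summary() for res in results]
    finals = [res.history[-1] for res in results]

    def mean_se(values):
        v = np.asarray(values, dtype=np.float64)
        se = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0
        return float(v.mean()), float(se)

    row = {
        "scenario": scenario.label,
        "strategy": scenario.strategy,
        "model": scenario.model,
        "heritability": scenario.heritability,
        "n_parents": scenario.n_parents,
        "runs": len(results),
    }
    for name, values in (
        ("cycles_to_dg90", [s.cycles_to_delta_g90 for s in summaries]),
        ("dg90_pct", [s.delta_g90_value for s in summaries]),
        ("dg90_per_cycle", [s.delta_g90_per_cycle for s in summaries]),
        ("final_hamming_pct", [f.hamming_pct for f in finals]),
        ("final_fixed_favorable_pct", [f.fixed_favorable_pct for f in finals]),
        ("final_fixed_nonfavorable_pct", [f.fixed_nonfavorable_pct for f in finals]),
        ("cumulative_gain_pct",
         [float(res.gain_percent().sum()) for res in results]),
    ):
        row[f"mean_{name}"], row[f"se_{name}"] = mean_se(values)
    return row


def run_experiment(
    grid: ScenarioGrid,
    design: TrialDesign,
    runs: int | None = None,
    *,
    cycles: int = 50,
    map_mode: str = "fixed",
    map_kwargs: dict | None = None,
    out_dir=None,
    keep_results: bool = False,
) -> pd.DataFrame:
    """Run every scenario of the grid and aggregate per-scenario statistics.

    Individual run failures are logged and excluded; the ``runs`` column of
    the returned frame records how many runs each mean is based on.  The
    frame is also written to ``summary.tsv`` when ``out_dir`` is given,
    together with per-run fit/ham/fre files.
    """
    runs = grid.config.runs if runs is None else runs
    rows = []
    all_results: dict[str, list[RunResult]] = {}
    n_failed = 0
    map_kw = dict(DEFAULT_MAP if map_kwargs is None else map_kwargs)
    config_cache = {k: StrategyConfig(kind=k, cycles=cycles) for k in grid.config.strategies}
    for scenario in grid.scenarios:
        results = []
        for r in range(runs):
            rng = grid.run_rng(scenario, r)
            try:
                system = _system_for_run(scenario, grid, rng, map_mode, map_kw)
                result = run_strategy(
                    system, config_cache[scenario.strategy], design,
                    scenario.n_parents, scenario.heritability, rng,
                )
            except Exception:
                logger.exception("scenario %s run %d failed", scenario.label, r)
                n_failed += 1
                continue
            if out_dir is not None:
                write_outputs(result, Path(out_dir) / scenario.label, run=r)
            results.append(result)
        if not results:
            logger.error("scenario %s produced no completed runs", scenario.label)
            continue
        rows.append(summarize_runs(scenario, results))
        if keep_results:
            all_results[scenario.label] = results
        logger.info("scenario %s: %d runs complete", scenario.label, len(results))
    summary = pd.DataFrame(rows)
    summary.attrs["design_n_total"] = design.n_total
    summary.attrs["failed_runs"] = n_failed
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    if keep_results:
        summary.attrs["results"] = all_results
    return summary
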