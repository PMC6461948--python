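"""Recurrent half-sib family selection: the AHS and AWHS strategy engines.

One breeding cycle runs:

    crossing block --polycross--> half-sib families --> field trial
        --> among-family selection (top fraction by phenotypic family mean)
        --> within-family selection (random k in AHS, best k by plant
            phenotype in AWHS)
        --> crossing-block update (selected plants become next parents)

With 20% among-family selection and 5 plants kept per advanced family, a
block of k parents yields 0.2k families x 5 plants = k new parents, so the
parental population size is conserved across cycles.  The system is closed:
no outside germplasm enters after the founders.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path

import numpy as np
import yaml

from .genetic_system import GeneticSystem, ideal_genotype_value
from .metrics import CycleStats, RunResult, cycle_stats, population_genotypic_mean
from .phenotyping import (
    ErrorModel,
    TrialDesign,
    calibrate_error_variance,
    simulate_trial,
)
from .population import HalfSibFamily, Population, make_halfsib_families

__all__ = [
    "StrategyConfig",
    "BreedingState",
    "select_among_families",
    "select_within_family",
    "update_crossing_block",
    "run_cycle",
    "run_strategy",
]

STRATEGY_KINDS = ("AHS", "AWHS")
WITHIN_FAMILY_MODES = ("random", "best_phenotype")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class StrategyConfig:
    """Parameters of a recurrent half-sib selection strategy.

    ``kind`` fixes the within-family mode: AHS takes a random
    ``within_family_count`` plants from each advanced family, AWHS the best
    by individual plant phenotype.
    """

    kind: str = "AWHS"
    family_selection_proportion: float = 0.2
    within_family_count: int = 5
    within_family_mode: str | None = None  # derived from kind when omitted
    cycles: int = 50
    crossing_block_replace_proportion: float = 1.0
    progeny_test_update: bool = True
    recalibrate_each_cycle: bool = False

    def __post_init__(self) -> None:
        if self.kind not in STRATEGY_KINDS:
            raise ValueError(f"unknown strategy kind {self.kind!r}")
        expected = "random" if self.kind == "AHS" else "best_phenotype"
        if self.within_family_mode is None:
            object.__setattr__(self, "within_family_mode", expected)
        elif self.within_family_mode != expected:
            raise ValueError(
                f"{self.kind} requires within_family_mode={expected!r}"
            )
        if not 0.0 < self.family_selection_proportion <= 1.0:
            raise ValueError("family_selection_proportion must lie in (0, 1]")
        if self.within_family_count < 1:
            raise ValueError("within_family_count must be >= 1")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if not 0.0 < self.crossing_block_replace_proportion <= 1.0:
            raise ValueError("crossing_block_replace_proportion must lie in (0, 1]")

    @classmethod
    def from_file(cls, path) -> "StrategyConfig":
        """Load from a YAML or JSON mapping; unknown keys are errors."""
        path = Path(path)
        with open(path) as fh:
            data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path} does not contain a key-value mapping")
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown strategy config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class BreedingState:
    """The evolving state of a breeding program between cycles."""

    cycle: int
    crossing_block: Population
    families: list[HalfSibFamily] | None
    history: list[CycleStats]

    @property
    def mean_series(self) -> np.ndarray:
        return np.array([s.mean_genotypic_value for s in self.history])


def select_among_families(family_means, proportion: float) -> np.ndarray:
    """Indices of the top round(k * proportion) families by phenotypic mean.

    At least one family always advances; ties are broken by family index
    (ascending), which a stable descending sort provides.
    """
    means = np.asarray(family_means, dtype=np.float64)
    if means.size == 0:
        raise ValueError("no families to select among")
    if not 0.0 < proportion <= 1.0:
        raise ValueError("proportion must lie in (0, 1]")
    n_keep = max(1, _round_half_up(means.size * proportion))
    order = np.argsort(-means, kind="stable")
    return np.sort(order[:n_keep])


def select_within_family(
    family: HalfSibFamily,
    plant_phenotypes: np.ndarray | None,
    k: int,
    mode: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Member indices of the k plants advanced from one family.

    ``random`` ignores the phenotypes; ``best_phenotype`` takes the top k
    plant records (ties by plant index).  If k covers the family, everyone
    advances.
    """
    if mode not in WITHIN_FAMILY_MODES:
        raise ValueError(f"unknown within-family mode {mode!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    n = family.n
    if k >= n:
        return np.arange(n)
    if mode == "random":
        return np.sort(rng.choice(n, size=k, replace=False))
    phen = np.asarray(plant_phenotypes, dtype=np.float64)
    if phen.shape != (n,):
        raise ValueError("plant_phenotypes must hold one record per family member")
    order = np.argsort(-phen, kind="stable")
    return np.sort(order[:k])


def update_crossing_block(
    old_block: Population,
    new_parents: Population,
    replace_proportion: float,
    rng: np.random.Generator,
) -> Population:
    """Replace round(size * proportion) random members of the block.

    Proportion 1 swaps in the new parents wholesale; partial proportions
    keep the block size constant by overwriting a random subset of slots
    with the first parents of ``new_parents``.
    """
    if not 0.0 < replace_proportion <= 1.0:
        raise ValueError("replace_proportion must lie in (0, 1]")
    if replace_proportion == 1.0:
        return new_parents
    n_replace = max(1, _round_half_up(old_block.n * replace_proportion))
    if n_replace > new_parents.n:
        raise ValueError(
            f"need {n_replace} replacement parents but only {new_parents.n} supplied"
        )
    slots = rng.choice(old_block.n, size=n_replace, replace=False)
    haps = old_block.haplotypes.copy()
    ids = old_block.ids.copy()
    fem = old_block.female_ids.copy()
    mal = old_block.male_ids.copy()
    haps[slots] = new_parents.haplotypes[:n_replace]
    ids[slots] = new_parents.ids[:n_replace]
    fem[slots] = new_parents.female_ids[:n_replace]
    mal[slots] = new_parents.male_ids[:n_replace]
    return Population(haps, ids, fem, mal, cycle=new_parents.cycle)


def run_cycle(
    state: BreedingState,
    system: GeneticSystem,
    design: TrialDesign,
    error_model: ErrorModel,
    config: StrategyConfig,
    rng: np.random.Generator,
    families: list[HalfSibFamily] | None = None,
) -> BreedingState:
    """Advance the program by one full selection cycle.

    The appended :class:`CycleStats` reports the mean genotypic value over
    *all* plants of the advanced (selected) families -- the populations the
    cycle delivers -- while the diversity statistics (Hamming distance,
    fixation) are computed on the new crossing block.
    """
    if families is None:
        families = make_halfsib_families(
            state.crossing_block, design.n_total, system.map, rng
        )
    trial = simulate_trial(families, design, error_model.sigma2_R, system, rng)
    kept = select_among_families(trial.family_means, config.family_selection_proportion)
    parent_pops = []
    for f in kept:
        idx = select_within_family(
            families[f], trial.phenotypes[f], config.within_family_count,
            config.within_family_mode, rng,
        )
        parent_pops.append(families[f].members.subset(idx))
    new_parents = Population(
        np.concatenate([p.haplotypes for p in parent_pops]),
        np.concatenate([p.ids for p in parent_pops]),
        np.concatenate([p.female_ids for p in parent_pops]),
        np.concatenate([p.male_ids for p in parent_pops]),
        cycle=state.cycle + 1,
    )
    new_block = update_crossing_block(
        state.crossing_block, new_parents, config.crossing_block_replace_proportion, rng
    )
    mean_g = float(trial.genotypic_values[kept].mean())
    stats = cycle_stats(state.cycle + 1, mean_g, new_block, system)
    return BreedingState(
        cycle=state.cycle + 1,
        crossing_block=new_block,
        families=families,
        history=state.history + [stats],
    )


def run_strategy(
    system: GeneticSystem,
    config: StrategyConfig,
    design: TrialDesign,
    n_parents: int,
    target_h2_fm: float,
    rng: np.random.Generator,
    keep_final_block: bool = False,
) -> RunResult:
    """Run one full breeding program from founders to ``config.cycles``.

    The residual variance is calibrated once, on the first batch of
    half-sib families (cycle-0 material), and held fixed unless
    ``config.recalibrate_each_cycle`` asks for per-cycle recalibration.
    Cycle 0 of the history describes the founder population itself.
    """
    from .population import initial_population

    founders = initial_population(system, n_parents, rng)
    mean0 = population_genotypic_mean(founders, system)
    state = BreedingState(
        cycle=0,
        crossing_block=founders,
        families=None,
        history=[cycle_stats(0, mean0, founders, system)],
    )
    families = make_halfsib_families(founders, design.n_total, system.map, rng)
    sigma2_R = calibrate_error_variance(families, design, target_h2_fm, system)
    error_model = ErrorModel(sigma2_R, target_h2_fm)
    for c in range(config.cycles):
        if c > 0:
            families = make_halfsib_families(
                state.crossing_block, design.n_total, system.map, rng
            )
            if config.recalibrate_each_cycle:
                error_model = ErrorModel(
                    calibrate_error_variance(families, design, target_h2_fm, system),
                    target_h2_fm,
                )
        state = run_cycle(
            state, system, design, error_model, config, rng, families=families
        )
    return RunResult(
        strategy=config.kind,
        history=state.history,
        ideal_value=ideal_genotype_value(system.effects),
        sigma2_R=sigma2_R,
        final_block=state.crossing_block if keep_final_block else None,
    )
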