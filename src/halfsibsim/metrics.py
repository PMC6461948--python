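"""Per-cycle gain and diversity statistics, run summaries, and result files.

Three statistics track a run, mirroring the FIT/HAM/FRE outputs of
family-based breeding simulators:

- mean genotypic value of all retained individuals per cycle (fit.tsv),
  and its between-cycle change expressed as a percentage of the gap
  between the ideal genotype and the founding mean (dG%);
- Hamming distance (ham.tsv): the average number of allele substitutions
  per individual still needed to reach the ideal genotype, as a percent of
  the 2 x n_qtl allele slots;
- allele fixation rates (fre.tsv): percent of QTL at which the whole
  population is homozygous for the favorable / non-favorable allele.

A run is summarized by dG90: 90% of the total cumulative gain, and the
first cycle at which cumulative gain reaches it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genetic_system import EffectTable, GeneticSystem
from .population import Population

__all__ = [
    "CycleStats",
    "RunSummary",
    "RunResult",
    "population_genotypic_mean",
    "genetic_gain_percent",
    "delta_g90",
    "hamming_distance",
    "fixation_rates",
    "write_outputs",
    "read_fit",
]


@dataclass(frozen=True)
class CycleStats:
    cycle: int
    mean_genotypic_value: float
    hamming_pct: float
    fixed_favorable_pct: float
    fixed_nonfavorable_pct: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.hamming_pct <= 100.0:
            raise ValueError("hamming_pct must lie in [0, 100]")
        if self.fixed_favorable_pct + self.fixed_nonfavorable_pct > 100.0 + 1e-9:
            raise ValueError("fixation percentages cannot exceed 100 in total")


@dataclass(frozen=True)
class RunSummary:
    """dG90 of one run: its size (in dG% units), the first cycle reaching it,
    and the per-cycle rate value/cycles."""

    delta_g90_value: float
    cycles_to_delta_g90: int
    delta_g90_per_cycle: float  # value / cycles_to_delta_g90 (0 when no gain)


@dataclass
class RunResult:
    """Full trace of one simulated breeding run."""

    strategy: str
    history: list[CycleStats]
    ideal_value: float
    sigma2_R: float
    final_block: Population | None = None

    @property
    def mean_series(self) -> np.ndarray:
        return np.array([s.mean_genotypic_value for s in self.history])

    @property
    def cycles(self) -> int:
        return len(self.history) - 1

    def gain_percent(self) -> np.ndarray:
        return genetic_gain_percent(self.mean_series, self.ideal_value)

    def summary(self) -> RunSummary:
        series = self.mean_series
        raw90, cycle = delta_g90(series)
        denom = self.ideal_value - series[0]
        value = 100.0 * raw90 / denom if denom > 0 else 0.0
        per_cycle = value / cycle if cycle > 0 else 0.0
        return RunSummary(value, cycle, per_cycle)


def population_genotypic_mean(population: Population, system: GeneticSystem) -> float:
    """Mean genotypic value over *all* members of a population (never a
    single sampled representative)."""
    if population.n == 0:
        raise ValueError("empty population")
    return float(population.genotypic_values(system).mean())


def genetic_gain_percent(mean_series: np.ndarray, ideal_value: float) -> np.ndarray:
    """Between-cycle gain as a percentage of the initially attainable gap.

    dG%_t = 100 * (G_t - G_{t-1}) / (ideal - G_0), for t = 1..T.  The
    normalization removes the trait scale; any statistic defined on
    cumulative-gain fractions (such as the dG90 cycle) is invariant to it.
    """
    series = np.asarray(mean_series, dtype=np.float64)
    if series.size < 2:
        raise ValueError("need a series of at least two cycle means")
    if ideal_value <= series[0]:
        raise ValueError("ideal value must exceed the initial mean")
    return 100.0 * np.diff(series) / (ideal_value - series[0])


def delta_g90(mean_series: np.ndarray) -> tuple[float, int]:
    """90% of the total cumulative gain and the first cycle reaching it.

    Returns (0.9 * (G_T - G_0), smallest t with G_t - G_0 >= 0.9 * total);
    a run with no net gain returns (0.0, 0).
    """
    series = np.asarray(mean_series, dtype=np.float64)
    total = series[-1] - series[0]
    if total <= 0:
        return 0.0, 0
    threshold = 0.9 * total
    cum = series - series[0]
    cycle = int(np.argmax(cum >= threshold * (1.0 - 1e-12)))
    return float(threshold), cycle


def _ideal_dosage_and_het(effects: EffectTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-QTL ideal dosage of allele 1, and whether the ideal is the
    heterozygote (overdominant loci: d above both homozygotes)."""
    het_ideal = effects.d > np.abs(effects.a)
    ideal_dos = np.where(effects.a >= 0, 2, 0)
    return ideal_dos, het_ideal


def hamming_distance(population: Population, system: GeneticSystem) -> float:
    """Mean allele substitutions to the ideal genotype, % of 2 x n_qtl slots.

    Per QTL: if the ideal is a homozygote, distance is |dosage - ideal
    dosage| (heterozygote 1, opposite homozygote 2); if the ideal is the
    heterozygote, either homozygote is one substitution away.  Marker loci
    have no favorable allele and are excluded.
    """
    if population.n == 0:
        raise ValueError("empty population")
    effects = system.effects
    if effects.n_qtl == 0:
        raise ValueError("need at least one QTL")
    dos = population.dosages(system.map.qtl_indices).astype(np.int64)
    ideal_dos, het_ideal = _ideal_dosage_and_het(effects)
    dist = np.where(het_ideal, dos != 1, np.abs(dos - ideal_dos))
    return float(dist.sum(axis=1).mean() / (2.0 * effects.n_qtl) * 100.0)


def fixation_rates(population: Population, system: GeneticSystem) -> tuple[float, float]:
    """Percent of QTL fixed for the favorable / non-favorable allele.

    A QTL is fixed when every individual is homozygous for the same allele;
    the favorable allele is the one of the higher-valued homozygote (the
    sign of a), also under overdominance for comparability of the rates
    across genetic models.
    """
    if population.n == 0:
        raise ValueError("empty population")
    effects = system.effects
    if effects.n_qtl == 0:
        return 0.0, 0.0
    dos = population.dosages(system.map.qtl_indices)
    fixed_1 = np.all(dos == 2, axis=0)
    fixed_0 = np.all(dos == 0, axis=0)
    fav_is_1 = effects.a >= 0
    fav = (fixed_1 & fav_is_1) | (fixed_0 & ~fav_is_1)
    nonfav = (fixed_1 & ~fav_is_1) | (fixed_0 & fav_is_1)
    scale = 100.0 / effects.n_qtl
    return float(fav.sum() * scale), float(nonfav.sum() * scale)


def cycle_stats(
    cycle: int,
    mean_genotypic_value: float,
    population: Population,
    system: GeneticSystem,
) -> CycleStats:
    """Bundle the three diversity statistics of a cycle's crossing block
    with the cycle's (separately computed) mean genotypic value."""
    fav, nonfav = fixation_rates(population, system)
    return CycleStats(
        cycle=cycle,
        mean_genotypic_value=mean_genotypic_value,
        hamming_pct=hamming_distance(population, system),
        fixed_favorable_pct=fav,
        fixed_nonfavorable_pct=nonfav,
    )


def write_outputs(run_result: RunResult, out_dir, run: int = 0) -> dict[str, Path]:
    """Write fit.tsv / ham.tsv / fre.tsv for one run (appending if present).

    fit.tsv: run, cycle, mean_genotypic_value, delta_g_pct (blank at cycle 0);
    ham.tsv: run, cycle, hamming_pct;
    fre.tsv: run, cycle, fixed_favorable_pct, fixed_nonfavorable_pct.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hist = run_result.history
    cycles = [s.cycle for s in hist]
    gains = np.concatenate([[np.nan], run_result.gain_percent()])
    fit = pd.DataFrame({
        "run": run, "cycle": cycles,
        "mean_genotypic_value": [s.mean_genotypic_value for s in hist],
        "delta_g_pct": gains,
    })
    ham = pd.DataFrame({
        "run": run, "cycle": cycles,
        "hamming_pct": [s.hamming_pct for s in hist],
    })
    fre = pd.DataFrame({
        "run": run, "cycle": cycles,
        "fixed_favorable_pct": [s.fixed_favorable_pct for s in hist],
        "fixed_nonfavorable_pct": [s.fixed_nonfavorable_pct for s in hist],
    })
    paths = {}
    for name, df in (("fit", fit), ("ham", ham), ("fre", fre)):
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, mode="a" if path.exists() else "w",
                  header=not path.exists(), float_format="%.17g")
        paths[name] = path
    return paths


def read_fit(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
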