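"""Field-trial simulation and heritability-driven error calibration.

Phenotypes follow P = G + R with a single environment type: year, location
and replicate carry no systematic effects, so all non-genetic variation is
pooled into one plant-level residual R ~ N(0, sigma2_R).  The residual
variance is not a free parameter; it is solved from the target family-mean
heritability

    h2_fm = sigma2_b / (sigma2_b + (sigma2_w + sigma2_R) / n_total)

where sigma2_b is the variance of true family genotypic means, sigma2_w the
mean within-family genotypic variance and n_total the plants tested per
family (years x locations x reps x plants per plot).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic_system import GeneticSystem
from .population import HalfSibFamily

__all__ = [
    "TrialDesign",
    "ErrorModel",
    "TrialResult",
    "calibrate_error_variance",
    "simulate_trial",
    "estimate_family_mean_h2",
]


@dataclass(frozen=True)
class TrialDesign:
    """A balanced years x locations x reps x plants-per-plot field trial."""

    years: int = 3
    locations: int = 3
    reps: int = 3
    plants_per_plot: int = 30

    def __post_init__(self) -> None:
        for name in ("years", "locations", "reps", "plants_per_plot"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def n_total(self) -> int:
        return self.years * self.locations * self.reps * self.plants_per_plot


@dataclass
class ErrorModel:
    """Plant-level residual variance and the heritability it was solved for."""

    sigma2_R: float
    target_h2_fm: float

    def __post_init__(self) -> None:
        if self.sigma2_R < 0:
            raise ValueError("sigma2_R must be >= 0")
        if not 0.0 < self.target_h2_fm <= 1.0:
            raise ValueError("target_h2_fm must lie in (0, 1]")


@dataclass
class TrialResult:
    """Phenotypes of a half-sib family trial, one row per family.

    ``phenotypes`` and ``genotypic_values`` are (k, n_total) matrices in
    family order; ``family_means`` is the row mean of ``phenotypes``.
    """

    family_ids: np.ndarray
    genotypic_values: np.ndarray
    phenotypes: np.ndarray
    family_means: np.ndarray

    def to_tsv(self, path) -> None:
        k, n = self.phenotypes.shape
        df = pd.DataFrame({
            "family_id": np.repeat(self.family_ids, n),
            "plant": np.tile(np.arange(n), k),
            "phenotype": self.phenotypes.ravel(),
            "genotypic_value": self.genotypic_values.ravel(),
        })
        df.to_csv(path, sep="\t", index=False)


def _family_value_matrix(
    families: list[HalfSibFamily], system: GeneticSystem, n_plants: int | None = None
) -> np.ndarray:
    rows = []
    for fam in families:
        g = fam.members.genotypic_values(system)
        if n_plants is not None:
            if fam.n < n_plants:
                raise ValueError(
                    f"family {fam.female_parent_id} has {fam.n} progeny; the "
                    f"trial needs {n_plants}"
                )
            g = g[:n_plants]
        rows.append(g)
    return np.asarray(rows)


def calibrate_error_variance(
    families: list[HalfSibFamily],
    design: TrialDesign,
    target_h2_fm: float,
    system: GeneticSystem,
) -> float:
    """Solve the plant-level residual variance for a target h2_fm.

    Returns max(0, n_total * sigma2_b * (1 - h2) / h2 - sigma2_w) computed
    from the true genotypic values of the supplied families; the floor
    applies when the design already exceeds the target (e.g. h2 = 1).
    """
    if len(families) < 2:
        raise ValueError("calibration needs >= 2 families to estimate sigma2_b")
    if not 0.0 < target_h2_fm <= 1.0:
        raise ValueError("target_h2_fm must lie in (0, 1]; 0 implies infinite noise")
    g = _family_value_matrix(families, system)
    sigma2_b = float(np.var(g.mean(axis=1), ddof=1))
    sigma2_w = float(np.mean(np.var(g, axis=1, ddof=1)))
    h2 = target_h2_fm
    return max(0.0, design.n_total * sigma2_b * (1.0 - h2) / h2 - sigma2_w)


def simulate_trial(
    families: list[HalfSibFamily],
    design: TrialDesign,
    sigma2_R: float,
    system: GeneticSystem,
    rng: np.random.Generator,
) -> TrialResult:
    """Phenotype n_total plants per family: P = G + N(0, sigma2_R).

    With a single environment type the year/location/rep structure carries
    no effects, so the trial reduces to n_total independent plant records
    per family.
    """
    if sigma2_R < 0:
        raise ValueError("sigma2_R must be >= 0")
    if not families:
        raise ValueError("no families to test")
    g = _family_value_matrix(families, system, design.n_total)
    noise = rng.normal(0.0, np.sqrt(sigma2_R), g.shape) if sigma2_R > 0 else 0.0
    phen = g + noise
    return TrialResult(
        family_ids=np.array([f.female_parent_id for f in families]),
        genotypic_values=g,
        phenotypes=phen,
        family_means=phen.mean(axis=1),
    )


def estimate_family_mean_h2(phenotypes: np.ndarray) -> float:
    """ANOVA-style realized family-mean heritability from a (k, n) trial.

    One-way variance decomposition: h2_fm = (MSB - MSW) / MSB, i.e. the
    among-family variance component over the variance of observed family
    means (clamped to [0, 1]).
    """
    phenotypes = np.asarray(phenotypes, dtype=np.float64)
    k, n = phenotypes.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 families and >= 2 plants per family")
    msb = n * np.var(phenotypes.mean(axis=1), ddof=1)
    msw = np.mean(np.var(phenotypes, axis=1, ddof=1))
    if msb <= 0:
        return 0.0
    return float(np.clip((msb - msw) / msb, 0.0, 1.0))
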