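"""Diploid individuals, map-based meiosis, crossing and half-sib families.

Populations are stored as a single ``(n, 2, L)`` uint8 allele array (two
haplotypes per individual, loci in map order) so that meiosis and genotypic
evaluation are vectorized across individuals.  ``Genotype`` objects are
lightweight per-individual views used at API boundaries.

Meiosis follows the Haldane model: no crossover interference, so the
parental strand switches between adjacent loci independently with
probability r = (1 - exp(-2 d/100))/2, and linkage groups assort
independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genetic_system import GeneticMap, GeneticSystem, genotypic_values

__all__ = [
    "Genotype",
    "Population",
    "HalfSibFamily",
    "PROPAGATION_MODES",
    "initial_population",
    "make_gamete",
    "cross",
    "make_halfsib_families",
    "bulk_propagate",
]

UNKNOWN_PARENT = -1

PROPAGATION_MODES = ("single_bulk", "bulk_per_family", "separate", "half_sib", "polycross")


@dataclass(frozen=True)
class Genotype:
    """One diploid individual: two 0/1 haplotypes aligned to the map order."""

    haplotypes: np.ndarray  # (2, L) uint8
    id: int = 0
    female_id: int = UNKNOWN_PARENT
    male_id: int = UNKNOWN_PARENT

    def __post_init__(self) -> None:
        h = np.asarray(self.haplotypes, dtype=np.uint8)
        if h.ndim != 2 or h.shape[0] != 2:
            raise ValueError("haplotypes must have shape (2, n_loci)")
        if h.max(initial=0) > 1:
            raise ValueError("alleles must be 0 or 1")
        object.__setattr__(self, "haplotypes", h)

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[1]

    def dosage(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0)


class Population:
    """A set of diploid individuals sharing one map, stored as allele arrays."""

    def __init__(
        self,
        haplotypes: np.ndarray,
        ids: np.ndarray | None = None,
        female_ids: np.ndarray | None = None,
        male_ids: np.ndarray | None = None,
        cycle: int = 0,
    ):
        haplotypes = np.asarray(haplotypes, dtype=np.uint8)
        if haplotypes.ndim != 3 or haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n, 2, n_loci)")
        n = haplotypes.shape[0]
        self.haplotypes = haplotypes
        self.ids = np.arange(n) if ids is None else np.asarray(ids, dtype=np.int64)
        self.female_ids = (
            np.full(n, UNKNOWN_PARENT) if female_ids is None
            else np.asarray(female_ids, dtype=np.int64)
        )
        self.male_ids = (
            np.full(n, UNKNOWN_PARENT) if male_ids is None
            else np.asarray(male_ids, dtype=np.int64)
        )
        if not (len(self.ids) == len(self.female_ids) == len(self.male_ids) == n):
            raise ValueError("id arrays must match the number of individuals")
        self.cycle = cycle

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    def __len__(self) -> int:
        return self.n

    def genotype(self, i: int) -> Genotype:
        return Genotype(
            self.haplotypes[i], int(self.ids[i]),
            int(self.female_ids[i]), int(self.male_ids[i]),
        )

    @property
    def members(self) -> list[Genotype]:
        return [self.genotype(i) for i in range(self.n)]

    @classmethod
    def from_genotypes(cls, genotypes: Sequence[Genotype], cycle: int = 0) -> "Population":
        if not genotypes:
            raise ValueError("a population needs at least one member")
        return cls(
            np.stack([g.haplotypes for g in genotypes]),
            ids=np.array([g.id for g in genotypes]),
            female_ids=np.array([g.female_id for g in genotypes]),
            male_ids=np.array([g.male_id for g in genotypes]),
            cycle=cycle,
        )

    def subset(self, index) -> "Population":
        return Population(
            self.haplotypes[index], self.ids[index],
            self.female_ids[index], self.male_ids[index], self.cycle,
        )

    def dosages(self, locus_indices=None) -> np.ndarray:
        """(n, L) counts of allele 1, optionally restricted to given loci."""
        d = self.haplotypes.sum(axis=1, dtype=np.uint8)
        return d if locus_indices is None else d[:, locus_indices]

    def genotypic_values(self, system: GeneticSystem) -> np.ndarray:
        return genotypic_values(self.dosages(system.map.qtl_indices), system.effects)

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 1))

    def to_tsv(self, path) -> None:
        """Export the 0/1/2 genotype matrix with pedigree columns."""
        df = pd.DataFrame(self.dosages(), columns=[f"L{j}" for j in range(self.n_loci)])
        df.insert(0, "male_id", self.male_ids)
        df.insert(0, "female_id", self.female_ids)
        df.insert(0, "id", self.ids)
        df.to_csv(path, sep="\t", index=False)


@dataclass
class HalfSibFamily:
    """Progeny bulked over one female parent; every member has that female
    as mother and some other crossing-block member as father (no selfs)."""

    female_parent_id: int
    members: Population

    def __post_init__(self) -> None:
        if np.any(self.members.female_ids != self.female_parent_id):
            raise ValueError("all members must share the family's female parent")
        if np.any(self.members.male_ids == self.female_parent_id):
            raise ValueError("self-pollination is excluded from half-sib families")

    @property
    def n(self) -> int:
        return self.members.n


def initial_population(
    system: GeneticSystem, n: int, rng: np.random.Generator
) -> Population:
    """Found a random parental population at allele frequency 0.5.

    Each individual carries exactly floor(L/2) heterozygous loci (a fresh
    random subset per individual, random phase); the remaining loci are
    split as evenly as possible between the two homozygote classes, the odd
    locus going to a coin-flipped class.  Pooled allele frequency is 0.5 in
    expectation at every locus.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    L = system.map.n_loci
    n_het = L // 2
    n_hom = L - n_het
    haps = np.zeros((n, 2, L), dtype=np.uint8)
    for i in range(n):
        perm = rng.permutation(L)
        het = perm[:n_het]
        phase = rng.integers(0, 2, n_het)
        haps[i, phase, het] = 1
        n_aa = n_hom // 2 + (int(rng.integers(0, 2)) if n_hom % 2 else 0)
        hom_ref = perm[n_het:n_het + (n_hom - n_aa)]
        haps[i, :, hom_ref] = 1
    return Population(haps, cycle=0)


def _gametes(
    haplotypes: np.ndarray,
    parent_index: np.ndarray,
    recomb: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized meiosis: one gamete per entry of ``parent_index``.

    ``recomb`` is the per-locus strand-switch probability from
    :meth:`GeneticMap.recombination_fractions`; the running XOR of the
    switch indicators selects which parental haplotype each locus is
    copied from.
    """
    m = parent_index.size
    switch = rng.random((m, recomb.size)) < recomb
    chooser = np.bitwise_xor.accumulate(switch, axis=1)
    hap0 = haplotypes[parent_index, 0, :]
    hap1 = haplotypes[parent_index, 1, :]
    return np.where(chooser, hap1, hap0)


def make_gamete(
    genotype: Genotype, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """One meiotic product of ``genotype`` as a 0/1 haplotype vector."""
    if genotype.n_loci != gmap.n_loci:
        raise ValueError("genotype and map are not aligned")
    haps = genotype.haplotypes[np.newaxis]
    return _gametes(haps, np.zeros(1, dtype=np.intp),
                    gmap.recombination_fractions(), rng)[0]


def cross(
    female: Genotype, male: Genotype, gmap: GeneticMap,
    rng: np.random.Generator, offspring_id: int = 0,
) -> Genotype:
    """Mate two individuals: one gamete from each, pedigree recorded."""
    gf = make_gamete(female, gmap, rng)
    gm = make_gamete(male, gmap, rng)
    return Genotype(np.stack([gf, gm]), offspring_id, female.id, male.id)


def make_halfsib_families(
    crossing_block: Population,
    progeny_per_family: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
    start_id: int | None = None,
) -> list[HalfSibFamily]:
    """Polycross the crossing block into one half-sib family per female.

    Every block member serves as female of one family; each progeny's male
    parent is redrawn uniformly from the *other* block members, so selfs
    never occur and the pollen cloud is an even mixture of the remaining
    parents.
    """
    k = crossing_block.n
    if k < 2:
        raise ValueError(
            "a crossing block needs >= 2 members: with selfing excluded a "
            "single parent has no pollen source"
        )
    if progeny_per_family < 1:
        raise ValueError("progeny_per_family must be >= 1")
    npf = progeny_per_family
    total = k * npf
    mothers = np.repeat(np.arange(k, dtype=np.intp), npf)
    fathers = rng.integers(0, k - 1, size=total).astype(np.intp)
    fathers += fathers >= mothers  # skip the mother's own slot
    recomb = gmap.recombination_fractions()
    gam_f = _gametes(crossing_block.haplotypes, mothers, recomb, rng)
    gam_m = _gametes(crossing_block.haplotypes, fathers, recomb, rng)
    haps = np.stack([gam_f, gam_m], axis=1)
    first = (int(crossing_block.ids.max()) + 1) if start_id is None else start_id
    progeny = Population(
        haps,
        ids=np.arange(first, first + total),
        female_ids=crossing_block.ids[mothers],
        male_ids=crossing_block.ids[fathers],
        cycle=crossing_block.cycle + 1,
    )
    return [
        HalfSibFamily(
            int(crossing_block.ids[f]),
            progeny.subset(slice(f * npf, (f + 1) * npf)),
        )
        for f in range(k)
    ]


def bulk_propagate(
    populations: Sequence[Population | HalfSibFamily],
    mode: str,
    *,
    progeny_per_family: int | None = None,
    gmap: GeneticMap | None = None,
    rng: np.random.Generator | None = None,
):
    """Reorganize or propagate selected material into next-stage populations.

    Modes mirror the propagation options of family-based breeding
    simulators: ``single_bulk`` concatenates everything into one
    population; ``bulk_per_family`` keeps one population per input family;
    ``separate`` splits every genotype into its own singleton population;
    ``half_sib`` / ``polycross`` merge the inputs into one crossing block
    and run a polycross via :func:`make_halfsib_families`.
    """
    if mode not in PROPAGATION_MODES:
        raise ValueError(f"unknown propagation mode {mode!r}")
    pops = [p.members if isinstance(p, HalfSibFamily) else p for p in populations]
    if not pops:
        raise ValueError("no populations to propagate")

    def merged() -> Population:
        return Population(
            np.concatenate([p.haplotypes for p in pops]),
            np.concatenate([p.ids for p in pops]),
            np.concatenate([p.female_ids for p in pops]),
            np.concatenate([p.male_ids for p in pops]),
            cycle=pops[0].cycle,
        )

    if mode == "single_bulk":
        return [merged()]
    if mode == "bulk_per_family":
        return list(pops)
    if mode == "separate":
        m = merged()
        return [m.subset(slice(i, i + 1)) for i in range(m.n)]
    if progeny_per_family is None or gmap is None or rng is None:
        raise ValueError(f"mode {mode!r} needs progeny_per_family, gmap and rng")
    return make_halfsib_families(merged(), progeny_per_family, gmap, rng)
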