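"""Genotype-environment system: linkage map, QTL effects and genotypic values.

The trait model is the classical biallelic per-locus parameterization: at a
QTL with alleles A/a, the three genotypes take values

    AA -> +a        Aa -> d        aa -> -a

where ``a`` is half the difference between the homozygotes and ``d`` the
dominance deviation of the heterozygote from the homozygote midpoint.  The
genotypic value of an individual is the sum of these per-locus contributions
(no epistasis), and the phenotype adds an environmental residual on top.

Three genetic-effect models are supported for sampling effect tables:

``additive``
    every QTL purely additive (d = 0);
``additive_dominance``
    half the QTL additive, the rest split between partial dominance
    (0 < |d| < |a|) and overdominance (|d| > |a|);
``dominance``
    every QTL shows partial or over dominance, none purely additive.

Additive effects are drawn from N(0, 1).  Dominance degrees are drawn as
``d = u * |a| * sign(a)`` with ``u ~ U(0,1)`` for partial and ``u ~ U(1,2)``
for overdominance, so the favorable allele is always well defined.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Locus",
    "GeneticMap",
    "EffectTable",
    "GeneticSystem",
    "GENETIC_MODELS",
    "build_synthetic_map",
    "sample_qtl_effects",
    "genotypic_value",
    "genotypic_values",
    "ideal_genotype_value",
]

GENETIC_MODELS = ("additive", "additive_dominance", "dominance")
DOMINANCE_CLASSES = ("none", "partial", "over")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class Locus:
    """A single map position, either a QTL or a neutral marker."""

    id: str
    linkage_group: int
    position: float  # centimorgans from the top of the group
    kind: str  # "qtl" | "marker"

    def __post_init__(self) -> None:
        if self.kind not in ("qtl", "marker"):
            raise ValueError(f"unknown locus kind {self.kind!r}")
        if self.position < 0:
            raise ValueError(f"negative map position for locus {self.id!r}")


class GeneticMap:
    """An ordered collection of loci grouped into linkage groups.

    Loci are stored sorted by (linkage group, position); all allele arrays in
    :mod:`halfsibsim.population` are aligned to this order.
    """

    def __init__(self, loci: Iterable[Locus]):
        loci = sorted(loci, key=lambda l: (l.linkage_group, l.position))
        if not loci:
            raise ValueError("a genetic map needs at least one locus")
        ids = [l.id for l in loci]
        if len(set(ids)) != len(ids):
            raise ValueError("locus ids must be unique")
        self.loci: list[Locus] = loci
        self.group = np.array([l.linkage_group for l in loci], dtype=np.int64)
        self.position = np.array([l.position for l in loci], dtype=np.float64)
        self.is_qtl = np.array([l.kind == "qtl" for l in loci], dtype=bool)
        self.qtl_indices = np.flatnonzero(self.is_qtl)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_qtl(self) -> int:
        return int(self.is_qtl.sum())

    @property
    def n_markers(self) -> int:
        return self.n_loci - self.n_qtl

    def recombination_fractions(self) -> np.ndarray:
        """Per-locus probability of switching parental strand during meiosis.

        Entry ``j`` is the recombination fraction between locus ``j-1`` and
        locus ``j`` under the Haldane mapping function (no interference),

            r = (1 - exp(-2 * d_cM / 100)) / 2.

        The first locus of every linkage group (including the very first
        locus) gets r = 0.5: independent assortment across groups and a fair
        choice of starting strand.
        """
        delta = np.diff(self.position, prepend=self.position[:1])
        r = 0.5 * (1.0 - np.exp(-2.0 * delta / 100.0))
        new_group = np.ones(self.n_loci, dtype=bool)
        new_group[1:] = self.group[1:] != self.group[:-1]
        r[new_group] = 0.5
        return r

    def __len__(self) -> int:
        return self.n_loci

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneticMap):
            return NotImplemented
        return self.loci == other.loci


class EffectTable:
    """Per-QTL additive (a) and dominance (d) effects, in trait units.

    Rows are aligned with the map's QTL in map order.  ``dominance_class``
    records how each d was generated and is validated against the values:
    ``none`` requires d == 0, ``partial`` 0 < |d| < |a|, ``over`` |d| > |a|.
    """

    def __init__(
        self,
        a: Sequence[float],
        d: Sequence[float],
        dominance_class: Sequence[str],
    ):
        self.a = np.asarray(a, dtype=np.float64)
        self.d = np.asarray(d, dtype=np.float64)
        self.dominance_class = np.asarray(dominance_class, dtype=object)
        if not (self.a.shape == self.d.shape == self.dominance_class.shape):
            raise ValueError("a, d and dominance_class must be equally long")
        for cls in np.unique(self.dominance_class):
            if cls not in DOMINANCE_CLASSES:
                raise ValueError(f"unknown dominance class {cls!r}")
        none_mask = self.dominance_class == "none"
        if np.any(self.d[none_mask] != 0.0):
            raise ValueError("class 'none' requires d = 0")
        part = self.dominance_class == "partial"
        if np.any(~((np.abs(self.d[part]) > 0) & (np.abs(self.d[part]) < np.abs(self.a[part])))):
            raise ValueError("class 'partial' requires 0 < |d| < |a|")
        over = self.dominance_class == "over"
        if np.any(~(np.abs(self.d[over]) > np.abs(self.a[over]))):
            raise ValueError("class 'over' requires |d| > |a|")

    @property
    def n_qtl(self) -> int:
        return self.a.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EffectTable):
            return NotImplemented
        return (
            np.array_equal(self.a, other.a)
            and np.array_equal(self.d, other.d)
            and np.array_equal(self.dominance_class, other.dominance_class)
        )


@dataclass
class GeneticSystem:
    """A complete genotype-environment system for one simulated trait.

    Couples the linkage map with the QTL effect table and the run-level
    metadata: the genetic-effects model used to sample effects, the number of
    environment types (a single type here: no GxE deviations are simulated),
    the epistasis connectivity (restricted to 0 -- purely per-locus gene
    action), and the founding allele frequency.
    """

    map: GeneticMap
    effects: EffectTable
    model: str
    n_env_types: int = 1
    epistasis_k: int = 0
    init_allele_freq: float = 0.5

    def __post_init__(self) -> None:
        if self.model not in GENETIC_MODELS:
            raise ValueError(f"unknown genetic model {self.model!r}")
        if self.epistasis_k != 0:
            raise ValueError(
                "epistasis networks (K > 0) are not supported; K must be 0"
            )
        if self.n_env_types < 1:
            raise ValueError("n_env_types must be >= 1")
        if not 0.0 < self.init_allele_freq < 1.0:
            raise ValueError("init_allele_freq must lie strictly in (0, 1)")
        if self.effects.n_qtl != self.map.n_qtl:
            raise ValueError(
                f"effect table has {self.effects.n_qtl} QTL but the map has "
                f"{self.map.n_qtl}"
            )

    # -- serialization ----------------------------------------------------

    _HEADER_KEYS = ("model", "n_env_types", "epistasis_k", "init_allele_freq")

    def to_tsv(self, path) -> None:
        """Write the system as a key-value header block plus a locus table."""
        is_q = self.map.is_qtl
        qpos = np.cumsum(is_q) - 1  # row in the effect table for each QTL
        rows = []
        for i, locus in enumerate(self.map.loci):
            if is_q[i]:
                j = qpos[i]
                a, d, cls = self.effects.a[j], self.effects.d[j], self.effects.dominance_class[j]
                rows.append((locus.id, locus.linkage_group, locus.position,
                             locus.kind, repr(float(a)), repr(float(d)), cls))
            else:
                rows.append((locus.id, locus.linkage_group, locus.position,
                             locus.kind, "", "", ""))
        buf = io.StringIO()
        for key in self._HEADER_KEYS:
            buf.write(f"#{key}\t{getattr(self, key)!r}\n")
        df = pd.DataFrame(
            rows,
            columns=["locus_id", "linkage_group", "position_cM", "kind", "a", "d",
                     "dominance_class"],
        )
        df.to_csv(buf, sep="\t", index=False)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_tsv(cls, path) -> "GeneticSystem":
        header: dict[str, str] = {}
        body_lines = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, value = line[1:].rstrip("\n").partition("\t")
                    header[key] = value
                else:
                    body_lines.append(line)
        df = pd.read_csv(
            io.StringIO("".join(body_lines)), sep="\t",
            dtype={"locus_id": str, "kind": str, "a": str, "d": str,
                   "dominance_class": str},
            keep_default_na=False,
        )
        loci = [
            Locus(r.locus_id, int(r.linkage_group), float(r.position_cM), r.kind)
            for r in df.itertuples()
        ]
        q = df[df["kind"] == "qtl"]
        effects = EffectTable(
            [float(x) for x in q["a"]],
            [float(x) for x in q["d"]],
            list(q["dominance_class"]),
        )
        import ast

        return cls(
            map=GeneticMap(loci),
            effects=effects,
            model=ast.literal_eval(header["model"]),
            n_env_types=ast.literal_eval(header["n_env_types"]),
            epistasis_k=ast.literal_eval(header["epistasis_k"]),
            init_allele_freq=ast.literal_eval(header["init_allele_freq"]),
        )


def build_synthetic_map(
    n_groups: int,
    n_qtl: int,
    n_markers: int,
    group_length_cM: float,
    rng: np.random.Generator,
) -> GeneticMap:
    """Generate a random linkage map with the requested locus counts.

    QTL and markers are spread across ``n_groups`` linkage groups as evenly
    as integer division allows (the first groups absorb the remainder);
    positions are drawn uniformly on [0, group_length_cM] and sorted within
    each group.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if n_qtl < 0 or n_markers < 0 or n_qtl + n_markers < 1:
        raise ValueError("need a non-negative locus count with >= 1 locus in total")
    if group_length_cM <= 0:
        raise ValueError("group_length_cM must be positive")

    def split(total: int) -> list[int]:
        base, rem = divmod(total, n_groups)
        return [base + (1 if g < rem else 0) for g in range(n_groups)]

    loci: list[Locus] = []
    qtl_per_group, mark_per_group = split(n_qtl), split(n_markers)
    iq = im = 0
    for g in range(n_groups):
        for _ in range(qtl_per_group[g]):
            loci.append(Locus(f"Q{iq:04d}", g, float(rng.uniform(0, group_length_cM)), "qtl"))
            iq += 1
        for _ in range(mark_per_group[g]):
            loci.append(Locus(f"M{im:04d}", g, float(rng.uniform(0, group_length_cM)), "marker"))
            im += 1
    return GeneticMap(loci)


def sample_qtl_effects(
    model: str, n_qtl: int, rng: np.random.Generator
) -> EffectTable:
    """Draw a QTL effect table under one of the three genetic models.

    Additive effects a ~ N(0, 1) for every QTL.  Dominance classes are
    assigned by a deterministic count split (round-half-up for the additive
    share) over a random permutation of the loci:

    - ``additive``: all loci class ``none``;
    - ``additive_dominance``: round(n/2) loci ``none``; the remainder split
      as evenly as possible between ``partial`` and ``over`` (partial gets
      the odd locus);
    - ``dominance``: all loci split between ``partial`` and ``over``.
    """
    if model not in GENETIC_MODELS:
        raise ValueError(f"unknown genetic model {model!r}")
    if n_qtl < 0:
        raise ValueError("n_qtl must be >= 0")
    a = rng.standard_normal(n_qtl)
    if model == "additive":
        n_none = n_qtl
    elif model == "additive_dominance":
        n_none = _round_half_up(n_qtl / 2)
    else:
        n_none = 0
    n_dom = n_qtl - n_none
    n_partial = _round_half_up(n_dom / 2)
    classes = np.array(
        ["none"] * n_none + ["partial"] * n_partial + ["over"] * (n_dom - n_partial),
        dtype=object,
    )
    classes = classes[rng.permutation(n_qtl)] if n_qtl else classes
    d = np.zeros(n_qtl)
    part = classes == "partial"
    over = classes == "over"
    d[part] = rng.uniform(0.0, 1.0, part.sum()) * np.abs(a[part]) * np.sign(a[part])
    d[over] = rng.uniform(1.0, 2.0, over.sum()) * np.abs(a[over]) * np.sign(a[over])
    return EffectTable(a, d, classes)


def genotypic_values(qtl_dosage: np.ndarray, effects: EffectTable) -> np.ndarray:
    """Genotypic values for an (n_individuals, n_qtl) allele-1 dosage matrix.

    Dosage 2 contributes +a, 1 contributes d, 0 contributes -a; markers are
    excluded from the dosage matrix by construction.
    """
    qtl_dosage = np.asarray(qtl_dosage)
    if qtl_dosage.shape[-1] != effects.n_qtl:
        raise ValueError(
            f"dosage matrix has {qtl_dosage.shape[-1]} loci, effect table "
            f"has {effects.n_qtl}"
        )
    dos = qtl_dosage.astype(np.float64)
    return (effects.a * (dos - 1.0) + effects.d * (dos == 1)).sum(axis=-1)


def genotypic_value(genotype, system: GeneticSystem) -> float:
    """Genotypic value of one individual under the system's effect table."""
    haps = np.asarray(genotype.haplotypes)
    if haps.shape[-1] != system.map.n_loci:
        raise ValueError(
            f"genotype has {haps.shape[-1]} loci but the map has {system.map.n_loci}"
        )
    dosage = haps.sum(axis=0)[system.map.qtl_indices]
    return float(genotypic_values(dosage[np.newaxis, :], system.effects)[0])


def ideal_genotype_value(effects: EffectTable) -> float:
    """Value of the locus-wise best genotype.

    Each QTL contributes max(a, d, -a): the better homozygote, or the
    heterozygote under overdominance.  Empty tables contribute 0.
    """
    if effects.n_qtl == 0:
        return 0.0
    return float(np.maximum(np.abs(effects.a), effects.d).sum())
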