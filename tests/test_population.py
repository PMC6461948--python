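"""Founding populations, meiosis, crossing and half-sib family construction."""

import numpy as np
import pytest
from scipy import stats

from halfsibsim import (
    GeneticMap,
    GeneticSystem,
    Genotype,
    Locus,
    Population,
    bulk_propagate,
    cross,
    initial_population,
    make_gamete,
    make_halfsib_families,
    sample_qtl_effects,
)
from halfsibsim.population import _gametes


def _two_locus_system(distance_cM, same_group=True):
    loci = [
        Locus("a", 0, 0.0, "qtl"),
        Locus("b", 0 if same_group else 1, distance_cM if same_group else 0.0, "qtl"),
    ]
    gmap = GeneticMap(loci)
    eff = sample_qtl_effects("additive", 2, np.random.default_rng(0))
    return GeneticSystem(gmap, eff, "additive")


class TestInitialPopulation:
    def test_heterozygous_locus_count(self, case_study_system, rng):
        pop = initial_population(case_study_system, 10, rng)
        assert pop.n == 10
        het = (pop.dosages() == 1).sum(axis=1)
        assert np.all(het == 128)  # floor(257 / 2)

    def test_two_locus_split(self, rng):
        sys_ = _two_locus_system(10.0)
        pop = initial_population(sys_, 1, rng)
        dos = pop.dosages()[0]
        assert (dos == 1).sum() == 1 and (dos != 1).sum() == 1

    def test_pooled_allele_frequency_near_half(self, small_system, rng):
        pop = initial_population(small_system, 1000, rng)
        freqs = pop.allele_frequencies()
        assert np.all(np.abs(freqs - 0.5) < 0.05)

    def test_empty_population_rejected(self, small_system, rng):
        with pytest.raises(ValueError):
            initial_population(small_system, 0, rng)


class TestMakeGamete:
    def test_homozygous_parent_transmits_its_haplotype(self, small_system, rng):
        L = small_system.map.n_loci
        haps = np.tile(rng.integers(0, 2, L, dtype=np.uint8), (2, 1))
        g = make_gamete(Genotype(haps), small_system.map, rng)
        assert np.array_equal(g, haps[0])

    def test_zero_distance_never_recombines(self, rng):
        sys_ = _two_locus_system(0.0)
        parent = Genotype(np.array([[1, 1], [0, 0]], dtype=np.uint8))
        gams = _gametes(
            parent.haplotypes[None], np.zeros(2000, dtype=np.intp),
            sys_.map.recombination_fractions(), rng,
        )
        assert not np.any(gams[:, 0] != gams[:, 1])

    @pytest.mark.parametrize(
        "distance,same_group,expected",
        [
            (20.0, True, 0.5 * (1 - np.exp(-0.4))),  # Haldane at 20 cM
            (10.0, False, 0.5),  # unlinked: independent assortment
        ],
    )
    def test_recombinant_fraction(self, rng, distance, same_group, expected):
        sys_ = _two_locus_system(distance, same_group)
        parent = Genotype(np.array([[1, 1], [0, 0]], dtype=np.uint8))
        gams = _gametes(
            parent.haplotypes[None], np.zeros(100_000, dtype=np.intp),
            sys_.map.recombination_fractions(), rng,
        )
        frac = np.mean(gams[:, 0] != gams[:, 1])
        assert frac == pytest.approx(expected, abs=0.01)


class TestCross:
    def test_fixed_cross_is_fully_heterozygous(self, small_system, rng):
        L = small_system.map.n_loci
        female = Genotype(np.ones((2, L), dtype=np.uint8), id=1)
        male = Genotype(np.zeros((2, L), dtype=np.uint8), id=2)
        child = cross(female, male, small_system.map, rng, offspring_id=3)
        assert np.all(child.dosage() == 1)
        assert child.female_id == 1 and child.male_id == 2

    def test_identical_homozygous_parents_breed_true(self, small_system, rng):
        L = small_system.map.n_loci
        haps = np.tile(rng.integers(0, 2, L, dtype=np.uint8), (2, 1))
        p = Genotype(haps)
        child = cross(p, p, small_system.map, rng)
        assert np.array_equal(child.haplotypes, haps)

    def test_offspring_frequency_matches_mid_parent(self, small_system, rng):
        L = small_system.map.n_loci
        female = Genotype(rng.integers(0, 2, (2, L), dtype=np.uint8))
        male = Genotype(rng.integers(0, 2, (2, L), dtype=np.uint8))
        mid = (female.dosage() + male.dosage()) / 4.0
        dosages = np.zeros(L)
        n = 10_000
        for _ in range(n):
            dosages += cross(female, male, small_system.map, rng).dosage()
        assert np.allclose(dosages / (2 * n), mid, atol=0.02)


class TestHalfSibFamilies:
    def test_one_family_per_female_no_selfing(self, small_system, rng):
        block = initial_population(small_system, 10, rng)
        fams = make_halfsib_families(block, 20, small_system.map, rng)
        assert len(fams) == 10
        for fam in fams:
            assert np.all(fam.members.female_ids == fam.female_parent_id)
            assert not np.any(fam.members.male_ids == fam.female_parent_id)

    def test_two_parents_degenerate_to_full_sibs(self, small_system, rng):
        block = initial_population(small_system, 2, rng)
        fams = make_halfsib_families(block, 15, small_system.map, rng)
        assert np.all(fams[0].members.male_ids == block.ids[1])
        assert np.all(fams[1].members.male_ids == block.ids[0])

    def test_single_parent_rejected(self, small_system, rng):
        block = initial_population(small_system, 1, rng)
        with pytest.raises(ValueError):
            make_halfsib_families(block, 5, small_system.map, rng)

    def test_male_usage_uniform(self, rng):
        sys_ = _two_locus_system(10.0)
        block = initial_population(sys_, 10, rng)
        fams = make_halfsib_families(block, 10_000, sys_.map, rng)
        counts = np.bincount(fams[0].members.male_ids, minlength=10)[1:]
        chi2 = stats.chisquare(counts)
        assert chi2.pvalue > 0.001

    def test_pedigree_traceability(self, small_system, rng):
        # every transmitted allele exists in the corresponding parent haplotypes
        block = initial_population(small_system, 4, rng)
        fams = make_halfsib_families(block, 5, small_system.map, rng)
        for fam in fams:
            for child in fam.members.members:
                mother = block.genotype(int(np.flatnonzero(block.ids == child.female_id)[0]))
                father = block.genotype(int(np.flatnonzero(block.ids == child.male_id)[0]))
                for hap, parent in ((0, mother), (1, father)):
                    ok = (child.haplotypes[hap] == parent.haplotypes[0]) | (
                        child.haplotypes[hap] == parent.haplotypes[1]
                    )
                    assert np.all(ok)


class TestDriftNeutrality:
    def test_allele_frequency_martingale(self, rng):
        # random mating without selection must not move allele frequency
        sys_ = _two_locus_system(50.0)
        finals = []
        for _ in range(200):
            block = initial_population(sys_, 20, rng)
            for _ in range(3):
                fams = make_halfsib_families(block, 1, sys_.map, rng)
                block = bulk_propagate(fams, "single_bulk")[0]
            finals.append(block.allele_frequencies().mean())
        finals = np.asarray(finals)
        se = finals.std(ddof=1) / np.sqrt(len(finals))
        assert abs(finals.mean() - 0.5) < 3 * se + 1e-12


class TestBulkPropagate:
    def test_single_bulk_concatenates(self, small_system, rng):
        block = initial_population(small_system, 3, rng)
        fams = make_halfsib_families(block, 5, small_system.map, rng)
        out = bulk_propagate(fams, "single_bulk")
        assert len(out) == 1 and out[0].n == 15

    def test_separate_gives_singletons(self, small_system, rng):
        block = initial_population(small_system, 3, rng)
        fams = make_halfsib_families(block, 5, small_system.map, rng)
        out = bulk_propagate(fams, "separate")
        assert len(out) == 15 and all(p.n == 1 for p in out)

    def test_bulk_per_family_preserves_structure(self, small_system, rng):
        block = initial_population(small_system, 3, rng)
        fams = make_halfsib_families(block, 5, small_system.map, rng)
        out = bulk_propagate(fams, "bulk_per_family")
        assert [p.n for p in out] == [5, 5, 5]

    def test_half_sib_mode_satisfies_family_invariants(self, small_system, rng):
        block = initial_population(small_system, 4, rng)
        pops = [block.subset(slice(i, i + 1)) for i in range(block.n)]
        fams = bulk_propagate(
            pops, "half_sib", progeny_per_family=6, gmap=small_system.map, rng=rng
        )
        assert len(fams) == 4
        for fam in fams:  # HalfSibFamily.__post_init__ audits the invariants
            assert fam.n == 6

    def test_unknown_mode_rejected(self, small_system, rng):
        block = initial_population(small_system, 3, rng)
        with pytest.raises(ValueError):
            bulk_propagate([block], "clone_everything")


class TestGenotypeMatrixExport:
    def test_tsv_has_pedigree_and_dosage_columns(self, tmp_path, small_system, rng):
        import pandas as pd

        block = initial_population(small_system, 3, rng)
        fam = make_halfsib_families(block, 4, small_system.map, rng)[0]
        path = tmp_path / "genotypes.tsv"
        fam.members.to_tsv(path)
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns[:3]) == ["id", "female_id", "male_id"]
        assert df.shape == (4, 3 + small_system.map.n_loci)
        assert np.array_equal(
            df.iloc[:, 3:].to_numpy(dtype=np.uint8), fam.members.dosages()
        )
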