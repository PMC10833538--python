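import numpy as np
import pytest

from holeysim import (
    ExplicitLandscape,
    Genotype,
    Population,
    count_II,
    jost_D,
    measure_DFE,
    measure_RI,
    population_robustness,
    sample_between_II,
    sample_within_II,
    sequence_diversity,
)
from holeysim.genotypes import iter_all_genotypes


def _mono(seq, N=10):
    return Population.from_ancestor(Genotype(seq, "binary"), N)


class TestCountII:
    def test_worked_example_two_incompatibilities(self, five_locus_example):
        land, (pop1, pop2) = five_locus_example
        assert count_II(pop1, pop2, land) == 2

    def test_zero_for_identical_genotypes(self, five_locus_example):
        land, (pop1, _) = five_locus_example
        assert count_II(pop1, pop1, land) == 0

    def test_zero_on_fully_viable_landscape(self, all_viable_L6, rng):
        a = Genotype("000000", "binary")
        b = Genotype("111111", "binary")
        assert count_II(a, b, all_viable_L6) == 0

    def test_inviable_input_rejected(self):
        land = ExplicitLandscape(3, "binary", inviable=["111"])
        with pytest.raises(ValueError):
            count_II(Genotype("111", "binary"), Genotype("000", "binary"), land)

    def test_bounded_by_divergence(self, rr_land, rng):
        from holeysim.experiments import random_viable_genotype

        for _ in range(20):
            a = random_viable_genotype(rr_land, 30, "binary", rng)
            b = random_viable_genotype(rr_land, 30, "binary", rng)
            k = int((a.codes != b.codes).sum())
            assert 0 <= count_II(a, b, rr_land) <= k


class TestSampleII:
    def test_identical_populations_zero(self, five_locus_example, rng):
        land, (pop1, _) = five_locus_example
        p = Population.from_ancestor(pop1, 20)
        s12, s21 = sample_between_II(p, p, land, rng=rng)
        assert s12.mean_II == 0.0 and s21.mean_II == 0.0

    def test_monomorphic_worked_example_exact(self, five_locus_example, rng):
        land, (g1, g2) = five_locus_example
        p1, p2 = Population.from_ancestor(g1, 30), Population.from_ancestor(g2, 30)
        s12, s21 = sample_between_II(p1, p2, land, rng=rng)
        assert s12.mean_II == 2.0  # alleles A and c are lethal in background 2
        assert s12.direction == (1, 2)
        assert all(c == 2 for c in s12.per_pair)

    def test_pair_count_is_N_when_small(self, five_locus_example, rng):
        land, (g1, g2) = five_locus_example
        p1, p2 = Population.from_ancestor(g1, 10), Population.from_ancestor(g2, 10)
        s12, _ = sample_between_II(p1, p2, land, max_pairs=100, rng=rng)
        assert s12.pair_count == 10

    def test_within_monomorphic_zero(self, five_locus_example, rng):
        land, (g1, _) = five_locus_example
        assert sample_within_II(
            Population.from_ancestor(g1, 40), land, rng=rng
        ).mean_II == 0.0

    def test_within_mixture_matches_enumeration(self, rng):
        # population half 000 / half 011; exchanging the variant alleles one
        # at a time creates 010 and 001 (lethal) from 000->011 direction and
        # 001/010 from the other; enumerate expectation over random pairs
        land = ExplicitLandscape(3, "binary", inviable=["010", "001"])
        codes = np.array([[0, 0, 0]] * 10 + [[0, 1, 1]] * 10, dtype=np.uint8)
        pop = Population(codes, "binary")
        # ordered mixed pair (000, 011): introgress 1 at site1 -> 010 lethal,
        # site2 -> 001 lethal => II = 2; (011, 000): 001, 010 => also 2.
        # P(mixed ordered pair) = 2 * (10/20) * (10/19)
        expected = 2 * (10 / 20) * (10 / 19) * 2
        vals = [
            sample_within_II(pop, land, rng=np.random.default_rng(s)).mean_II
            for s in range(400)
        ]
        assert np.mean(vals) == pytest.approx(expected, rel=0.1)


class TestJostD:
    def test_identical_monomorphic_zero(self):
        assert jost_D(_mono("00000"), _mono("00000")) == 0.0

    def test_fixed_differences_give_k_over_L(self):
        # matches the weak-mutation distance D = k/L for monomorphic pairs
        assert jost_D(_mono("11000"), _mono("00000")) == pytest.approx(2 / 5)
        assert jost_D(_mono("11111"), _mono("00000")) == 1.0

    def test_symmetry_and_range(self, rng):
        for _ in range(20):
            a = Population(rng.integers(0, 2, (12, 6)).astype(np.uint8), "binary")
            b = Population(rng.integers(0, 2, (12, 6)).astype(np.uint8), "binary")
            d1, d2 = jost_D(a, b), jost_D(b, a)
            assert d1 == pytest.approx(d2)
            assert 0.0 <= d1 <= 1.0

    def test_shared_polymorphism_is_not_differentiation(self):
        codes = np.array([[0], [1]] * 5, dtype=np.uint8)
        a = Population(codes.copy(), "binary")
        b = Population(codes.copy(), "binary")
        assert jost_D(a, b) == 0.0


class TestSequenceDiversity:
    def test_monomorphic_zero(self):
        assert sequence_diversity(_mono("0000")) == 0.0

    def test_single_polymorphic_locus(self):
        codes = np.zeros((10, 5), dtype=np.uint8)
        codes[:5, 0] = 1
        assert sequence_diversity(Population(codes, "binary")) == pytest.approx(0.5 / 5)

    def test_maximal_four_allele_locus(self):
        codes = np.arange(4, dtype=np.uint8).reshape(4, 1)
        assert sequence_diversity(Population(codes, "rna")) == pytest.approx(0.75)

    def test_invariant_under_member_order(self, rng):
        codes = rng.integers(0, 2, (20, 8)).astype(np.uint8)
        pi1 = sequence_diversity(Population(codes, "binary"))
        pi2 = sequence_diversity(Population(codes[::-1], "binary"))
        assert pi1 == pytest.approx(pi2)


class TestPopulationRobustness:
    def test_monomorphic_is_exact(self, five_locus_example, rng):
        from holeysim import genotype_robustness

        land, (g1, _) = five_locus_example
        pop = Population.from_ancestor(g1, 25)
        assert population_robustness(pop, land, rng=rng) == pytest.approx(
            genotype_robustness(g1, land)
        )

    def test_fully_viable_is_one(self, all_viable_L6, rng):
        pop = Population.from_ancestor(Genotype("000000", "binary"), 10)
        assert population_robustness(pop, all_viable_L6, rng=rng) == 1.0


class TestMeasureRI:
    def test_identical_fit_populations_no_isolation(self, all_viable_L6, rng):
        pop = Population.from_ancestor(Genotype("000000", "binary"), 20)
        assert measure_RI(pop, pop, all_viable_L6, "free", rng) == 0.0

    def test_fully_incompatible_pair_matches_enumeration(self, two_island_L3, rng):
        # only the pure parental genotypes survive free recombination:
        # P(viable hybrid) = 2 * (1/2)^L, so RI -> 1 - 2^(1-L) = 0.75 at L=3
        p1 = Population.from_ancestor(Genotype("000", "binary"), 4000)
        p2 = Population.from_ancestor(Genotype("111", "binary"), 4000)
        ri = measure_RI(p1, p2, two_island_L3, "free", rng)
        assert ri == pytest.approx(1 - 2 ** (1 - 3), abs=0.02)

    def test_none_regime_substitutes_recombinant_hybrids(self, two_island_L3, rng):
        # cloning a parent would trivially give RI = 0; hybrids must recombine
        p1 = Population.from_ancestor(Genotype("000", "binary"), 2000)
        p2 = Population.from_ancestor(Genotype("111", "binary"), 2000)
        ri = measure_RI(p1, p2, two_island_L3, "none", rng)
        assert ri == pytest.approx(0.75, abs=0.03)


class TestMeasureDFE:
    def test_fully_neutral_landscape(self, all_viable_L6, rng):
        pop = Population.from_ancestor(Genotype("000000", "binary"), 10)
        dfe = measure_DFE(pop, all_viable_L6, 50, rng)
        assert dfe.fraction_neutral == 1.0
        assert dfe.fraction_lethal == 0.0
        assert dfe.mean_s_all == 0.0

    def test_lethal_fraction_matches_one_minus_nu(self, rr_land, rng):
        from holeysim import genotype_robustness
        from holeysim.experiments import random_viable_genotype

        g = random_viable_genotype(rr_land, 30, "binary", rng)
        pop = Population.from_ancestor(g, 100)
        dfe = measure_DFE(pop, rr_land, 100, rng)
        nu = genotype_robustness(g, rr_land)
        # mutations hit the 30 neighbors uniformly; lethal fraction = 1 - nu
        assert dfe.fraction_lethal == pytest.approx(1 - nu, abs=0.02)

    def test_classification_partitions(self, rr_land, rng):
        from holeysim.experiments import random_viable_genotype

        g = random_viable_genotype(rr_land, 30, "binary", rng)
        pop = Population.from_ancestor(g, 50)
        dfe = measure_DFE(pop, rr_land, 40, rng)
        total = dfe.fraction_deleterious + dfe.fraction_neutral + dfe.fraction_beneficial
        assert total == pytest.approx(1.0)
        assert dfe.fraction_lethal <= dfe.fraction_deleterious
        assert dfe.n_mutations == 50 * 40
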