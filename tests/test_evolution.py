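import numpy as np
import pytest

from holeysim import (
    EvolutionParams,
    ExplicitLandscape,
    Genotype,
    Population,
    PopulationExtinct,
    Regime,
    blind_ant_walk,
    diverge_pair,
    evolve_to_equilibrium,
    mutate,
    recombine,
    select_parents,
    wf_generation,
)
from holeysim.evolution import WFStreams, recombine_many
from holeysim.genotypes import iter_all_genotypes
from holeysim.landscapes import robustness_many


class TestBlindAnt:
    def test_always_moves_on_fully_viable_landscape(self, all_viable_L6, rng):
        start = Genotype("000000", "binary")
        state = blind_ant_walk(start, all_viable_L6, 1, rng)
        assert int((state.current.codes != start.codes).sum()) == 1

    def test_absorbing_when_all_neighbors_inviable(self, rng):
        inviable = [g.sequence for g in iter_all_genotypes(4, "binary")
                    if g.sequence.count("1") == 1]
        land = ExplicitLandscape(4, "binary", inviable=inviable)
        start = Genotype("0000", "binary")
        state = blind_ant_walk(start, land, 50, rng, record_trajectory=True)
        assert state.current == start
        assert len(state.trajectory) == 51
        assert all(g == start for g in state.trajectory)

    def test_inviable_start_rejected(self, rng):
        land = ExplicitLandscape(3, "binary", inviable=["000"])
        with pytest.raises(ValueError):
            blind_ant_walk(Genotype("000", "binary"), land, 1, rng)

    def test_visited_robustness_matches_p(self, rr_land, rng):
        # stationary distribution of the walk is uniform over the network,
        # so mean nu of visited genotypes approaches p
        from holeysim.experiments import random_viable_genotype

        start = random_viable_genotype(rr_land, 30, "binary", rng)
        state = blind_ant_walk(start, rr_land, 4000, rng, record_trajectory=True)
        codes = np.array([g.codes for g in state.trajectory[::20]])
        nu = robustness_many(codes, "binary", rr_land).mean()
        assert nu == pytest.approx(0.5, abs=0.04)


class TestSelectParents:
    def test_monomorphic_population(self, all_viable_L6, rng):
        pop = Population.from_ancestor(Genotype("000000", "binary"), 10)
        s1, s2 = select_parents(pop, all_viable_L6, rng)
        assert len(s1) == len(s2) == 10

    def test_fitness_proportional_weights(self, scripted_folder_cls, rng):
        # two genotypes with w = 1.0 and w = 0.5 in equal numbers:
        # expected frequency of the fitter one is 2/3
        from holeysim import RNALandscape

        ref = "(" * 20 + "..." + ")" * 20 + "." * 57
        half = "(" * 16 + "." * 4 + "..." + "." * 4 + ")" * 16 + "." * 57
        land = RNALandscape(
            ref, sigma=0.025, alpha=12,
            folder=scripted_folder_cls({"A" * 100: ref, "C" * 100: half}),
        )
        assert land.fitness_of_sequence("C" * 100) == pytest.approx(0.9)
        # use explicit weights 1.0 / 0.5 via a table instead for exactness
        land2 = ExplicitLandscape(
            2, "binary", fitness_table={"00": 1.0, "11": 0.5, "01": 0.0, "10": 0.0}
        )
        codes = np.array([[0, 0]] * 50 + [[1, 1]] * 50, dtype=np.uint8)
        pop = Population(codes, "binary")
        draws = []
        for _ in range(200):
            s1, _ = select_parents(pop, land2, rng)
            draws.append((s1 < 50).mean())
        assert np.mean(draws) == pytest.approx(2 / 3, abs=0.01)

    def test_zero_fitness_member_never_sampled(self, rng):
        land = ExplicitLandscape(
            2, "binary", fitness_table={"00": 1.0, "01": 0.0, "10": 1.0, "11": 1.0}
        )
        codes = np.array([[0, 0]] * 9 + [[0, 1]], dtype=np.uint8)
        pop = Population(codes, "binary")
        for _ in range(50):
            s1, s2 = select_parents(pop, land, rng)
            assert 9 not in s1 and 9 not in s2

    def test_extinction_raises(self, rng):
        land = ExplicitLandscape(2, "binary", inviable=["00"])
        pop = Population(np.zeros((5, 2), dtype=np.uint8), "binary")
        with pytest.raises(PopulationExtinct) as err:
            select_parents(pop, land, rng)
        assert err.value.generation == 0


class TestRecombine:
    @pytest.mark.parametrize("regime", ["none", "free", 0.5])
    def test_identical_parents_identical_offspring(self, regime, rng):
        g = Genotype("0110", "binary")
        assert recombine(g, g, regime, rng) == g

    def test_free_recombination_crossover_count(self, rng):
        # expected number of crossover events at L = 100 is 0.5 * 99 = 49.5
        L = 100
        p1 = np.zeros((4000, L), dtype=np.uint8)
        p2 = np.ones((4000, L), dtype=np.uint8)
        children = recombine_many(p1, p2, Regime("free"), rng)
        switches = (children[:, 1:] != children[:, :-1]).sum(axis=1)
        assert switches.mean() == pytest.approx(49.5, abs=0.5)

    def test_single_crossover_forms(self, rng):
        # r = 1 with parents 00000/11111: offspring must be 0^i 1^(5-i) or
        # 1^i 0^(5-i) with 1 <= i <= 4, each boundary equally likely
        p1 = Genotype("00000", "binary")
        p2 = Genotype("11111", "binary")
        seen = set()
        for _ in range(600):
            child = recombine(p1, p2, 1.0, rng).sequence
            switches = sum(a != b for a, b in zip(child, child[1:]))
            assert switches == 1
            seen.add(child)
        expected = {"0" * i + "1" * (5 - i) for i in range(1, 5)} | {
            "1" * i + "0" * (5 - i) for i in range(1, 5)
        }
        assert seen == expected

    def test_none_regime_clones_a_parent(self, rng):
        p1 = Genotype("0000", "binary")
        p2 = Genotype("1111", "binary")
        children = {recombine(p1, p2, "none", rng).sequence for _ in range(100)}
        assert children == {"0000", "1111"}

    def test_limited_regime_clone_probability(self, rng):
        p1 = np.zeros((10_000, 10), dtype=np.uint8)
        p2 = np.ones((10_000, 10), dtype=np.uint8)
        children = recombine_many(p1, p2, Regime.parse(0.2), rng)
        is_clone = (children.min(axis=1) == children.max(axis=1))
        assert is_clone.mean() == pytest.approx(0.8, abs=0.015)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            recombine(Genotype("00", "binary"), Genotype("000", "binary"), "free", rng)

    def test_bad_regime_rejected(self):
        with pytest.raises(ValueError):
            Regime.parse("sometimes")
        with pytest.raises(ValueError):
            Regime("limited", 1.5)


class TestMutate:
    def test_zero_rate_is_identity(self, rng):
        g = Genotype("ACGU", "rna")
        assert mutate(g, 0.0, rng) == g

    def test_mean_mutations_matches_U(self, rng):
        # U = mu * L = 0.1 mutations per genome per generation
        from holeysim.evolution import mutate_many

        L, n = 30, 10_000
        codes = np.zeros((n, L), dtype=np.uint8)
        out = mutate_many(codes, 0.1 / L, 2, rng)
        assert (out != codes).sum() / n == pytest.approx(0.1, rel=0.1)

    def test_rna_mutation_targets_uniform(self, rng):
        from holeysim.evolution import mutate_many

        codes = np.zeros((30_000, 1), dtype=np.uint8)  # all 'A'
        out = mutate_many(codes, 1.0, 4, rng)
        counts = np.bincount(out[:, 0], minlength=4)
        assert counts[0] == 0  # a mutated site always changes
        for c in counts[1:]:
            assert c / 30_000 == pytest.approx(1 / 3, abs=0.02)


class TestWFGeneration:
    def test_near_zero_mutation_monomorphic_is_stable(self, all_viable_L6, rng):
        pop = Population.from_ancestor(Genotype("010101", "binary"), 20)
        params = EvolutionParams(N=20, U=1e-12, regime="none")
        out = wf_generation(pop, all_viable_L6, params, rng)
        assert out.generation == 1
        assert np.array_equal(out.codes, pop.codes)

    def test_population_size_conserved(self, all_viable_L6, rng):
        pop = Population.from_ancestor(Genotype("000000", "binary"), 17)
        params = EvolutionParams(N=17, U=0.1, regime="free")
        for _ in range(20):
            pop = wf_generation(pop, all_viable_L6, params, rng)
            assert pop.N == 17

    def test_neutral_drift_matches_wright_fisher_variance(self, rng):
        # on a fully viable landscape allele-frequency change per generation
        # has variance x (1 - x) / N
        land = ExplicitLandscape(2, "binary", inviable=[])
        N = 50
        params = EvolutionParams(N=N, U=1e-12, regime="none")
        deltas = []
        for _ in range(800):
            codes = np.zeros((N, 2), dtype=np.uint8)
            codes[: N // 2, 0] = 1
            pop = Population(codes, "binary")
            out = wf_generation(pop, land, params, rng)
            deltas.append(out.codes[:, 0].mean() - 0.5)
        var = np.var(deltas)
        expected = 0.5 * 0.5 / N
        assert var == pytest.approx(expected, rel=0.2)

    def test_extinction_path_reports_generation(self, rng):
        land = ExplicitLandscape(2, "binary", inviable=["01", "10", "11"])
        pop = Population.from_ancestor(Genotype("00", "binary"), 2)
        params = EvolutionParams(N=2, U=1.8, regime="none")  # mu = 0.9 per site
        with pytest.raises(PopulationExtinct) as err:
            for _ in range(200):
                pop = wf_generation(pop, land, params, rng)
        assert err.value.generation >= 1

    def test_origin_log_records_new_alleles(self, all_viable_L6, rng):
        pop = Population.from_ancestor(
            Genotype("000000", "binary"), 10, track_origins=True
        )
        assert set(pop.origin_log) == {(i, 0) for i in range(6)}
        params = EvolutionParams(N=10, U=2.0, regime="free")
        pop = wf_generation(pop, all_viable_L6, params, rng)
        derived = [k for k in pop.origin_log if k[1] == 1]
        assert derived and all(pop.origin_log[k] == 1 for k in derived)


class TestEquilibration:
    def test_fully_viable_converges_with_constant_nu(self, all_viable_L6):
        params = EvolutionParams(N=20, U=0.1, regime="free", max_generations=3000)
        pop, diag = evolve_to_equilibrium(
            Genotype("000000", "binary"), all_viable_L6, params, seed=3
        )
        assert diag["converged"]
        assert np.all(diag["nu"] == 1.0)
        gens = diag["generations"]
        assert np.all(np.diff(gens) > 0)  # monotone coverage of the run
        assert gens[-1] == diag["stopped_at"]

    def test_inviable_ancestor_rejected(self):
        land = ExplicitLandscape(3, "binary", inviable=["000"])
        with pytest.raises(ValueError):
            evolve_to_equilibrium(
                Genotype("000", "binary"), land, EvolutionParams(N=5, U=0.1)
            )


class TestDivergence:
    def _setup(self, seed=5):
        land = ExplicitLandscape(6, "binary", inviable=[])
        pop = Population.from_ancestor(Genotype("000000", "binary"), 20)
        params = EvolutionParams(N=20, U=0.1, regime="free", max_generations=300)
        return land, pop, params

    def test_target_zero_yields_single_row(self):
        land, pop, params = self._setup()
        record = diverge_pair(pop, land, params, target_D=0.0, seed=1)
        assert len(record.table) == 1
        assert record.table["generation"].iloc[0] == 0

    def test_identical_streams_never_diverge(self):
        land, pop, params = self._setup()
        ss = np.random.SeedSequence(99)
        record = diverge_pair(
            pop, land, params, target_D=0.5, seed=1, pop_seeds=(ss, ss)
        )
        assert (record.table["D"] == 0.0).all()

    def test_bit_identical_reproducibility(self):
        land, pop, params = self._setup()
        rec1 = diverge_pair(pop, land, params, target_D=0.3, seed=17)
        rec2 = diverge_pair(pop, land, params, target_D=0.3, seed=17)
        assert rec1.table.equals(rec2.table)

    def test_snapshots_cover_every_generation(self):
        land, pop, params = self._setup()
        record = diverge_pair(
            pop, land, params, target_D=0.4, snapshots=True, seed=2
        )
        n = record.table["generation"].iloc[-1] + 1
        for pid in (0, 1):
            assert len(record.snapshots[pid]) >= n
            assert record.origin_logs[pid]
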