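import numpy as np
import pytest
from scipy import stats

from sympatry.fixtures import make_fixture
from sympatry.genetics import MutationSchedule
from sympatry.mating import (
    MatingConfig,
    Pair,
    choose_mate,
    fecundity,
    form_pairs,
    next_generation,
    nonrandom_mating_probability,
    phenotype_distance,
    rank_by_biomass,
)
from sympatry.population import Population


def population(biomass, genomes=None):
    biomass = np.asarray(biomass, dtype=float)
    if genomes is None:
        genomes = np.tile([0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5], (len(biomass), 1))
    return Population(genomes=genomes, biomass=biomass)


class TestRanking:
    def test_descending_by_biomass(self):
        pop = population([2.0, 5.0, 3.0])
        assert list(pop.biomass[rank_by_biomass(pop)]) == [5.0, 3.0, 2.0]

    def test_ties_broken_by_id(self):
        pop = population([1.0, 1.0, 1.0])
        assert list(rank_by_biomass(pop)) == [0, 1, 2]

    def test_singleton_and_empty(self):
        assert list(rank_by_biomass(population([7.0]))) == [0]
        assert len(rank_by_biomass(Population(np.empty((0, 8)), np.empty(0)))) == 0


class TestNonrandomProbability:
    def test_study_calibration_72_percent(self):
        # the published gamma = 0.2 yields non-random mating 72% of the time
        # for an m phenotype one tenth away from neutral on either side
        assert nonrandom_mating_probability(0.6, 0.2) == pytest.approx(0.72, abs=0.005)
        assert nonrandom_mating_probability(0.4, 0.2) == pytest.approx(0.72, abs=0.005)

    def test_neutral_and_extreme(self):
        assert nonrandom_mating_probability(0.5, 0.2) == 0.0
        assert nonrandom_mating_probability(1.0, 0.7) == 1.0
        assert nonrandom_mating_probability(0.0, 0.7) == 1.0

    def test_increasing_in_deviation(self):
        ms = np.linspace(0.5, 1.0, 20)
        ps = [nonrandom_mating_probability(m, 0.2) for m in ms]
        assert all(a <= b for a, b in zip(ps, ps[1:]))


class TestPhenotypeDistance:
    def test_identical_is_zero(self):
        p = np.array([0.3, 0.7, 0.2, 0.9])
        assert phenotype_distance(p, p) == 0.0

    def test_euclidean_over_foraging_traits_only(self):
        a = np.array([0.0, 0.0, 0.0, 0.0])
        b = np.array([1.0, 2.0, 2.0, 1.0])  # m differs too but is excluded
        assert phenotype_distance(a, b) == pytest.approx(3.0)

    def test_single_trait_difference(self):
        a = np.array([0.0, 0.5, 0.5, 0.5])
        b = np.array([1.0, 0.5, 0.5, 0.5])
        assert phenotype_distance(a, b) == pytest.approx(1.0)


class TestChooseMate:
    def phen(self):
        # focal row 0; candidates 1 (near) and 2 (far); m set per test
        return np.array(
            [
                [0.5, 0.5, 0.5, 0.1],
                [0.6, 0.6, 0.6, 0.5],
                [1.5, 1.5, 1.5, 0.5],
            ]
        )

    def test_assortative_picks_nearest(self):
        phen = self.phen()
        phen[0, 3] = 0.0  # D = 1: always non-random; m < 0.5 -> argmin
        cfg = MatingConfig(mode="m_trait")
        rng = np.random.default_rng(1)
        picks = {choose_mate(0, np.array([1, 2]), phen, cfg, rng) for _ in range(20)}
        assert picks == {1}

    def test_disassortative_picks_farthest(self):
        phen = self.phen()
        phen[0, 3] = 1.0  # D = 1; m > 0.5 -> argmax
        cfg = MatingConfig(mode="m_trait")
        rng = np.random.default_rng(1)
        picks = {choose_mate(0, np.array([1, 2]), phen, cfg, rng) for _ in range(20)}
        assert picks == {2}

    def test_random_mode_is_uniform_regardless_of_m(self):
        phen = self.phen()
        phen[0, 3] = 0.0  # maximally assortative m, but mode=random ignores it
        cfg = MatingConfig(mode="random")
        rng = np.random.default_rng(8)
        counts = np.zeros(3)
        for _ in range(10_000):
            counts[choose_mate(0, np.array([1, 2]), phen, cfg, rng)] += 1
        chi2, p = stats.chisquare(counts[1:])
        assert p > 0.01

    def test_empty_candidates(self):
        cfg = MatingConfig()
        assert choose_mate(0, np.array([], dtype=int), self.phen(), cfg,
                           np.random.default_rng(0)) is None


class TestFormPairs:
    def test_two_individuals_one_pair(self, rng):
        pairs = form_pairs(population([1.0, 2.0]), MatingConfig(mode="random"), rng)
        assert len(pairs) == 1

    def test_odd_population_leaves_one_unmated(self, rng):
        pairs = form_pairs(population([1, 2, 3, 4, 5.0]), MatingConfig(mode="random"), rng)
        assert len(pairs) == 2
        used = [p.parent_a for p in pairs] + [p.parent_b for p in pairs]
        assert len(used) == len(set(used)) == 4

    def test_matching_property(self, rng):
        pop = population(np.arange(1, 21, dtype=float))
        pairs = form_pairs(pop, MatingConfig(mode="random"), rng)
        used = [p.parent_a for p in pairs] + [p.parent_b for p in pairs]
        assert len(pairs) == 10 and len(set(used)) == 20

    def test_tiny_population_produces_nothing(self, rng):
        assert form_pairs(population([1.0]), MatingConfig(), rng) == []

    def test_assortative_clusters_pair_within(self):
        # two well-separated (alpha, delta, rho) clusters, all m = 0.1:
        # forced non-random choices must stay within-cluster >= 95% of the time
        pop = make_fixture("two-cluster-maters")
        cfg = MatingConfig(mode="m_trait")
        rng = np.random.default_rng(42)
        within = total = 0
        for _ in range(100):
            for pair in form_pairs(pop, cfg, rng):
                total += 1
                same = (pair.parent_a < 10) == (pair.parent_b < 10)
                within += same
        # D^gamma = 0.8^0.2 ~ 0.956: a small fraction of choices are random
        assert within / total >= 0.95


class TestFecundity:
    def test_top_pair_always_maxes_out(self, rng):
        pair = Pair(0, 1, b_pair=5.0, p_pair=0.0)
        cfg = MatingConfig(n_max=4)
        for _ in range(20):
            assert fecundity(pair, 5.0, cfg, rng) == 4

    def test_zero_biomass_pair_is_sterile(self, rng):
        pair = Pair(0, 1, b_pair=0.0, p_pair=0.0)
        assert fecundity(pair, 5.0, MatingConfig(), rng) == 0

    def test_binomial_mean(self, rng):
        cfg = MatingConfig(n_max=4)
        draws = [fecundity(Pair(0, 1, 2.5, 0.0), 5.0, cfg, rng) for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(2.0, abs=0.05)


class TestNextGeneration:
    def schedule(self):
        return MutationSchedule(0.1, 0.001, 100)

    def test_progeny_count_bookkeeping(self, rng):
        pop = population(np.linspace(1, 4, 10))
        cfg = MatingConfig(mode="random")
        progeny, pairs = next_generation(pop, 0, cfg, self.schedule(), rng)
        assert progeny.n == sum(p.n_pair for p in pairs)
        assert np.all(progeny.biomass == cfg.offspring_initial_biomass)

    def test_clonal_homozygous_parents_breed_true_without_mutation(self, rng):
        genomes = np.tile([0.3, 0.3, 0.8, 0.8, 0.2, 0.2, 0.5, 0.5], (6, 1))
        pop = population(np.full(6, 2.0), genomes=genomes)
        tiny = MutationSchedule(1e-15, 1e-15, 100)
        progeny, _ = next_generation(pop, 0, MatingConfig(mode="random"), tiny, rng)
        assert progeny is not None
        assert np.allclose(progeny.genomes, genomes[0], atol=1e-12)

    def test_extinction_signal(self, rng):
        pop = population([1.0])  # cannot form a single pair
        progeny, pairs = next_generation(pop, 0, MatingConfig(), self.schedule(), rng)
        assert progeny is None and pairs == []

    def test_positions_drawn_on_grid(self, rng):
        pop = population(np.full(8, 3.0))
        progeny, _ = next_generation(
            pop, 0, MatingConfig(mode="random"), self.schedule(), rng, grid_shape=(7, 9)
        )
        assert progeny.pos is not None
        assert progeny.pos[:, 0].max() < 7 and progeny.pos[:, 1].max() < 9
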