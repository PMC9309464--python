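"""Founder seeding, survival, pair formation, reproduction, species assignment."""

import numpy as np
import pytest

from evorescue.genetics import FLAVILATERALIS, SILVANUS, TraitSet, make_founder_genome
from evorescue.landscape import LandscapeGrid
from evorescue.population import (
    Bird,
    annual_survival,
    assign_offspring_species,
    default_species,
    form_pair,
    initialize_population,
    repair_pairs,
    reproduce_all,
    reproduce_pair,
    trait_scale,
)
from conftest import make_grid


def make_bird(species, sex, row=0, col=0, bird_id=0):
    params = default_species()[species]
    genome = make_founder_genome(params.founder, species)
    return Bird(bird_id, species, sex, genome, params.founder, row, col)


def founder_pop_on(agc_value, n_patches=200, rng=None, species=None):
    rng = rng or np.random.default_rng(0)
    grid = make_grid(np.full((1, n_patches), float(agc_value)))
    pop = initialize_population(grid, species or default_species(), rng)
    return grid, pop


class TestInitialization:
    def test_specialist_only_patch(self, rng, species_pair):
        """AGC 150 lies in 90-270 but not 3-97: only specialist founders."""
        grid, pop = founder_pop_on(150.0, rng=rng)
        assert np.all(pop.species == SILVANUS)
        occ = np.bincount(pop.patch_index(grid.n_cols), minlength=grid.n_cols)
        assert np.all(occ <= grid.capacity.ravel())
        assert len(pop) > 0

    def test_overlap_patch_hosts_both(self, rng):
        """AGC 95 is inside both bands; totals stay within capacity."""
        grid, pop = founder_pop_on(95.0, rng=rng)
        assert set(np.unique(pop.species)) == {SILVANUS, FLAVILATERALIS}
        occ = np.bincount(pop.patch_index(grid.n_cols), minlength=grid.n_cols)
        assert np.all(occ <= grid.capacity.ravel())

    def test_out_of_band_patch_is_empty(self, rng):
        _, pop = founder_pop_on(300.0, rng=rng)
        assert len(pop) == 0

    def test_bootstrap_pairs_are_conspecific_and_symmetric(self, rng):
        grid, pop = founder_pop_on(95.0, rng=rng)
        paired = np.flatnonzero(pop.partner >= 0)
        assert paired.size > 0
        mates = pop.partner[paired]
        np.testing.assert_array_equal(pop.partner[mates], paired)
        np.testing.assert_array_equal(pop.species[mates], pop.species[paired])
        assert np.all(pop.sex[mates] != pop.sex[paired])


class TestSurvival:
    def test_certain_survival_is_identity(self, rng):
        _, pop = founder_pop_on(150.0, rng=rng)
        n = len(pop)
        assert annual_survival(pop, 1.0, rng) == 0
        assert len(pop) == n

    def test_binomial_envelope(self):
        rng = np.random.default_rng(13)
        grid = make_grid(np.full((50, 50), 150.0))
        pop = initialize_population(grid, default_species(), rng)
        # top up to exactly 10,000 via repeated init? use what we have
        n = len(pop)
        deaths = annual_survival(pop, 0.875, rng)
        sd = np.sqrt(n * 0.875 * 0.125)
        assert abs(deaths - 0.125 * n) <= 3 * sd

    def test_widowing(self):
        rng = np.random.default_rng(1)
        _, pop = founder_pop_on(150.0, n_patches=400, rng=rng)
        paired_before = int((pop.partner >= 0).sum())
        annual_survival(pop, 0.6, rng)
        singles = repair_pairs(pop)  # validates symmetry too
        # some birds must have been widowed at this mortality
        assert paired_before > 0 and singles.size > 0

    def test_invalid_probability(self, rng):
        _, pop = founder_pop_on(150.0, rng=rng)
        with pytest.raises(ValueError):
            annual_survival(pop, 0.0, rng)


class TestFormPair:
    def test_conspecifics_always_pair(self, rng):
        a, b = make_bird(SILVANUS, 0), make_bird(SILVANUS, 1, bird_id=1)
        assert form_pair(a, b, 0.0, rng)
        assert a.partner is b and b.partner is a

    def test_heterospecifics_never_pair_at_zero(self, rng):
        for _ in range(200):
            a, b = make_bird(SILVANUS, 0), make_bird(FLAVILATERALIS, 1, bird_id=1)
            assert not form_pair(a, b, 0.0, rng)

    def test_heterospecific_acceptance_rate(self):
        rng = np.random.default_rng(3)
        wins = 0
        for _ in range(10_000):
            a, b = make_bird(SILVANUS, 0), make_bird(FLAVILATERALIS, 1, bird_id=1)
            wins += form_pair(a, b, 0.5, rng)
        assert abs(wins - 5000) <= 150

    def test_same_sex_rejected(self, rng):
        with pytest.raises(ValueError):
            form_pair(make_bird(SILVANUS, 0), make_bird(SILVANUS, 0, bird_id=1), 1.0, rng)

    def test_already_paired_rejected(self, rng):
        a, b = make_bird(SILVANUS, 0), make_bird(SILVANUS, 1, bird_id=1)
        form_pair(a, b, 0.0, rng)
        c = make_bird(SILVANUS, 0, bird_id=2)
        with pytest.raises(ValueError):
            form_pair(b, c, 0.0, rng)


class TestReproduction:
    def test_point_mass_zero_brood(self, rng):
        m, f = make_bird(SILVANUS, 0), make_bird(SILVANUS, 1, bird_id=1)
        assert reproduce_pair(m, f, (1.0, 0.0, 0.0), rng) == []

    def test_uniform_brood_mean(self):
        """Default Uniform{0,1,2} over 9,000 broods has mean 1 +- 0.03."""
        rng = np.random.default_rng(17)
        m, f = make_bird(SILVANUS, 0), make_bird(SILVANUS, 1, bird_id=1)
        total = sum(len(reproduce_pair(m, f, (1/3, 1/3, 1/3), rng)) for _ in range(9000))
        assert abs(total / 9000 - 1.0) <= 0.03

    def test_pure_lineage_is_closed(self, rng):
        m, f = make_bird(SILVANUS, 0), make_bird(SILVANUS, 1, bird_id=1)
        for _ in range(50):
            for juv in reproduce_pair(m, f, (0.0, 0.0, 1.0), rng):
                assert juv.species == SILVANUS
                assert juv.traits == m.traits
                assert np.all(juv.genome.origins == SILVANUS)

    def test_vectorized_reproduction_brood_distribution(self):
        rng = np.random.default_rng(23)
        _, pop = founder_pop_on(150.0, n_patches=500, rng=rng)
        n_pairs = int((pop.partner >= 0).sum()) // 2
        cohort = reproduce_all(pop, default_species(), rng)
        mean_brood = len(cohort) / n_pairs
        assert abs(mean_brood - 1.0) <= 3 * np.sqrt(2 / 3 / n_pairs)
        # natal location equals the mother's patch value set
        assert set(np.unique(cohort.natal_row)) <= set(np.unique(pop.row))


class TestSpeciesAssignment:
    def scale(self):
        return trait_scale(default_species())

    def test_conspecific_parents(self, rng):
        tag = assign_offspring_species(
            np.array([180, 90, 30, 10.0]), SILVANUS, SILVANUS,
            np.array([180, 90, 30, 10.0]), np.array([180, 90, 30, 10.0]),
            self.scale(), rng,
        )
        assert tag == SILVANUS

    def test_exact_tie_is_random(self):
        """An offspring exactly midway between its parents (the F1 of pure
        founders) draws its label uniformly."""
        rng = np.random.default_rng(29)
        mother = np.array([180, 90, 30, 10.0])
        father = np.array([50, 47, 15, 5.0])
        mid = (mother + father) / 2
        tags = [
            assign_offspring_species(
                mid, SILVANUS, FLAVILATERALIS, mother, father, self.scale(), rng
            )
            for _ in range(400)
        ]
        frac = np.mean(np.array(tags) == SILVANUS)
        assert 0.4 < frac < 0.6

    def test_backcross_goes_to_nearer_parent(self, rng):
        """Backcross offspring keeping the specialist's tolerance/dispersal
        alleles but a heterozygous optimum: scaled distance 0.25 to the pure
        mother vs 0.75 to the F1 father -> specialist tag (hand-computed)."""
        mother = np.array([180, 90, 30, 10.0])      # pure specialist
        father = np.array([115, 68.5, 22.5, 7.5])   # F1 phenotype
        off = np.array([115, 90, 30, 10.0])
        tag = assign_offspring_species(
            off, SILVANUS, FLAVILATERALIS, mother, father, self.scale(), rng
        )
        assert tag == SILVANUS
        off2 = father.copy()  # phenotypically identical to the F1 father
        tag2 = assign_offspring_species(
            off2, SILVANUS, FLAVILATERALIS, mother, father, self.scale(), rng
        )
        assert tag2 == FLAVILATERALIS
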