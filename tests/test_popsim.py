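"""Meiosis simulation and phenotype generation."""

import numpy as np
import pytest

from triqtl import genome, popsim


def two_marker_map(distance_cm):
    return genome.GeneticMap(("a", "b"), np.array([1, 1]), np.array([1.0, 1.0 + distance_cm]))


class TestGenotypeSimulation:
    def test_entries_are_plus_minus_one(self, tiny_fixture):
        pop, _ = tiny_fixture
        assert np.isin(pop.genotypes, (-1, 1)).all()

    def test_haldane_switch_frequency_one_cm(self):
        """Adjacent markers 1 cM apart recombine at r = (1-exp(-0.02))/2."""
        n = 100_000
        rng = np.random.default_rng(42)
        geno = popsim.simulate_dh_genotypes(two_marker_map(1.0), n, rng)
        r_true = float(popsim.haldane_recombination_fraction(1.0))
        p_hat = np.mean(geno[:, 0] != geno[:, 1])
        se = np.sqrt(r_true * (1 - r_true) / n)
        assert r_true == pytest.approx(0.009901, abs=1e-6)
        assert abs(p_hat - r_true) < 3 * se

    def test_pair_correlation_matches_map_function(self):
        """E[x_a x_b] = 1 - 2 r(d) for two markers d apart on one chromosome."""
        n = 100_000
        rng = np.random.default_rng(43)
        for d in (5.0, 25.0, 80.0):
            geno = popsim.simulate_dh_genotypes(two_marker_map(d), n, rng)
            prod = (geno[:, 0] * geno[:, 1]).astype(float)
            expected = 1.0 - 2.0 * float(popsim.haldane_recombination_fraction(d))
            se = prod.std(ddof=1) / np.sqrt(n)
            assert abs(prod.mean() - expected) < 3 * se

    def test_independent_chromosomes(self):
        gmap = genome.GeneticMap(("a", "b"), np.array([1, 2]), np.array([1.0, 1.0]))
        rng = np.random.default_rng(44)
        geno = popsim.simulate_dh_genotypes(gmap, 50_000, rng)
        frac = np.mean(geno[:, 0] != geno[:, 1])
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 50_000)

    def test_allele_frequency_half(self):
        gmap = genome.default_map(n_chromosomes=1, markers_per_chromosome=10, spacing_cm=10.0)
        n = 100_000
        rng = np.random.default_rng(45)
        geno = popsim.simulate_dh_genotypes(gmap, n, rng)
        freq = (geno == 1).mean(axis=0)
        assert np.all(np.abs(freq - 0.5) < 3 * np.sqrt(0.25 / n))

    def test_sign_flip_symmetry_of_odd_moments(self):
        """Sample odd moments are symmetric around zero across seeds."""
        gmap = genome.default_map(n_chromosomes=1, markers_per_chromosome=5, spacing_cm=20.0)
        rng = np.random.default_rng(46)
        geno = popsim.simulate_dh_genotypes(gmap, 200_000, rng)
        triple = (geno[:, 0] * geno[:, 2] * geno[:, 4]).astype(float)
        assert abs(triple.mean()) < 3 * triple.std(ddof=1) / np.sqrt(triple.size)

    def test_reproducible_byte_for_byte(self, toy_map):
        a = popsim.simulate_dh_genotypes(toy_map, 100, np.random.default_rng(7))
        b = popsim.simulate_dh_genotypes(toy_map, 100, np.random.default_rng(7))
        assert a.tobytes() == b.tobytes()

    def test_too_few_lines_rejected(self, toy_map):
        with pytest.raises(ValueError):
            popsim.simulate_dh_genotypes(toy_map, 1, np.random.default_rng(0))


class TestGeneticValues:
    def test_all_plus_one_line_c01(self, default_gmap):
        """mu + 14*2 + 5*2 + 15 = 153 for an all-+1 genotype under C01."""
        arch = genome.build_architecture("C01", True, 5.0, default_gmap)
        geno = np.ones((1, default_gmap.n_markers), dtype=np.int8)
        assert popsim.genetic_values(geno, arch)[0] == pytest.approx(153.0)

    def test_all_effects_zero_gives_intercept(self, default_gmap):
        arch = genome.TraitArchitecture(
            qtl_names=("Q1",),
            qtl_markers=(0,),
            additive_effects=(0.0,),
            epistatic_pairs=(),
            triples=(),
            intercept=100.0,
            error_variance=0.0,
        )
        geno = popsim.simulate_dh_genotypes(default_gmap, 10, np.random.default_rng(1))
        assert np.allclose(popsim.genetic_values(geno, arch), 100.0)

    def test_negation_parity(self, default_gmap, rng):
        """Flipping all genotypes flips odd-degree terms, keeps pair terms."""
        arch = genome.build_architecture("C01", True, 0.0, default_gmap)
        geno = popsim.simulate_dh_genotypes(default_gmap, 50, rng)
        g_plus = popsim.genetic_values(geno, arch)
        g_minus = popsim.genetic_values(-geno, arch)
        pair_part = np.zeros(50)
        x = geno.astype(float)
        for a, b, gamma in arch.epistatic_pairs:
            pair_part += gamma * x[:, a] * x[:, b]
        # g = mu + odd + pair  ->  g(-x) = mu - odd + pair
        assert np.allclose(g_plus + g_minus, 2 * (arch.intercept + pair_part))


class TestPhenotypes:
    def test_noise_free_is_exact(self, rng):
        g = np.array([100.0, 105.0, 95.0])
        plants, means, variances = popsim.simulate_phenotypes(g, 0.0, 10, rng)
        assert np.array_equal(plants, np.repeat(g[:, None], 10, axis=1))
        assert np.array_equal(means, g)
        assert np.array_equal(variances, np.zeros(3))

    def test_line_mean_error_variance(self, rng):
        """The line mean has error variance sigma^2 under the default scaling."""
        g = np.zeros(20_000)
        _, means, variances = popsim.simulate_phenotypes(g, 5.0, 10, rng)
        assert means.var(ddof=1) == pytest.approx(5.0, rel=0.05)
        # plant-level variance is n_plants * sigma^2
        assert variances.mean() == pytest.approx(50.0, rel=0.05)

    def test_plant_level_switch(self, rng):
        g = np.zeros(20_000)
        _, means, _ = popsim.simulate_phenotypes(g, 5.0, 10, rng, error_level="plant")
        assert means.var(ddof=1) == pytest.approx(0.5, rel=0.05)

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValueError):
            popsim.simulate_phenotypes(np.zeros(3), -1.0, 10, rng)
        with pytest.raises(ValueError):
            popsim.simulate_phenotypes(np.zeros(3), 1.0, 1, rng)


class TestDHPopulation:
    def test_invariants_enforced(self, toy_map):
        geno = popsim.simulate_dh_genotypes(toy_map, 5, np.random.default_rng(0))
        with pytest.raises(ValueError, match="-1 or \\+1"):
            popsim.DHPopulation(
                genotypes=np.zeros((5, toy_map.n_markers)),
                line_means=np.zeros(5),
                line_variances=np.ones(5),
            )
        with pytest.raises(ValueError, match="row means"):
            popsim.DHPopulation(
                genotypes=geno,
                line_means=np.zeros(5),
                line_variances=np.ones(5),
                plant_values=np.ones((5, 3)),
            )

    def test_simulated_population_consistency(self, tiny_fixture):
        pop, arch = tiny_fixture
        assert pop.n_lines == 40
        assert pop.n_plants == 10
        assert np.allclose(pop.plant_values.mean(axis=1), pop.line_means)
        assert np.allclose(pop.plant_values.var(axis=1, ddof=1), pop.line_variances)

    def test_population_mean_near_intercept_without_epistasis(self, default_gmap):
        """Without epistatic pairs, odd-moment symmetry centers the trait at mu."""
        arch = genome.build_architecture("C01", False, 5.0, default_gmap)
        means = []
        for rep in range(20):
            pop = popsim.simulate_population(
                default_gmap, arch, 500, 10, np.random.default_rng(100 + rep)
            )
            means.append(pop.line_means.mean())
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - 100.0) < 4 * se
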