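"""Design construction, OLS/WLS fitting and stepwise model selection."""

import itertools

import numpy as np
import pytest

from triqtl import genome, popsim, regest
from triqtl.regest import ModelSpec


def make_population(geno, y, gmap, variances=None):
    return popsim.DHPopulation.from_line_means(geno, y, gmap, line_variances=variances)


class TestModelSpec:
    def test_canonical_order(self):
        spec = ModelSpec(additive=(3, 1, 2), pairs=((3, 1),), triples=((2, 3, 1),))
        assert spec.additive == (1, 2, 3)
        assert spec.pairs == ((1, 3),)
        assert spec.triples == ((1, 2, 3),)

    def test_duplicate_locus_in_term_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(additive=(1, 2), pairs=((1, 1),))

    def test_interaction_outside_additive_rejected(self):
        with pytest.raises(ValueError, match="without additive"):
            ModelSpec(additive=(1, 2), pairs=((1, 3),))

    def test_from_architecture(self, default_gmap):
        arch = genome.build_architecture("C04", True, 5.0, default_gmap)
        spec = ModelSpec.from_architecture(arch)
        assert len(spec.additive) == 14
        assert len(spec.pairs) == 5
        assert len(spec.triples) == 2


class TestBuildDesign:
    def test_triple_column_is_elementwise_product(self):
        geno = np.array([[1, 1, -1], [-1, 1, -1]], dtype=np.int8)
        spec = ModelSpec(additive=(0, 1, 2), triples=((0, 1, 2),))
        G = regest.build_design(geno, spec)
        assert G.shape == (2, 5)  # 1 + 3 additive + 1 triple
        assert np.array_equal(G[:, -1], [-1.0, 1.0])

    def test_column_count(self, tiny_fixture):
        pop, arch = tiny_fixture
        spec = ModelSpec.from_architecture(arch)
        G = regest.build_design(pop.genotypes, spec)
        assert G.shape[1] == 1 + len(spec.additive) + len(spec.pairs) + len(spec.triples)
        assert np.array_equal(G[:, 0], np.ones(pop.n_lines))

    def test_out_of_range_marker_rejected(self):
        geno = np.ones((4, 3), dtype=np.int8)
        with pytest.raises(IndexError):
            regest.build_design(geno, ModelSpec(additive=(5,)))


class TestFitOls:
    def test_two_point_closed_form(self):
        G = np.column_stack([np.ones(2), np.array([-1.0, 1.0])])
        fit = regest.fit_ols(G, np.array([98.0, 102.0]))
        assert fit.mu_hat == pytest.approx(100.0)
        assert fit.beta_hat[0] == pytest.approx(2.0)

    def test_exact_interpolation(self, rng):
        G = np.column_stack([np.ones(30), rng.normal(size=(30, 4))])
        alpha = np.array([1.0, -2.0, 0.5, 3.0, 0.0])
        fit = regest.fit_ols(G, G @ alpha)
        assert np.allclose(np.concatenate([[fit.mu_hat], fit.beta_hat]), alpha, atol=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_duplicate_column_rejected(self):
        x = np.array([-1.0, 1.0, 1.0, -1.0])
        G = np.column_stack([np.ones(4), x, x])
        with pytest.raises(regest.CollinearityError, match="dependent"):
            regest.fit_ols(G, np.array([1.0, 2.0, 3.0, 4.0]))

    def test_residuals_orthogonal_to_design(self, rng):
        G = np.column_stack([np.ones(50), rng.normal(size=(50, 3))])
        fit = regest.fit_ols(G, rng.normal(size=50))
        assert np.allclose(G.T @ fit.residuals, 0.0, atol=1e-8)

    def test_scale_equivariance(self, rng):
        G = np.column_stack([np.ones(40), rng.choice([-1.0, 1.0], size=(40, 3))])
        y = rng.normal(size=40)
        f1 = regest.fit_ols(G, y)
        f2 = regest.fit_ols(G, 3.0 * y)
        assert np.allclose(3.0 * f1.coef, f2.coef)


class TestFitWls:
    def test_constant_weights_equal_ols(self, rng):
        G = np.column_stack([np.ones(40), rng.choice([-1.0, 1.0], size=(40, 3))])
        y = rng.normal(size=40)
        ols = regest.fit_ols(G, y)
        for c in (0.3, 1.0, 7.5):
            wls = regest.fit_wls(G, y, np.full(40, c))
            assert np.allclose(wls.coef, ols.coef, atol=1e-12)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        G = np.column_stack([np.ones(60), rng.choice([-1.0, 1.0], size=(60, 4))])
        y = rng.normal(size=60) + G[:, 1]
        w = rng.uniform(0.5, 3.0, size=60)  # per-observation variances
        ours = regest.fit_wls(G, y, w)
        ref = sm.WLS(y, G, weights=1.0 / w).fit()
        assert np.allclose(ours.coef, ref.params, atol=1e-10)
        assert np.allclose(ours.coef_se, ref.bse, atol=1e-10)
        assert ours.r_squared == pytest.approx(ref.rsquared, abs=1e-10)

    def test_huge_variance_downweights_to_exclusion(self, rng):
        G = np.column_stack([np.ones(21), rng.choice([-1.0, 1.0], size=(21, 2))])
        y = rng.normal(size=21)
        y[0] += 100.0  # gross outlier
        w = np.ones(21)
        w[0] = 1e12
        wls = regest.fit_wls(G, y, w)
        reduced = regest.fit_ols(G[1:], y[1:])
        assert np.allclose(wls.coef, reduced.coef, atol=1e-4)

    def test_nonpositive_weight_rejected(self):
        G = np.column_stack([np.ones(3), np.array([-1.0, 0.5, 1.0])])
        with pytest.raises(ValueError, match="positive"):
            regest.fit_wls(G, np.zeros(3), np.array([1.0, 0.0, 1.0]))

    def test_floor_weights(self):
        w = np.array([0.0, 1.0, 2.0, 4.0])
        floored = regest.floor_weights(w)
        assert floored[0] == pytest.approx(1.5e-6)
        assert np.array_equal(floored[1:], w[1:])


class TestTotalAaaAndR2:
    def test_total_aaa(self, tiny_fixture):
        pop, arch = tiny_fixture
        spec = ModelSpec.from_architecture(arch)
        G = regest.build_design(pop.genotypes, spec)
        fit = regest.fit_ols(G, pop.line_means, spec)
        assert regest.total_aaa(fit) == pytest.approx(np.sum(fit.delta_hat))
        no_triples = ModelSpec(additive=spec.additive, pairs=spec.pairs)
        fit0 = regest.fit_ols(
            regest.build_design(pop.genotypes, no_triples), pop.line_means, no_triples
        )
        assert fit0.delta_hat.size == 0
        assert regest.total_aaa(fit0) == 0.0

    def test_r_squared_bounds_and_recompute(self, rng):
        G = np.column_stack([np.ones(30), rng.normal(size=30)])
        y = G @ np.array([1.0, 2.0])
        fit = regest.fit_ols(G, y)
        assert fit.r_squared == pytest.approx(1.0)
        assert regest.r_squared(fit, y) == pytest.approx(1.0)
        fit_i = regest.fit_ols(np.ones((30, 1)), y)
        assert fit_i.r_squared == pytest.approx(0.0)
        with pytest.raises(ValueError):
            regest.r_squared(fit, np.ones(30))

    def test_nested_monotonicity(self, rng):
        """Adding a column never decreases OLS R^2."""
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        prev = -1.0
        for k in range(1, 7):
            G = np.column_stack([np.ones(40), X[:, :k]])
            r2 = regest.fit_ols(G, y).r_squared
            assert r2 >= prev - 1e-12
            prev = r2


class TestOracleRecovery:
    @pytest.mark.parametrize("code", genome.VARIANT_CODES)
    def test_noise_free_true_spec_recovery(self, code, default_gmap):
        """With sigma^2 = 0 and the true terms, OLS returns the generating
        coefficients to machine precision for every variant layout."""
        arch = genome.build_architecture(code, True, 0.0, default_gmap)
        pop = popsim.simulate_population(
            default_gmap, arch, 500, 10, np.random.default_rng(3)
        )
        spec = ModelSpec.from_architecture(arch)
        G = regest.build_design(pop.genotypes, spec)
        fit = regest.fit_ols(G, pop.line_means, spec)
        assert fit.mu_hat == pytest.approx(100.0, abs=1e-8)
        assert np.allclose(fit.beta_hat, 2.0, atol=1e-8)
        assert np.allclose(fit.gamma_hat, 2.0, atol=1e-8)
        assert regest.total_aaa(fit) == pytest.approx(15.0, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0)


class TestSelection:
    def test_noise_free_single_marker(self, toy_map):
        rng = np.random.default_rng(7)
        geno = popsim.simulate_dh_genotypes(toy_map, 200, rng)
        y = 2.0 * geno[:, 7].astype(float)
        pop = make_population(geno, y, toy_map)
        spec = regest.select_model(y, pop, toy_map)
        assert spec == ModelSpec(additive=(7,))

    def test_type_one_error_controlled(self, toy_map):
        """Pure-noise traits yield an empty model in >= 90% of runs."""
        empty = 0
        runs = 200
        for i in range(runs):
            rng = np.random.default_rng(1000 + i)
            geno = popsim.simulate_dh_genotypes(toy_map, 500, rng)
            y = rng.normal(0.0, 1.0, 500)
            pop = make_population(geno, y, toy_map)
            if regest.select_model(y, pop, toy_map).n_terms == 0:
                empty += 1
        assert empty / runs >= 0.90

    def test_interactions_reference_selected_markers(self, toy_map):
        rng = np.random.default_rng(11)
        geno = popsim.simulate_dh_genotypes(toy_map, 400, rng)
        x = geno.astype(float)
        y = (
            2.0 * x[:, 2]
            + 2.0 * x[:, 10]
            + 2.0 * x[:, 16]
            + 10.0 * x[:, 2] * x[:, 10] * x[:, 16]
            + rng.normal(0, 1, 400)
        )
        pop = make_population(geno, y, toy_map)
        for weighting in ("none", "final_stage", "all_stages"):
            spec = regest.select_model(y, pop, toy_map, weighting=weighting)
            aset = set(spec.additive)
            assert all(set(p) <= aset for p in spec.pairs)
            assert all(set(t) <= aset for t in spec.triples)
            assert (2, 10, 16) in spec.triples

    def test_stepwise_agrees_with_best_subset(self, rng):
        """On a small noise-free instance, stepwise AIC finds the exhaustive
        best-subset AIC optimum (the exact generating pair of markers)."""
        gmap = genome.default_map(n_chromosomes=1, markers_per_chromosome=8, spacing_cm=12.0)
        geno = popsim.simulate_dh_genotypes(gmap, 120, rng)
        x = geno.astype(float)
        y = 2.0 * x[:, 1] - 3.0 * x[:, 5]
        n = y.size

        def aic_of(subset):
            G = np.column_stack([np.ones(n)] + [x[:, j] for j in subset])
            sse = float(np.sum((y - G @ np.linalg.lstsq(G, y, rcond=None)[0]) ** 2))
            return n * np.log(max(sse, 1e-12) / n) + 2 * G.shape[1]

        best = min(
            (
                subset
                for r in range(4)
                for subset in itertools.combinations(range(8), r)
            ),
            key=aic_of,
        )
        pop = make_population(geno, y, gmap)
        spec = regest.select_model(y, pop, gmap)
        assert tuple(spec.additive) == tuple(sorted(best)) == (1, 5)

    def test_empty_selection_is_valid(self, toy_map):
        rng = np.random.default_rng(5)
        geno = popsim.simulate_dh_genotypes(toy_map, 300, rng)
        y = rng.normal(size=300)
        pop = make_population(geno, y, toy_map)
        spec = regest.select_model(y, pop, toy_map)
        assert isinstance(spec, ModelSpec)  # empty or near-empty, but well formed

    def test_weighting_mode_validated(self, tiny_fixture):
        pop, _ = tiny_fixture
        with pytest.raises(ValueError, match="weighting"):
            regest.select_model(pop.line_means, pop, weighting="bogus")
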