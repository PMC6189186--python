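"""Posterior-predictive population extrapolation and its analytic oracles."""

import numpy as np
import pytest

from brainmosaic.lineage_model import (LineageParams,
                                       prob_at_least_one_region)
from brainmosaic.prevalence import (PrevalenceConfig, calibrate_pathogenic_sites,
                                    fixed_region_model, fraction_with_region,
                                    order_of_magnitude_check,
                                    posterior_from_interval,
                                    region_count_interval,
                                    simulate_population)


class TestSimulatePopulation:
    def test_zero_posterior_empty_population(self):
        cfg = PrevalenceConfig(n_individuals=100, pathogenic_sites=148,
                               seed=0)
        pop = simulate_population([0.0], cfg)
        assert pop.counts.sum() == 0
        assert fraction_with_region(pop, 262_144)[0] == 0.0

    def test_zero_pathogenic_sites_allowed(self):
        cfg = PrevalenceConfig(n_individuals=50, pathogenic_sites=0.0,
                               seed=0)
        pop = simulate_population([1e-9], cfg)
        assert pop.counts.sum() == 0

    def test_point_posterior_matches_analytic(self):
        """With a one-point posterior, the fraction of individuals with at
        least one generation-i region equals the Poisson seeding formula
        within 3 Bernoulli standard errors."""
        lam, n_path = 1.3e-9, 148.0
        cfg = PrevalenceConfig(n_individuals=10_000, pathogenic_sites=n_path,
                               seed=4)
        pop = simulate_population([lam], cfg)
        for i in (18, 19, 20, 22):
            size = 2.0 ** (37 - i)
            expected = prob_at_least_one_region(lam, n_path, i)
            frac, se = fraction_with_region(pop, size)
            assert abs(frac - expected) < 3 * max(se, 1e-4)

    def test_point_posterior_mean_count(self):
        # Poisson oracle: mean region count at a size is lambda*N*d(i)
        lam, n_path = 1.3e-9, 148.0
        cfg = PrevalenceConfig(n_individuals=20_000, pathogenic_sites=n_path,
                               seed=5)
        pop = simulate_population([lam], cfg)
        col = pop._column(128)
        expected = lam * n_path * 2.0 ** 30
        se = np.std(col, ddof=1) / np.sqrt(len(col))
        assert abs(np.mean(col) - expected) < 3 * se

    def test_seed_determinism(self):
        cfg = PrevalenceConfig(n_individuals=200, seed=6)
        a = simulate_population([1e-9, 2e-9], cfg)
        b = simulate_population([1e-9, 2e-9], cfg)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_monotone_in_rate_and_sites(self):
        cfg = PrevalenceConfig(n_individuals=5000, pathogenic_sites=148,
                               seed=7)
        lo = fraction_with_region(simulate_population([5e-10], cfg), 262_144)[0]
        hi = fraction_with_region(simulate_population([5e-9], cfg), 262_144)[0]
        assert hi > lo
        cfg_more = PrevalenceConfig(n_individuals=5000,
                                    pathogenic_sites=1480, seed=7)
        more = fraction_with_region(simulate_population([5e-10], cfg_more),
                                    262_144)[0]
        assert more > lo

    def test_multimodality_driven_by_largest_region(self):
        """Among individuals carrying any early-generation event, the
        largest region accounts for at least half the total burden in most
        of them."""
        draws = posterior_from_interval(4.8e-10, 2.99e-9, n=4000, rng=8)
        cfg = PrevalenceConfig(n_individuals=4000, pathogenic_sites=148,
                               seed=9)
        pop = simulate_population(draws, cfg)
        sizes = np.array([pop.region_size(i) for i in pop.generations])
        total = pop.counts @ sizes
        largest = np.max(np.where(pop.counts > 0, sizes[None, :], 0), axis=1)
        # "early" = clones of >= 2^21 cells (generations 1..16), large
        # enough to rival the rest of the typical 1e5-1e6 cell burden
        has_early = pop.counts[:, :16].sum(axis=1) > 0
        carriers = has_early & (total > 0)
        assert carriers.sum() > 30
        frac_dominated = np.mean(largest[carriers] >= 0.5 * total[carriers])
        assert frac_dominated > 0.5

    def test_neurons_only_halves_sizes(self):
        cfg_all = PrevalenceConfig(n_individuals=10, seed=1)
        cfg_neu = PrevalenceConfig(n_individuals=10, neurons_only=True,
                                   seed=1)
        pop_all = simulate_population([1e-9], cfg_all)
        pop_neu = simulate_population([1e-9], cfg_neu)
        assert pop_neu.region_size(19) == 0.5 * pop_all.region_size(19)


class TestRegionCountInterval:
    def test_zero_rate(self):
        cfg = PrevalenceConfig(n_individuals=100, seed=0)
        pop = simulate_population([0.0], cfg)
        assert region_count_interval(pop, 128) == (0.0, 0.0)


class TestCalibration:
    def test_published_interval_solutions(self):
        # arithmetic oracle: 75/(2^30 * 4.8e-10) and 481/(2^30 * 2.99e-9)
        cal = calibrate_pathogenic_sites((4.8e-10, 2.99e-9), (75, 481), 128)
        assert cal["n_path_low"] == pytest.approx(145.5, abs=0.1)
        assert cal["n_path_high"] == pytest.approx(149.8, abs=0.1)
        assert cal["relative_discrepancy"] < 0.05

    def test_linearity(self):
        a = calibrate_pathogenic_sites((1e-9, 2e-9), (100, 200), 128)
        b = calibrate_pathogenic_sites((1e-9, 2e-9), (200, 400), 128)
        assert b["n_path"] == pytest.approx(2 * a["n_path"], rel=1e-9)

    def test_inconsistent_inputs_warn(self):
        with pytest.warns(UserWarning):
            calibrate_pathogenic_sites((1e-9, 1.1e-9), (100, 400), 128)


class TestFixedRegionModel:
    def test_zero_probability(self):
        out = fixed_region_model(128, 1000, 0.0, rng=0)
        assert out["mean_regions"] == 0.0
        assert out["fraction_with_region"] == 0.0

    def test_binomial_moments(self):
        out = fixed_region_model(128, 500, 0.02, n_individuals=40_000, rng=1)
        assert out["mean_regions"] == pytest.approx(out["analytic_mean"],
                                                    rel=0.05)
        assert out["var_regions"] == pytest.approx(out["analytic_var"],
                                                   rel=0.1)

    def test_agrees_with_branching_model_within_factor_two(self):
        """Matching the per-region marginal probability, the fixed-region
        model's prevalence agrees with the branching model's within 2x."""
        lam, n_path, i = 1.2e-9, 148.0, 19
        p_region = prob_at_least_one_region(lam, n_path, i)
        n_regions = 2 ** i
        # per-region marginal so that the expected count matches
        p_per = lam * n_path * 2.0 ** i / n_regions
        out = fixed_region_model(2 ** (37 - i), n_regions, p_per,
                                 n_individuals=30_000, rng=2)
        ratio = out["fraction_with_region"] / p_region
        assert 0.5 <= ratio <= 2.0


class TestOrderOfMagnitude:
    def test_zero_rate(self):
        out = order_of_magnitude_check(0.0, 148)
        assert out["expected_regions"] == 0.0

    def test_published_band_arithmetic(self):
        # generations 21..23 have sizes 1.6e4..6.6e4 inside [1e4, 1e5]
        out = order_of_magnitude_check(1e-9, 148, (1e4, 1e5))
        expected = 148e-9 * (2 ** 21 + 2 ** 22 + 2 ** 23)
        assert out["generations"] == (21, 22, 23)
        assert out["expected_regions"] == pytest.approx(expected, rel=1e-12)
        assert out["expected_regions"] == pytest.approx(2.17, abs=0.05)
        assert out["order_of_magnitude"] == 0  # ~1 region per individual

    def test_band_restricted_to_large_regions(self):
        # only generations with >= 2^20 cells contribute to a [1e6, 1e8] band
        out = order_of_magnitude_check(1e-9, 148, (1e6, 1e8))
        assert all(2 ** (37 - i) >= 2 ** 20 for i in out["generations"])


class TestPosteriorFromInterval:
    def test_quantiles_match_target(self):
        draws = posterior_from_interval(4.8e-10, 2.99e-9, n=200_000, rng=3)
        lo, hi = np.quantile(draws, [0.025, 0.975])
        assert lo == pytest.approx(4.8e-10, rel=0.02)
        assert hi == pytest.approx(2.99e-9, rel=0.02)

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            posterior_from_interval(2e-9, 1e-9)
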