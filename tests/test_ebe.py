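"""MAP/empirical-Bayes estimation of individual random effects."""

import numpy as np
import pytest

from iohexolpk import (DogCovariates, PopulationModel, RandomEffects,
                       SimulationConfig, estimate_ebe, estimate_ebe_batch,
                       individual_from_effects, map_objective, shrinkage,
                       simulate_profiles)
from iohexolpk.ebe import map_objective_many
from iohexolpk.model import InvalidParameterError, concentration


def reference_objective(eta, y, times, pop, cov, dose):
    """Literal transcription of the penalised objective, scalar arithmetic."""
    phi = individual_from_effects(pop, cov, RandomEffects(*eta))
    total = 0.0
    for t, yt in zip(times, y):
        f = concentration(phi, dose, t)
        g2 = (pop.sigma_prop * f) ** 2
        total += (yt - f) ** 2 / g2 + np.log(g2)
    om = [pop.omega_cl, pop.omega_v1, pop.omega_v2]
    total += sum(e ** 2 / w ** 2 for e, w in zip(eta, om))
    return total


def typical_curve(pop, cov, times, dose=64.7):
    phi = individual_from_effects(pop, cov, RandomEffects())
    return concentration(phi, dose, np.asarray(times, float))


class TestMapObjective:
    def test_matches_independent_transcription(self, pop, healthy_dog, rng):
        times = np.array([30.0, 90.0, 180.0])
        for _ in range(20):
            eta = rng.normal(0, 0.3, 3)
            y = typical_curve(pop, healthy_dog, times) * rng.uniform(0.7, 1.3, 3)
            got = map_objective(eta, y, times, pop, healthy_dog, 64.7)
            want = reference_objective(eta, y, times, pop, healthy_dog, 64.7)
            assert got == pytest.approx(want, abs=1e-12 * max(1, abs(want)))

    def test_exact_data_at_zero_eta_leaves_only_log_terms(self, pop, healthy_dog):
        times = np.array([60.0, 120.0])
        f = typical_curve(pop, healthy_dog, times)
        got = map_objective(np.zeros(3), f, times, pop, healthy_dog, 64.7)
        assert got == pytest.approx(np.log((pop.sigma_prop * f) ** 2).sum(),
                                    rel=1e-12)

    def test_flat_prior_limit_is_weighted_least_squares(self, healthy_dog):
        pop = PopulationModel()
        flat = PopulationModel(omega_cl=1e8, omega_v1=1e8, omega_v2=1e8)
        times = np.array([60.0, 120.0, 180.0])
        y = typical_curve(pop, healthy_dog, times) * 1.1
        eta = np.array([0.2, -0.1, 0.3])
        with_prior = map_objective(eta, y, times, flat, healthy_dog, 64.7)
        wls = reference_objective(eta, y, times, pop, healthy_dog, 64.7) \
            - sum(e ** 2 / w ** 2 for e, w in
                  zip(eta, [pop.omega_cl, pop.omega_v1, pop.omega_v2]))
        assert with_prior == pytest.approx(wls, rel=1e-12)

    def test_singular_omega_rejected(self, healthy_dog):
        with pytest.raises(InvalidParameterError):
            PopulationModel(omega_cl=0.0)


class TestEstimateEBE:
    def test_noise_free_limit_recovers_truth_exactly(self, healthy_dog):
        # exact data in the vanishing-residual-error limit pin eta at 0
        pop = PopulationModel(sigma_prop=1e-5)
        times = np.array([30.0, 60.0, 90.0])
        y = typical_curve(pop, healthy_dog, times)
        res = estimate_ebe(y, times, pop, healthy_dog, 64.7)
        assert res.converged
        assert np.abs(res.eta_hat.as_array()).max() < 1e-6
        assert res.gfr_hat == pytest.approx(
            individual_from_effects(pop, healthy_dog, RandomEffects()).cl,
            rel=1e-5)

    def test_log_variance_term_pulls_estimate_at_finite_noise(self, pop,
                                                              healthy_dog):
        # the ln g^2 term is kept inside the objective, so exact data at the
        # study residual error give a small O(b^2) offset, not exactly zero
        times = np.array([30.0, 60.0, 90.0])
        y = typical_curve(pop, healthy_dog, times)
        res = estimate_ebe(y, times, pop, healthy_dog, 64.7)
        shift = np.abs(res.eta_hat.as_array()).max()
        assert 0 < shift < 0.02
        at_zero = map_objective(np.zeros(3), y, times, pop, healthy_dog, 64.7)
        assert res.objective_value < at_zero

    def test_descent_from_zero_start(self, pop, ckd_dog, rng):
        times = np.array([90.0, 180.0])
        for _ in range(10):
            y = typical_curve(pop, ckd_dog, times) * rng.uniform(0.6, 1.5, 2)
            res = estimate_ebe(y, times, pop, ckd_dog, 64.7)
            at_zero = map_objective(np.zeros(3), y, times, pop, ckd_dog, 64.7)
            assert res.objective_value <= at_zero + 1e-9

    def test_observation_order_irrelevant(self, pop, healthy_dog):
        times = np.array([30.0, 90.0, 180.0])
        y = typical_curve(pop, healthy_dog, times) * np.array([1.1, 0.95, 1.02])
        a = estimate_ebe(y, times, pop, healthy_dog, 64.7)
        b = estimate_ebe(y[::-1], times[::-1], pop, healthy_dog, 64.7)
        np.testing.assert_allclose(a.eta_hat.as_array(), b.eta_hat.as_array(),
                                   atol=1e-8)

    def test_beats_dense_grid_on_random_instances(self, pop, healthy_dog, rng):
        # global-minimum check on a coarse grid (fast variant; the full
        # 50-instance fine-grid check lives in the acceptance suite)
        g = np.arange(-1.0, 1.0 + 1e-9, 0.1)
        G = np.stack(np.meshgrid(g, g, g, indexing="ij"), -1).reshape(-1, 3)
        for _ in range(8):
            k = rng.integers(1, 4)
            times = np.sort(rng.choice([30., 60., 90., 120., 150., 180.],
                                       size=k, replace=False))
            eta = rng.normal(0, 0.2, 3)
            phi = individual_from_effects(pop, healthy_dog, RandomEffects(*eta))
            y = concentration(phi, 64.7, times) \
                * (1 + pop.sigma_prop * rng.standard_normal(k))
            res = estimate_ebe(np.atleast_1d(y), np.atleast_1d(times),
                               pop, healthy_dog, 64.7)
            grid_min = map_objective_many(G, np.atleast_1d(y),
                                          np.atleast_1d(times), pop,
                                          healthy_dog, 64.7).min()
            assert res.objective_value <= grid_min + 1e-9

    def test_dense_design_consistency(self, pop, healthy_dog):
        # rich sampling + small noise pins the random effects near truth
        small = PopulationModel(sigma_prop=0.005)
        times = np.geomspace(2.0, 360.0, 20)
        eta = np.array([0.25, -0.15, 0.1])
        phi = individual_from_effects(small, healthy_dog, RandomEffects(*eta))
        rng = np.random.default_rng(4)
        y = concentration(phi, 64.7, times) \
            * (1 + small.sigma_prop * rng.standard_normal(20))
        res = estimate_ebe(y, times, small, healthy_dog, 64.7)
        assert np.abs(res.eta_hat.as_array() - eta).max() < 5 * small.sigma_prop

    def test_noise_monotonicity(self, healthy_dog):
        # smaller residual error -> better eta recovery
        times = np.array([30.0, 90.0, 180.0])
        errs = []
        for b in (0.01, 0.0617, 0.2):
            pop = PopulationModel(sigma_prop=b)
            prof = simulate_profiles(pop, healthy_dog,
                                     SimulationConfig(n_replicates=400,
                                                      times=tuple(times),
                                                      seed=55))
            out = estimate_ebe_batch(prof.concentrations, times, pop,
                                     healthy_dog, 64.7)
            errs.append(np.abs(out["eta"][:, 0] - prof.eta[:, 0]).mean())
        assert errs[0] < errs[1] < errs[2]


class TestShrinkage:
    def test_limits(self, pop, rng):
        zeros = np.zeros((50, 3))
        np.testing.assert_allclose(shrinkage(zeros, pop), 1.0)
        draws = rng.standard_normal((20000, 3)) * pop.omega
        assert np.abs(shrinkage(draws, pop)).max() < 0.05

    def test_sparser_designs_shrink_more(self, pop, healthy_dog):
        prof = simulate_profiles(pop, healthy_dog,
                                 SimulationConfig(n_replicates=300, seed=21))
        cols = {("one"): [3], ("three"): [0, 3, 5]}
        sh = {}
        for name, idx in cols.items():
            out = estimate_ebe_batch(prof.concentrations[:, idx],
                                     prof.times[idx], pop, healthy_dog, 64.7)
            sh[name] = shrinkage(out["eta"], pop)[0]
        assert sh["one"] > sh["three"]

    def test_minimum_sample_size_enforced(self, pop):
        with pytest.raises(ValueError):
            shrinkage(np.zeros((10, 3)), pop)
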