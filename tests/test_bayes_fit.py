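"""Hierarchical model construction, MCMC machinery and DIC."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seedshadow import bayes_fit
from seedshadow.bayes_fit import (
    HYPOTHESES,
    PosteriorDraws,
    build_model,
    dic,
    fit_mcmc,
    gelman_rubin,
)
from seedshadow.kernels import POWER_EXPONENTIAL, T2D, KernelSpec, kernel_pdf
from seedshadow.seed_shadow import StandData, basal_area_m2


def two_trap_stand():
    trees = pd.DataFrame(
        [
            {"tree_id": "t1", "site_id": "s1", "island": "Guam", "x_m": 0.0,
             "y_m": 0.0, "dbh_cm": 20.0},
            {"tree_id": "t2", "site_id": "s1", "island": "Guam", "x_m": 4.0,
             "y_m": 0.0, "dbh_cm": 10.0},
        ]
    )
    traps = pd.DataFrame(
        [
            {"trap_id": "k1", "site_id": "s1", "island": "Guam", "x_m": 0.0,
             "y_m": 3.0, "area_m2": 0.5, "seed_count": 7, "ingested_count": 0,
             "total_classified": 0},
            {"trap_id": "k2", "site_id": "s1", "island": "Guam", "x_m": 10.0,
             "y_m": 0.0, "area_m2": 0.5, "seed_count": 1, "ingested_count": 0,
             "total_classified": 0},
        ]
    )
    return StandData(trees, traps)


class TestBuildModel:
    def test_shared_hypothesis_single_scale(self, world):
        model = build_model(world.stand(), T2D, "shared")
        assert sum(n.startswith("log_a") for n in model.param_names) == 1
        model4 = build_model(world.stand(), T2D, "all_distinct")
        assert sum(n.startswith("log_a") for n in model4.param_names) == 4

    def test_log_posterior_matches_hand_summed_oracle(self):
        """Independent recomputation of the log-posterior on a 2-trap toy
        stand: NB likelihood via scipy.stats.nbinom, plus each prior term
        and the log-scale sampling Jacobians, summed by hand."""
        stand = two_trap_stand()
        model = build_model(stand, T2D, "shared")
        # natural-scale point
        mu_beta, sigma_beta, beta, a, k1, k2 = 6.0, 0.7, 800.0, 2.5, 0.6, 0.15
        theta = np.array(
            [mu_beta, math.log(sigma_beta), math.log(beta), math.log(a),
             math.log(k1), math.log(k2)]
        )
        spec = KernelSpec(T2D, a)
        expected_ll = 0.0
        for _, trap in stand.traps.iterrows():
            mu = 0.0
            for _, tree in stand.trees.iterrows():
                r = math.hypot(tree.x_m - trap.x_m, tree.y_m - trap.y_m)
                mu += (
                    trap.area_m2 * beta * basal_area_m2(tree.dbh_cm)
                    * kernel_pdf(spec, r)
                )
            n = mu / (k1 + k2 * mu)
            expected_ll += stats.nbinom.logpmf(trap.seed_count, n, n / (n + mu))
        expected = (
            expected_ll
            + stats.norm.logpdf(mu_beta, 0, 1e3)
            + stats.norm.logpdf(math.log(a), 0, 1e3)
            + math.log(1 / 10) + math.log(sigma_beta)      # sigma uniform + Jacobian
            + math.log(1 / 100) + math.log(k1)             # k1 uniform + Jacobian
            + math.log(1 / 10) + math.log(k2)              # k2 uniform + Jacobian
            + stats.norm.logpdf(math.log(beta), mu_beta, sigma_beta)
        )
        assert model.log_posterior(theta) == pytest.approx(expected, rel=1e-10)

    def test_out_of_bounds_prior_rejected(self):
        model = build_model(two_trap_stand(), T2D, "shared")
        theta = model.initial_point()
        theta[model._i_sig] = math.log(11.0)  # sigma above its uniform bound
        assert model.log_posterior(theta) == -np.inf

    def test_empty_stand_rejected(self):
        stand = two_trap_stand()
        with pytest.raises(ValueError):
            build_model(StandData(stand.trees, stand.traps.iloc[:0]), T2D, "shared")

    def test_site_label_permutation_invariance(self, world):
        stand = world.stand()
        model = build_model(stand, POWER_EXPONENTIAL, "guam_vs_rest")
        theta = model.initial_point()
        lp = model.log_posterior(theta)
        # permute the row order of trees and traps; site set is unchanged
        trees_p = world.trees.sample(frac=1.0, random_state=1)
        traps_p = world.traps.sample(frac=1.0, random_state=2)
        model_p = build_model(StandData(trees_p, traps_p), POWER_EXPONENTIAL, "guam_vs_rest")
        assert model_p.log_posterior(_permute(theta, model, model_p)) == pytest.approx(
            lp, rel=1e-10
        )


def _permute(theta, model_from, model_to):
    out = np.empty_like(theta)
    for i, name in enumerate(model_to.param_names):
        out[i] = theta[model_from.param_names.index(name)]
    return out


class _StdNormalModel:
    """A known 1D target for sampler sanity checks."""

    ndim = 1
    param_names = ["x"]

    def log_posterior_batch(self, thetas):
        thetas = np.atleast_2d(thetas)
        return -0.5 * np.sum(thetas**2, axis=1)

    def initial_point(self):
        return np.array([0.0])


class TestFitMcmc:
    def test_recovers_standard_normal(self):
        draws = fit_mcmc(_StdNormalModel(), n_chains=3, n_retain=2000,
                         burn_in=300, thin=1, seed=42)
        x = draws.flat()[:, 0]
        se = x.std() / math.sqrt(min(draws.ess["x"], len(x)))
        assert abs(x.mean()) < 3 * max(se, 0.01)
        assert x.std() == pytest.approx(1.0, rel=0.05)

    def test_identical_seeds_identical_draws(self):
        d1 = fit_mcmc(_StdNormalModel(), n_chains=2, n_retain=200, burn_in=50,
                      thin=1, seed=7)
        d2 = fit_mcmc(_StdNormalModel(), n_chains=2, n_retain=200, burn_in=50,
                      thin=1, seed=7)
        assert np.array_equal(d1.samples, d2.samples)
        d3 = fit_mcmc(_StdNormalModel(), n_chains=2, n_retain=200, burn_in=50,
                      thin=1, seed=8)
        assert not np.array_equal(d1.samples, d3.samples)

    def test_posterior_positivity_constraints(self, world):
        model = build_model(world.stand(), POWER_EXPONENTIAL, "shared")
        draws = fit_mcmc(model, n_chains=2, n_retain=150, burn_in=300, thin=1,
                         seed=3)
        nat = draws.natural
        for col in ("sigma_beta", "k1", "k2"):
            assert (nat[col] > 0).all()
        for col in [c for c in nat.columns if c.startswith(("a[", "beta["))]:
            assert (nat[col] > 0).all()

    def test_prior_dominance_without_likelihood(self):
        """With the likelihood switched off the marginal posterior of
        mu_beta must match its diffuse Normal(0, 1e6) prior."""
        stand = two_trap_stand()
        model = build_model(stand, T2D, "shared")
        model.loglik_batch = lambda thetas: np.zeros(np.atleast_2d(thetas).shape[0])
        draws = fit_mcmc(model, n_chains=3, n_retain=3000, burn_in=4000,
                         thin=1, seed=11, init_scale=500.0)
        mu = draws.natural["mu_beta"].to_numpy()
        # the prior sd is 1000; a slowly-mixing diffuse target warrants a
        # generous Monte-Carlo allowance on the mean (0.15 prior sd)
        assert abs(mu.mean()) < 150.0
        assert 0.75e3 < mu.std() < 1.25e3


class TestGelmanRubin:
    def test_hand_worked_two_by_four(self):
        chains = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 7.0]])[..., None]
        m, n = 2, 4
        means = chains[:, :, 0].mean(axis=1)          # 2.5, 4.0
        W = chains[:, :, 0].var(axis=1, ddof=1).mean()
        B_over_n = means.var(ddof=1)
        expected = math.sqrt(((n - 1) / n * W + B_over_n) / W)
        assert gelman_rubin(chains)[0] == pytest.approx(expected, rel=1e-12)

    def test_identical_distribution_near_one(self, rng):
        chains = rng.standard_normal((3, 4000, 2))
        assert np.all(gelman_rubin(chains) < 1.01)

    def test_disjoint_constant_chains_diverge(self):
        chains = np.stack([np.zeros((50, 1)), np.ones((50, 1))])
        assert gelman_rubin(chains)[0] > 10

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100, 2)))


class TestDic:
    def test_point_mass_posterior_zero_pd(self, world):
        model = build_model(world.stand(), T2D, "shared")
        theta = model.initial_point()
        samples = np.tile(theta, (2, 50, 1))
        dev = model.deviance_batch(theta[None, :])[0]
        nat = pd.DataFrame(
            model.to_natural(samples.reshape(-1, model.ndim)),
            columns=model.natural_names(),
        )
        nat["deviance"] = dev
        draws = PosteriorDraws(
            samples=samples, param_names=model.param_names, natural=nat,
            deviance=np.full((2, 50), dev), rhat={}, ess={}, model=model,
        )
        score = dic(draws, model)
        assert score.pd == pytest.approx(0.0, abs=1e-8)
        assert score.dic == pytest.approx(dev, rel=1e-10)

    def test_normal_toy_pd_near_parameter_count(self, rng):
        """Flat-prior Gaussian mean problem: pD should approach the number
        of free parameters (1)."""

        y = rng.standard_normal(40) + 2.0

        class GaussModel:
            ndim = 1
            param_names = ["m"]

            def deviance_batch(self, thetas):
                thetas = np.atleast_2d(thetas)
                return np.array(
                    [np.sum((y - m) ** 2) + len(y) * math.log(2 * math.pi)
                     for m in thetas[:, 0]]
                )

            def natural_names(self):
                return ["m"]

            def to_natural(self, t):
                return t

            def from_natural(self, t):
                return t

        model = GaussModel()
        # exact posterior of the mean under a flat prior
        post = rng.normal(y.mean(), 1 / math.sqrt(len(y)), size=(3, 4000, 1))
        nat = pd.DataFrame(post.reshape(-1, 1), columns=["m"])
        dev = model.deviance_batch(post.reshape(-1, 1)).reshape(3, 4000)
        nat["deviance"] = dev.reshape(-1)
        draws = PosteriorDraws(
            samples=post, param_names=["m"], natural=nat, deviance=dev,
            rhat={}, ess={},
        )
        score = dic(draws, model)
        assert score.pd == pytest.approx(1.0, abs=0.15)
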