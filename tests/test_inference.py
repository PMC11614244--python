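import numpy as np
import pytest
from scipy import stats

from icmsim.inference import (
    GaussianMixtureConditionalEstimator,
    GaussianMixturePosterior,
    LinearGaussianToy,
    build_prior,
    conditional_correlations,
    credible_region_contains,
    make_training_pairs,
    run_inference,
    run_round,
    select_posterior,
)


class TestPrior:
    def test_dimensions_by_variant(self):
        assert build_prior("ITWT").dim == 19
        assert build_prior("RTM").dim == 4
        with pytest.raises(ValueError):
            build_prior("TM-A")

    def test_bounds_and_uniform_marginals(self, rng):
        prior = build_prior("ITWT")
        draws = prior.sample(10_000, rng)
        assert prior.contains(draws).all()
        i = prior.names.index("tau_exchange")
        assert prior.lows[i] == 30.0 and prior.highs[i] == 4200.0
        j = prior.names.index("chi_auto")
        assert prior.lows[j] == 0.0 and prior.highs[j] == 1.0
        for k in (i, j):
            u = (draws[:, k] - prior.lows[k]) / (prior.highs[k] - prior.lows[k])
            assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_rtm_prior_covers_core_motif_only(self):
        prior = build_prior("RTM")
        assert set(prior.names) == {"Nanog_NANOG", "Gata6_GATA6",
                                    "Gata6_NANOG", "Nanog_GATA6"}


class TestGaussianMixtureMachinery:
    def test_conditioning_matches_analytic_gaussian_formulas(self, rng):
        cov = np.array([[2.0, 0.8, 0.3],
                        [0.8, 1.5, -0.4],
                        [0.3, -0.4, 1.0]])
        mu = np.array([1.0, -2.0, 0.5])
        post = GaussianMixturePosterior(np.array([1.0]), mu[None, :],
                                        cov[None, :, :])
        cond = post.condition([2], np.array([1.5]))
        # oracle: standard Gaussian conditioning formulas
        s_ab = cov[:2, 2]
        mean_expect = mu[:2] + s_ab * (1.5 - mu[2]) / cov[2, 2]
        cov_expect = cov[:2, :2] - np.outer(s_ab, s_ab) / cov[2, 2]
        assert np.allclose(cond.means[0], mean_expect)
        assert np.allclose(cond.covs[0], cov_expect)

    def test_moments_and_sampling(self, rng):
        cov = np.array([[1.0, -0.9], [-0.9, 1.0]])
        post = GaussianMixturePosterior(np.array([1.0]),
                                        np.array([[0.0, 0.0]]), cov[None])
        draws = post.sample(20_000, rng)
        assert np.allclose(np.cov(draws.T), cov, atol=0.05)
        assert post.correlation()[0, 1] == pytest.approx(-0.9)

    def test_map_estimate_of_gaussian_is_its_mean(self, rng):
        post = GaussianMixturePosterior(
            np.array([1.0]), np.array([[2.0, -1.0]]),
            np.array([[[0.5, 0.1], [0.1, 0.3]]]),
            bounds=(np.array([-5.0, -5.0]), np.array([5.0, 5.0])))
        theta = post.map_estimate(rng)
        assert np.allclose(theta, [2.0, -1.0], atol=0.05)

    def test_truncated_sampling_respects_bounds(self, rng):
        post = GaussianMixturePosterior(
            np.array([1.0]), np.array([[0.0]]), np.array([[[4.0]]]),
            bounds=(np.array([-1.0]), np.array([1.0])))
        draws = post.sample(500, rng)
        assert (draws >= -1).all() and (draws <= 1).all()

    def test_estimator_recovers_linear_gaussian_posterior(self, rng):
        """Fit on simulated (theta, x) pairs and condition on an observation;
        the result must match the analytic least-squares posterior mean."""
        toy = LinearGaussianToy.make(dim_theta=2, dim_x=6, sigma=0.05, seed=0)
        lo, hi = np.array([-1.0, -1.0]), np.array([1.0, 1.0])
        thetas = rng.uniform(lo, hi, size=(1500, 2))
        xs = np.stack([toy.simulate(t, int(s)) for t, s in
                       zip(thetas, rng.integers(0, 2**31, 1500))])
        est = GaussianMixtureConditionalEstimator(n_components=1, seed=0)
        est.fit(thetas, xs)
        theta_true = np.array([0.3, -0.4])
        x_obs = toy.simulate(theta_true, 999)
        post = est.condition(x_obs, bounds=(lo, hi))
        mean_exact, cov_exact = toy.analytic_posterior(x_obs)
        assert np.allclose(post.mean(), mean_exact, atol=0.1)


class TestConditionalCorrelations:
    def test_known_correlation_recovered(self):
        cov = np.array([[1.0, -0.9, 0.0],
                        [-0.9, 1.0, 0.0],
                        [0.0, 0.0, 1.0]])
        post = GaussianMixturePosterior(np.array([1.0]),
                                        np.zeros((1, 3)), cov[None])
        corr = conditional_correlations(post, np.zeros(3))
        assert corr[0, 1] == pytest.approx(-0.9, abs=0.05)
        assert np.allclose(np.diag(corr), 1.0)
        assert abs(corr[0, 2]) < 0.05
        assert np.allclose(corr, corr.T)


class TestRounds:
    @staticmethod
    def toy_setup():
        toy = LinearGaussianToy.make(dim_theta=2, dim_x=6, sigma=0.05, seed=3)
        prior = build_prior("RTM")
        # restrict to 2 dimensions by wrapping the simulator
        from icmsim.inference import PriorSpec
        prior2 = PriorSpec(("a", "b"), np.array([0.0, 0.0]),
                           np.array([1.0, 1.0]))
        return toy, prior2

    def test_training_pairs_drop_failures(self):
        thetas = np.zeros((3, 2))
        feats = [np.ones(4), None, np.ones(4)]
        t, x = make_training_pairs(thetas, feats)
        assert t.shape == (2, 2) and x.shape == (2, 4)
        with pytest.raises(ValueError):
            make_training_pairs(thetas, [None, None, None])

    def test_single_budget_smoke(self):
        toy, prior = self.toy_setup()
        sim = lambda th, seed: toy.simulate(th, seed)
        cands, t, x = run_round(None, prior, sim, budget=30, round_index=0,
                                seed=5, n_candidates=1,
                                x_target=toy.simulate([0.5, 0.5], 0))
        assert len(cands) == 1
        assert cands[0].posterior.log_prob(cands[0].theta_map[None, :]).shape == (1,)

    def test_candidates_with_distinct_seeds_differ(self):
        toy, prior = self.toy_setup()
        sim = lambda th, seed: toy.simulate(th, seed)
        cands, *_ = run_round(None, prior, sim, budget=200, round_index=0,
                              seed=5, n_candidates=3,
                              x_target=toy.simulate([0.5, 0.5], 0))
        seeds = {c.train_seed for c in cands}
        assert len(seeds) == 3

    def test_select_posterior_orders_by_meta_score(self):
        toy, prior = self.toy_setup()
        theta_good = np.array([0.5, 0.5])
        post = GaussianMixturePosterior(np.array([1.0]), theta_good[None],
                                        0.01 * np.eye(2)[None])
        good = type("C", (), {})()
        from icmsim.inference import PosteriorCandidate
        cand_a = PosteriorCandidate(None, post, theta_good, 0, 1)
        cand_b = PosteriorCandidate(None, post, np.array([0.0, 0.0]), 0, 2)

        def sim(theta, seed):
            # score-like feature: 1 near theta_good, lower away from it
            return np.full(5, np.exp(-np.linalg.norm(theta - theta_good)))

        best = select_posterior([cand_a, cand_b], sim, n_validation=4, seed=0)
        assert best is cand_a
        assert best.meta == pytest.approx(1.0)
        with pytest.raises(ValueError):
            select_posterior([], sim, 1, 0)

    def test_multi_round_recovery_on_identifiable_toy(self):
        """Over three rounds the posterior concentrates around the
        generating parameters of the linear-Gaussian toy."""
        toy, prior = self.toy_setup()
        theta_true = np.array([0.62, 0.31])
        x_obs = toy.simulate(theta_true, 12345)
        sim = lambda th, seed: toy.simulate(th, seed)
        out = run_inference(prior, sim, rounds=3, budget=400, n_candidates=2,
                            n_validation=5, seed=7, x_target=x_obs)
        assert np.linalg.norm(out["theta_map"] - theta_true) < 0.1
        rng = np.random.default_rng(0)
        assert credible_region_contains(out["posterior"], theta_true, 0.95,
                                        rng)


def test_tissue_feature_simulator_yields_score_window(map_params):
    """The composite (signaling on/off) tissue simulator reduces one
    parameter vector to the 48-point joint-score feature in [0, 1]."""
    from icmsim.inference import tissue_feature_simulator

    sim = tissue_feature_simulator(map_params, "ITWT", n_cells=4, t_end_h=13.0)
    x = sim(np.array(map_params.free_vector()), seed=5)
    assert x is not None
    assert x.shape == (48,)
    assert ((x >= 0) & (x <= 1)).all()


def test_credible_region_membership_is_calibrated(rng):
    post = GaussianMixturePosterior(np.array([1.0]), np.zeros((1, 2)),
                                    np.eye(2)[None])
    inside = credible_region_contains(post, np.array([0.1, 0.1]), 0.9, rng)
    outside = credible_region_contains(post, np.array([3.5, 3.5]), 0.9, rng)
    assert inside and not outside
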