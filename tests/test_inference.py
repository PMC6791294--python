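"""MCMC sampling, stepping-stone marginal likelihoods, model comparison,
and ancestral-state summaries."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from syndive.inference import (PosteriorSet, _mh_chain, ancestral_states,
                               bayes_factor, comparison_table,
                               marginal_likelihood, mcmc_sample, prefer,
                               stepping_stone)
from syndive.sse_core import make_model
from syndive.treeio import CharacterData, SamplingFractions


class TestBayesFactorBasics:
    def test_definition_and_zero(self):
        assert bayes_factor(-380.395, -384.786) == pytest.approx(8.782, abs=1e-9)
        assert bayes_factor(-7.0, -7.0) == 0.0

    def test_prefer_threshold(self):
        assert prefer(8.782) == "focal"
        assert prefer(1.097) == "neither"
        assert prefer(-4.464) == "competing"
        assert prefer(1.16) == "neither"       # strictly greater required

    def test_comparison_table_antisymmetric_zero_diagonal(self):
        rng = np.random.default_rng(0)
        lnls = {f"M{i}": float(v) for i, v in enumerate(rng.normal(-300, 5, 6))}
        table = comparison_table(lnls)
        bf = table.bf
        np.testing.assert_allclose(bf + bf.T, 0.0, atol=1e-12)
        np.testing.assert_allclose(np.diag(bf), 0.0)


class TestSteppingStone:
    def test_zero_free_parameters_exact(self):
        assert stepping_stone(lambda th: -3.25, None, None, 0) == -3.25

    def _poisson_gamma(self, data, a0=2.0, b0=1.0):
        data = np.asarray(data)

        def ll(th):
            lam = th[0]
            if lam <= 0:
                return -np.inf
            return float(np.sum(data * np.log(lam) - lam - gammaln(data + 1)))

        def lp(th):
            lam = th[0]
            if lam <= 0:
                return -np.inf
            return float(a0 * np.log(b0) - gammaln(a0)
                         + (a0 - 1) * np.log(lam) - b0 * lam)

        an, bn = a0 + data.sum(), b0 + data.size
        true_lnz = float(a0 * np.log(b0) - gammaln(a0) + gammaln(an)
                         - an * np.log(bn) - np.sum(gammaln(data + 1)))
        return ll, lp, true_lnz

    def test_conjugate_toy_matches_closed_form(self):
        ll, lp, true_lnz = self._poisson_gamma([3, 5, 2, 4, 6])
        est = stepping_stone(ll, lp, lambda r: np.array([r.gamma(2.0, 1.0)]),
                             1, n_stones=30, iters_per_stone=2000, seed=3)
        assert est == pytest.approx(true_lnz, abs=0.05)

    def test_converges_when_doubling_stones(self):
        ll, lp, _ = self._poisson_gamma([3, 5, 2, 4, 6])
        prior = lambda r: np.array([r.gamma(2.0, 1.0)])
        a = stepping_stone(ll, lp, prior, 1, n_stones=15,
                           iters_per_stone=1500, seed=11)
        b = stepping_stone(ll, lp, prior, 1, n_stones=30,
                           iters_per_stone=1500, seed=12)
        assert abs(a - b) < 0.1


class TestMCMC:
    def test_prior_recovery_with_likelihood_off(self, three_tip):
        cd = CharacterData({"a": 0, "b": 1, "c": 0})
        spec = make_model("B1")
        post = mcmc_sample(three_tip, cd, spec, n_iter=30000, seed=2,
                           likelihood_off=True)
        ess = post.ess()
        # exponential prior means: 10 for lambda/mu, 1 for q
        want = np.array([10.0, 10, 10, 10, 1, 1])
        sd = np.array([10.0, 10, 10, 10, 1, 1])
        for j, name in enumerate(spec.param_names):
            se = sd[j] / np.sqrt(max(ess[name], 1.0))
            assert abs(post.draws[:, j].mean() - want[j]) < 3 * se + 0.05 * want[j]

    def test_same_seed_bit_identical(self, three_tip):
        cd = CharacterData({"a": 0, "b": 1, "c": 0})
        spec = make_model("B2")
        a = mcmc_sample(three_tip, cd, spec, n_iter=500, seed=7)
        b = mcmc_sample(three_tip, cd, spec, n_iter=500, seed=7)
        np.testing.assert_array_equal(a.draws, b.draws)
        np.testing.assert_array_equal(a.loglik, b.loglik)

    def test_detailed_balance_against_grid_posterior(self):
        # 2-parameter toy: independent Poisson-Gamma targets with exact
        # Gamma(a0+S, b0+n) posteriors; chain medians must match the exact
        # quantiles within Monte-Carlo error
        dataA = np.array([4, 6, 5])
        dataB = np.array([1, 0, 2])
        a0, b0 = 2.0, 1.0

        def ll(th):
            if np.any(th <= 0):
                return -np.inf
            return float(np.sum(dataA * np.log(th[0]) - th[0])
                         + np.sum(dataB * np.log(th[1]) - th[1]))

        def lp(th):
            if np.any(th <= 0):
                return -np.inf
            return float(np.sum((a0 - 1) * np.log(th) - b0 * th))

        rng = np.random.default_rng(5)
        samples, _, _, _, _ = _mh_chain(ll, lp, np.array([1.0, 1.0]), 40000,
                                        rng, adapt_until=5000)
        samples = samples[5000:]
        for j, data in enumerate((dataA, dataB)):
            post = stats.gamma(a0 + data.sum(), scale=1 / (b0 + data.size))
            x = samples[:, j]
            n_eff = max(50.0, _ess(x))
            # MC standard error of the sample median
            se_med = 1.2533 * x.std() / np.sqrt(n_eff)
            assert abs(np.median(x) - post.median()) < 3 * se_med
            assert abs(x.mean() - post.mean()) < 3 * x.std() / np.sqrt(n_eff)

    def test_recovers_unequal_diversification(self, crownlike):
        spec = make_model("B1")
        post = mcmc_sample(crownlike.tree, crownlike.states, spec,
                           SamplingFractions(1.0, 1.0), n_iter=8000, seed=13)
        r = np.array([p.r for p in post.parameter_draws()])
        assert np.mean(r[:, 0] > r[:, 1]) > 0.9


def _ess(x):
    from syndive.inference import _ess_1d
    return _ess_1d(x)


class TestMarginalLikelihoodSSE:
    def test_nested_models_rank_sensibly(self, crownlike):
        # data generated with r0 > r1: B1 should beat B4 clearly
        f = SamplingFractions(1.0, 1.0)
        kw = dict(n_stones=12, iters_per_stone=600, adapt_iters=200)
        lnl_b1 = marginal_likelihood(crownlike.tree, crownlike.states,
                                     make_model("B1"), f, seed=1, **kw)
        lnl_b4 = marginal_likelihood(crownlike.tree, crownlike.states,
                                     make_model("B4"), f, seed=2, **kw)
        assert bayes_factor(lnl_b1, lnl_b4) > 1.16


class TestAncestralStates:
    def test_all_state0_gives_no_origins(self, four_tip_balanced):
        cd = CharacterData({lb: 0 for lb in four_tip_balanced.tip_labels})
        spec = make_model("B1")
        theta = np.array([1.0, 1.0, 0.1, 0.1, 0.01, 0.01])
        post = PosteriorSet(spec, theta[None, :], np.zeros(1), np.zeros(1),
                            seed=0, burn_in=0, thin=1)
        anc = ancestral_states(four_tip_balanced, cd, spec,
                               SamplingFractions(1, 1), post)
        assert anc.origins == 0
        assert np.all(anc.summary_state == 0)

    def test_two_tip_symmetric_root_is_tied(self, two_tip):
        cd = CharacterData({"a": 0, "b": 1})
        spec = make_model("B1")
        theta = np.array([1.0, 1.0, 0.2, 0.2, 0.5, 0.5])
        post = PosteriorSet(spec, theta[None, :], np.zeros(1), np.zeros(1),
                            seed=0, burn_in=0, thin=1)
        anc = ancestral_states(two_tip, cd, spec, SamplingFractions(1, 1), post)
        assert anc.obs_prob[two_tip.root, 1] == pytest.approx(0.5, abs=1e-9)
        assert two_tip.root in anc.ties

    def test_node_probabilities_sum_to_one(self, crownlike):
        spec = make_model("B1")
        theta = np.array(list(crownlike.params.lam) + list(crownlike.params.mu)
                         + [crownlike.params.q[0, 1], crownlike.params.q[1, 0]])
        post = PosteriorSet(spec, theta[None, :], np.zeros(1), np.zeros(1),
                            seed=0, burn_in=0, thin=1)
        anc = ancestral_states(crownlike.tree, crownlike.states, spec,
                               SamplingFractions(1, 1), post)
        np.testing.assert_allclose(anc.node_prob.sum(axis=1), 1.0, atol=1e-6)

    def test_recovers_origin_count_on_tippy_data(self, crownlike):
        from syndive.phylometrics import origins_parsimony
        spec = make_model("B1")
        post = mcmc_sample(crownlike.tree, crownlike.states, spec,
                           SamplingFractions(1.0, 1.0), n_iter=6000, seed=21)
        anc = ancestral_states(crownlike.tree, crownlike.states, spec,
                               SamplingFractions(1.0, 1.0), post, max_draws=40)
        truth = origins_parsimony(crownlike.tree, crownlike.states)
        assert abs(anc.origins - truth) <= 2
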