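"""SSE model structures and likelihood correctness."""

import numpy as np
import pytest

from syndive.sse_core import (SSEParameters, make_model, net_diversification,
                              sse_loglik)
from syndive.treeio import CharacterData, SamplingFractions

from conftest import oracle_loglik, random_states, random_ultrametric

F_FULL = SamplingFractions(1.0, 1.0)


class TestMakeModel:
    @pytest.mark.parametrize("name,n_free,n_states", [
        ("B1", 6, 2), ("B2", 5, 2), ("B3", 5, 2), ("B4", 4, 2),
        ("H1", 12, 4), ("CID2", 8, 4), ("CID4", 22, 8),
    ])
    def test_free_parameter_counts(self, name, n_free, n_states):
        spec = make_model(name)
        assert spec.n_free == n_free
        assert spec.n_states == n_states

    def test_unknown_name(self):
        with pytest.raises(ValueError):
            make_model("B9")

    def test_b3_fixes_q10_to_zero(self):
        spec = make_model("B3")
        p = spec.build_params(np.array([1.0, 2.0, 0.1, 0.2, 0.4]))
        assert p.q[1, 0] == 0.0
        assert p.q[0, 1] == 0.4

    def test_b4_ties_diversification(self):
        spec = make_model("B4")
        p = spec.build_params(np.array([2.0, 0.5, 0.1, 0.3]))
        assert p.lam[0] == p.lam[1] == 2.0
        assert p.mu[0] == p.mu[1] == 0.5

    def test_b2_ties_transitions(self):
        p = make_model("B2").build_params(np.array([1, 2, 0.1, 0.2, 0.7]))
        assert p.q[0, 1] == p.q[1, 0] == 0.7

    def test_cid4_transition_structure(self):
        spec = make_model("CID4")
        n_q = sum(1 for k in spec.param_kinds if k == "q")
        assert n_q == 14
        theta = np.arange(1.0, 23.0)
        p = spec.build_params(theta)
        # no simultaneous observed+hidden change: 0A -> 1B entry must be zero
        i0A, i1B = spec.state_names.index("0A"), spec.state_names.index("1B")
        assert p.q[i0A, i1B] == 0.0
        # hidden chain: A<->B allowed, A<->C not
        i0C = spec.state_names.index("0C")
        assert p.q[i0A, i0C] == 0.0

    def test_cid_models_tie_within_hidden_class(self):
        spec = make_model("CID2")
        p = spec.build_params(np.array([3.0, 1.0, 0.5, 0.2, .1, .1, .1, .1]))
        names = list(spec.state_names)
        assert p.lam[names.index("0A")] == p.lam[names.index("1A")] == 3.0
        assert p.lam[names.index("0B")] == p.lam[names.index("1B")] == 1.0


class TestNetDiversification:
    def test_examples(self):
        p = SSEParameters(np.array([6.0, 3.0]), np.array([1.0, 1.0]),
                          np.zeros((2, 2)), ("0", "1"))
        np.testing.assert_allclose(net_diversification(p), [5.0, 2.0])
        p0 = SSEParameters(np.ones(2), np.ones(2), np.zeros((2, 2)), ("0", "1"))
        np.testing.assert_allclose(net_diversification(p0), [0.0, 0.0])

    def test_four_state(self):
        spec = make_model("H1")
        p = spec.build_params(np.array([4, 3, 2, 1, 1, 1, 1, 1, .1, .1, .1, .1],
                                       dtype=float))
        assert net_diversification(p).shape == (4,)


class TestLoglik:
    def test_pure_birth_closed_form(self, two_tip):
        cd = CharacterData({"a": 0, "b": 0})
        lnl = sse_loglik(two_tip, cd, make_model("B1"),
                         np.array([1.0, 1.0, 0, 0, 0, 0]), F_FULL,
                         condition_on_survival=False)
        assert lnl == pytest.approx(-2.0, abs=1e-8)

    def test_yule_closed_form_random_trees(self):
        # q=0, mu=0, f=1, one state: lnL = (n-1) ln(lam) - lam * total_length
        rng = np.random.default_rng(5)
        spec = make_model("B1")
        for n in (5, 9, 20):
            t = random_ultrametric(n, rng)
            cd = CharacterData({lb: 0 for lb in t.tip_labels})
            lam = float(rng.uniform(0.5, 2.0))
            lnl = sse_loglik(t, cd, spec, np.array([lam, lam, 0, 0, 0, 0]),
                             F_FULL, condition_on_survival=False)
            expected = (n - 1) * np.log(lam) - lam * t.total_length()
            assert lnl == pytest.approx(expected, abs=1e-7)

    def test_label_flip_symmetry(self, three_tip):
        spec = make_model("B1")
        th = np.array([1.2, 1.2, 0.3, 0.3, 0.4, 0.4])
        cd = CharacterData({"a": 0, "b": 1, "c": 0})
        cd_flip = CharacterData({"a": 1, "b": 0, "c": 1})
        f = SamplingFractions(0.8, 0.8)
        assert sse_loglik(three_tip, cd, spec, th, f) == pytest.approx(
            sse_loglik(three_tip, cd_flip, spec, th, f), abs=1e-10)

    def test_matches_fixed_step_oracle(self):
        rng = np.random.default_rng(11)
        spec = make_model("B1")
        f = SamplingFractions(0.83, 0.79)
        for _ in range(8):
            n = int(rng.integers(4, 11))
            t = random_ultrametric(n, rng)
            cd = random_states(t, rng)
            lam = rng.uniform(0.5, 3.0, 2)
            mu = rng.uniform(0.0, 1.0, 2)
            q01, q10 = rng.uniform(0.05, 1.0, 2)
            th = np.array([lam[0], lam[1], mu[0], mu[1], q01, q10])
            got = sse_loglik(t, cd, spec, th, f)
            want = oracle_loglik(t, cd, lam, mu,
                                 np.array([[0, q01], [q10, 0]]),
                                 f0=0.83, f1=0.79, h_step=1e-5)
            assert got == pytest.approx(want, abs=1e-6)

    def test_hisse_collapses_to_bisse(self):
        rng = np.random.default_rng(23)
        t = random_ultrametric(8, rng)
        cd = random_states(t, rng)
        f = SamplingFractions()
        b1 = np.array([1.5, 0.8, 0.3, 0.1, 0.4, 0.15])
        h1 = np.array([1.5, 0.8, 1.5, 0.8, 0.3, 0.1, 0.3, 0.1,
                       0.4, 0.15, 0.0, 0.0])
        lnl_b = sse_loglik(t, cd, make_model("B1"), b1, f)
        lnl_h = sse_loglik(t, cd, make_model("H1"), h1, f)
        assert lnl_h == pytest.approx(lnl_b, abs=1e-8)

    def test_cid2_invariant_under_state_permutation(self):
        # with q01 = q10 the observed trait is diversification-neutral in CID2
        rng = np.random.default_rng(3)
        t = random_ultrametric(8, rng)
        cd = random_states(t, rng)
        flipped = CharacterData({k: 1 - v for k, v in cd.states.items()})
        spec = make_model("CID2")
        th = np.array([2.0, 0.8, 0.4, 0.2, 0.3, 0.3, 0.1, 0.05])
        f = SamplingFractions(0.8, 0.8)
        assert sse_loglik(t, cd, spec, th, f) == pytest.approx(
            sse_loglik(t, flipped, spec, th, f), abs=1e-9)

    def test_negative_rates_rejected(self, two_tip):
        cd = CharacterData({"a": 0, "b": 0})
        with pytest.raises(ValueError):
            sse_loglik(two_tip, cd, make_model("B1"),
                       np.array([1.0, 1.0, -0.1, 0, 0, 0]))

    def test_non_ultrametric_rejected(self):
        from syndive.treeio import read_newick
        t = read_newick("((a:1,b:1):1,c:1.5):0;")
        cd = CharacterData({"a": 0, "b": 0, "c": 1})
        with pytest.raises(ValueError, match="ultrametric"):
            sse_loglik(t, cd, make_model("B1"), np.ones(6))
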