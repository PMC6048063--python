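import numpy as np
import pytest

from mycostate import (
    Chronogram,
    RateModel,
    RootPrior,
    SimulationSpec,
    TipData,
    TransitionKernel,
    build_Q,
    log_likelihood,
    simulate_tree,
    transition_probabilities,
)

from conftest import random_model, state, uniform_data
from _helpers import brute_force_likelihood, random_tip_data


class TestBuildQ:
    def test_two_state_definition(self, space2):
        nm_m = (space2.index(state("NM")), space2.index(state("M")))
        m_nm = nm_m[::-1]
        m = RateModel(space2, {nm_m: 0.1, m_nm: 0.2})
        assert np.allclose(build_Q(m), [[-0.1, 0.1], [0.2, -0.2]])

    def test_all_rates_zero_gives_zero_matrix(self, space4):
        assert np.all(build_Q(RateModel.uniform(space4, 0.0)) == 0)

    def test_hamming_two_entries_are_structurally_zero(self, space4):
        Q = build_Q(RateModel.uniform(space4, 0.7))
        i, j = space4.index(state("NM")), space4.index(state("G+M"))
        assert Q[i, j] == 0.0 and Q[j, i] == 0.0

    def test_rows_sum_to_zero(self, space5):
        Q = build_Q(random_model(space5, np.random.default_rng(0)))
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_negative_rate_rejected(self, space2):
        rates = {mv: -0.1 for mv in space2.moves}
        with pytest.raises(ValueError, match=">= 0"):
            RateModel(space2, rates)

    def test_structural_zero_must_have_zero_rate(self, space2):
        mv = next(iter(space2.moves))
        with pytest.raises(ValueError, match="structural"):
            RateModel(space2, {m: 0.1 for m in space2.moves},
                      structural_zeros=frozenset([mv]))

    def test_json_round_trip(self, space4):
        m = random_model(space4, np.random.default_rng(3))
        back = RateModel.from_json(m.to_json())
        assert back.space == m.space
        for mv in m.space.moves:
            assert back.rates[mv] == pytest.approx(m.rates[mv])


class TestTransitionProbabilities:
    def test_identity_at_zero(self, space4):
        Q = build_Q(random_model(space4, np.random.default_rng(1)))
        assert np.allclose(transition_probabilities(Q, 0.0), np.eye(4), atol=1e-12)

    def test_rows_stochastic(self, space5):
        Q = build_Q(random_model(space5, np.random.default_rng(2)))
        P = transition_probabilities(Q, 3.7)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert P.min() >= 0 and P.max() <= 1

    def test_two_state_symmetric_closed_form(self, space2):
        q = 0.13
        Q = build_Q(RateModel.uniform(space2, q))
        for t in (0.0, 0.5, 2.0, 10.0):
            P = transition_probabilities(Q, t)
            assert P[0, 0] == pytest.approx(0.5 * (1 + np.exp(-2 * q * t)), abs=1e-10)

    def test_long_time_reaches_stationary(self, space4):
        Q = build_Q(random_model(space4, np.random.default_rng(4), scale=0.5))
        P = transition_probabilities(Q, 1e4)
        # left null vector of Q as the independent stationary oracle
        w, v = np.linalg.eig(Q.T)
        pi = np.real(v[:, np.argmin(np.abs(w))])
        pi = pi / pi.sum()
        assert np.allclose(P, np.tile(pi, (4, 1)), atol=1e-6)

    def test_chapman_kolmogorov(self, space5):
        rng = np.random.default_rng(5)
        for _ in range(10):
            Q = build_Q(random_model(space5, rng))
            K = TransitionKernel(Q)
            t1, t2 = rng.uniform(0.1, 3.0, size=2)
            assert np.allclose(K.at(t1) @ K.at(t2), K.at(t1 + t2), atol=1e-8)

    def test_negative_time_rejected(self, space2):
        with pytest.raises(ValueError):
            transition_probabilities(build_Q(RateModel.uniform(space2, 0.1)), -1.0)

    def test_kernel_matches_expm(self, space5):
        rng = np.random.default_rng(6)
        Q = build_Q(random_model(space5, rng))
        K = TransitionKernel(Q)
        for t in (0.3, 1.7, 12.0):
            assert np.allclose(K.at(t), transition_probabilities(Q, t), atol=1e-10)


class TestLogLikelihood:
    def test_all_uncertain_likelihood_is_one(self, tree5, space4):
        m = random_model(space4, np.random.default_rng(7))
        assert log_likelihood(tree5, uniform_data(tree5, space4), m) == pytest.approx(0.0)

    def test_two_tip_closed_form(self, space4):
        tree = Chronogram.from_newick("(A:1.3,B:1.3);")
        a, b = state("M"), state("G")
        data = TipData({"A": a, "B": b}, space4)
        m = random_model(space4, np.random.default_rng(8))
        P = TransitionKernel(build_Q(m)).at(1.3)
        ia, ib = space4.index(a), space4.index(b)
        expected = np.log(np.sum(0.25 * P[:, ia] * P[:, ib]))
        assert log_likelihood(tree, data, m) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_enumeration(self, tree5, space4):
        rng = np.random.default_rng(9)
        data = random_tip_data(tree5, space4, rng)
        m = random_model(space4, rng)
        K = TransitionKernel(build_Q(m))
        P = K.at_many(tree5.branch_length)
        pi = np.full(4, 0.25)
        expected = np.log(brute_force_likelihood(tree5, data, P, pi))
        assert log_likelihood(tree5, data, m) == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_child_order(self, space4):
        rng = np.random.default_rng(10)
        m = random_model(space4, rng)
        t1 = Chronogram.from_newick("((A:1,B:1):1,C:2);")
        t2 = Chronogram.from_newick("(C:2,(B:1,A:1):1);")
        assignments = {"A": state("M"), "B": state("G+M"), "C": state("NM")}
        d1 = TipData(assignments, space4)
        assert log_likelihood(t1, d1, m) == pytest.approx(log_likelihood(t2, d1, m),
                                                          abs=1e-12)

    def test_impossible_data_under_constraints_is_minus_inf(self, space2):
        """Root fixed non-mycorrhizal with the gain structurally zeroed:
        any M-bearing tip is unreachable, so the likelihood is 0."""
        tree = Chronogram.from_newick("(A:1,B:1);")
        gain = (space2.index(state("NM")), space2.index(state("M")))
        m = RateModel.uniform(space2, 0.1).with_structural_zero(gain)
        data = TipData({"A": state("M"), "B": state("NM")}, space2)
        ll = log_likelihood(tree, data, m, RootPrior.fixed(state("NM")))
        assert ll == -np.inf

    def test_fast_evaluator_matches_reference(self, space4):
        from mycostate import TreeLikelihood
        rng = np.random.default_rng(11)
        tree = simulate_tree(SimulationSpec(n_tips=30, seed=11))
        data = random_tip_data(tree, space4, rng)
        m = random_model(space4, rng, scale=0.02)
        tl = TreeLikelihood(tree, data)
        assert tl.log_likelihood(m) == pytest.approx(log_likelihood(tree, data, m),
                                                     abs=1e-9)

    def test_mismatched_space_errors(self, tree5, space2, space4):
        data = uniform_data(tree5, space2)
        with pytest.raises(ValueError, match="state space"):
            log_likelihood(tree5, data, RateModel.uniform(space4, 0.1))


class TestRootPrior:
    def test_vectors(self, space4):
        assert np.allclose(RootPrior().vector(space4), 0.25)
        pi = RootPrior.fixed(state("NM")).vector(space4)
        assert pi[space4.index(state("NM"))] == 1.0 and pi.sum() == 1.0

    def test_stationary_is_left_null_vector(self, space4):
        Q = build_Q(random_model(space4, np.random.default_rng(12)))
        pi = RootPrior("stationary").vector(space4, Q)
        assert np.allclose(pi @ Q, 0.0, atol=1e-9) and pi.sum() == pytest.approx(1.0)
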