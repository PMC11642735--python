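import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

import karyorate as kr
from karyorate.ctmc import ChromLikelihood, LinkedChromLikelihood

from conftest import (enumeration_loglik, enumeration_marginals,
                      random_tree_and_states)


class TestStateSpace:
    def test_contiguous_range(self):
        sp = kr.build_state_space([38, 40, 41], pad=0)
        assert list(sp.states) == [38, 39, 40, 41]

    def test_floor_at_one(self):
        sp = kr.build_state_space([2], pad=5)
        assert (sp.n_min, sp.n_max) == (1, 7)

    def test_padding(self):
        sp = kr.build_state_space([10, 12], pad=2)
        assert (sp.n_min, sp.n_max) == (8, 14)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            kr.build_state_space([], pad=2)


class TestRateMatrix:
    def test_forced_entries(self):
        sp = kr.ChromStateSpace(2, 4)
        Q = kr.build_rate_matrix(kr.ChromParams(0.1, 0.2), sp)
        expected = np.array([[-0.1, 0.1, 0.0],
                             [0.2, -0.3, 0.1],
                             [0.0, 0.2, -0.2]])
        np.testing.assert_allclose(Q.matrix, expected, atol=1e-15)

    def test_zero_rates_give_zero_matrix(self):
        sp = kr.ChromStateSpace(2, 6)
        Q = kr.build_rate_matrix(kr.ChromParams(0.0, 0.0), sp)
        assert np.all(Q.matrix == 0)

    @given(lf=st.floats(0, 5), lu=st.floats(0, 5),
           n=st.integers(2, 40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_row_sums_vanish(self, lf, lu, n):
        sp = kr.ChromStateSpace(1, n)
        Q = kr.build_rate_matrix(kr.ChromParams(lf, lu), sp)
        np.testing.assert_allclose(Q.matrix.sum(axis=1), 0, atol=1e-12)

    def test_linked_block_structure(self):
        sp = kr.ChromStateSpace(5, 6)
        p = kr.LinkedChromParams(0, 0, 0, 0, 0.3, 0)
        Q = kr.build_linked_rate_matrix(p, sp)
        expected = np.zeros((4, 4))
        expected[0, 2] = expected[1, 3] = 0.3
        expected[0, 0] = expected[1, 1] = -0.3
        np.testing.assert_allclose(Q.matrix, expected, atol=1e-15)

    def test_linked_zero_matrix(self):
        sp = kr.ChromStateSpace(3, 7)
        Q = kr.build_linked_rate_matrix(
            kr.LinkedChromParams(0, 0, 0, 0, 0, 0), sp)
        assert Q.matrix.shape == (10, 10)
        assert np.all(Q.matrix == 0)

    def test_state_labeling_convention(self):
        sp = kr.ChromStateSpace(5, 7)
        Q = kr.build_linked_rate_matrix(
            kr.LinkedChromParams(1, 1, 1, 1, 1, 1), sp)
        assert Q.state_index(6, 0) == 1
        assert Q.state_index(5, 1) == 3
        assert Q.state_label(4) == (6, 1)


class TestTransitionProbabilities:
    def test_identity_at_zero_time(self):
        sp = kr.ChromStateSpace(1, 5)
        Q = kr.build_rate_matrix(kr.ChromParams(0.4, 0.7), sp)
        np.testing.assert_allclose(kr.transition_probabilities(Q, 0.0),
                                   np.eye(5), atol=1e-14)

    def test_two_state_closed_form(self):
        # symmetric 2-state chain: P(stay) = (1 + e^{-2t}) / 2
        Q = np.array([[-1.0, 1.0], [1.0, -1.0]])
        t = np.log(2)
        P = kr.transition_probabilities(Q, t)
        stay = (1 + np.exp(-2 * t)) / 2
        np.testing.assert_allclose(P, [[stay, 1 - stay], [1 - stay, stay]],
                                   atol=1e-12)

    def test_negative_time_rejected(self):
        Q = kr.build_rate_matrix(kr.ChromParams(1, 1),
                                 kr.ChromStateSpace(1, 3))
        with pytest.raises(ValueError):
            kr.transition_probabilities(Q, -0.1)

    def test_series_oracle_and_row_stochasticity(self):
        # agreement with a truncated Taylor series on random generators
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(2, 7)
            lf, lu = rng.uniform(0, 2, size=2)
            sp = kr.ChromStateSpace(1, int(n))
            Q = kr.build_rate_matrix(kr.ChromParams(lf, lu), sp)
            t = rng.uniform(0, 2)
            P = kr.transition_probabilities(Q, t)
            series = np.eye(int(n))
            term = np.eye(int(n))
            for k in range(1, 60):
                term = term @ (Q.matrix * t) / k
                series = series + term
            np.testing.assert_allclose(P, series, atol=1e-9)
            np.testing.assert_allclose(P.sum(axis=1), 1, atol=1e-10)

    def test_row_stochastic_long_times_high_rates(self):
        sp = kr.ChromStateSpace(1, 40)
        Q = kr.build_rate_matrix(kr.ChromParams(5.0, 5.0), sp)
        P = kr.transition_probabilities(Q, 200.0)
        np.testing.assert_allclose(P.sum(axis=1), 1, atol=1e-10)
        assert P.min() >= 0


class TestPruningLikelihood:
    def test_matches_enumeration_small_tree(self, three_tip_tree):
        sp = kr.ChromStateSpace(3, 6)
        Q = kr.build_rate_matrix(kr.ChromParams(0.3, 0.4), sp)
        tips = {"A": 3, "B": 5, "C": 4}
        for mode in ("weighted", "flat", ("fixed", 4)):
            got = kr.pruning_likelihood(three_tip_tree, tips, Q, mode)
            want = enumeration_loglik(three_tip_tree, tips, Q, mode)
            assert got.log_likelihood == pytest.approx(want, abs=1e-10)

    def test_no_change_limit(self, three_tip_tree):
        sp = kr.ChromStateSpace(4, 6)
        Q = kr.build_rate_matrix(kr.ChromParams(0.0, 0.0), sp)
        tips = {"A": 5, "B": 5, "C": 5}
        res = kr.pruning_likelihood(three_tip_tree, tips, Q, ("fixed", 5))
        assert res.log_likelihood == pytest.approx(0.0, abs=1e-12)

    def test_tip_order_invariance(self, balanced_four_tip_tree):
        sp = kr.ChromStateSpace(1, 6)
        Q = kr.build_rate_matrix(kr.ChromParams(0.5, 0.2), sp)
        tips = {"A": 2, "B": 3, "C": 5, "D": 4}
        rev = dict(reversed(list(tips.items())))
        a = kr.pruning_likelihood(balanced_four_tip_tree, tips, Q)
        b = kr.pruning_likelihood(balanced_four_tip_tree, rev, Q)
        assert a.log_likelihood == pytest.approx(b.log_likelihood, abs=1e-12)

    def test_polytomy_handled(self):
        tree = kr.read_newick("(A:1,B:1,C:1,D:2);")
        sp = kr.ChromStateSpace(1, 4)
        Q = kr.build_rate_matrix(kr.ChromParams(0.3, 0.3), sp)
        tips = {"A": 1, "B": 2, "C": 3, "D": 4}
        got = kr.pruning_likelihood(tree, tips, Q)
        want = enumeration_loglik(tree, tips, Q)
        assert got.log_likelihood == pytest.approx(want, abs=1e-10)

    def test_unknown_tip_state_names_species(self, three_tip_tree):
        sp = kr.ChromStateSpace(3, 5)
        Q = kr.build_rate_matrix(kr.ChromParams(0.1, 0.1), sp)
        with pytest.raises(ValueError, match="B"):
            kr.pruning_likelihood(three_tip_tree, {"A": 3, "B": 9, "C": 4}, Q)

    def test_proper_root_distribution_bounds_likelihood(self, three_tip_tree):
        sp = kr.ChromStateSpace(1, 5)
        Q = kr.build_rate_matrix(kr.ChromParams(0.7, 0.9), sp)
        tips = {"A": 1, "B": 3, "C": 5}
        for mode in ("weighted", "flat"):
            assert kr.pruning_likelihood(three_tip_tree, tips, Q,
                                         mode).log_likelihood <= 0

    def test_random_sweep_against_enumeration(self):
        """Pruning equals exhaustive enumeration on random small trees."""
        rng = np.random.default_rng(7)
        for _ in range(30):
            tree, space, states = random_tree_and_states(rng)
            lf, lu = rng.uniform(0.05, 2, size=2)
            Q = kr.build_rate_matrix(kr.ChromParams(lf, lu), space)
            got = kr.pruning_likelihood(tree, states, Q)
            want = enumeration_loglik(tree, states, Q)
            assert got.log_likelihood == pytest.approx(want, abs=1e-8)

    def test_linked_marginalization_matches_simple(self):
        """A trait-symmetric linked model with trait-ambiguous tips gives
        the simple model's likelihood."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            tree = kr.simulate_tree(6, 1.0, 0.0,
                                    seed=int(rng.integers(2 ** 31)))
            sp = kr.ChromStateSpace(3, 8)
            lf, lu = rng.uniform(0.05, 1.0, size=2)
            q01, q10 = rng.uniform(0.05, 1.0, size=2)
            tips = {lf_.taxon.label: int(rng.integers(3, 9))
                    for lf_ in tree.leaf_node_iter()}
            Qs = kr.build_rate_matrix(kr.ChromParams(lf, lu), sp)
            Ql = kr.build_linked_rate_matrix(
                kr.LinkedChromParams(lf, lu, lf, lu, q01, q10), sp)
            amb = {k: (v, None) for k, v in tips.items()}
            for mode in ("flat", "weighted"):
                simple = kr.pruning_likelihood(tree, tips, Qs, mode)
                linked = kr.pruning_likelihood(tree, amb, Ql, mode)
                # the trait dimension marginalizes out exactly: ambiguous
                # tip indicators sum to one over trait states and count
                # rates are trait-symmetric
                assert linked.log_likelihood == pytest.approx(
                    simple.log_likelihood, abs=1e-8)


class TestMarginalAncestralStates:
    def test_point_mass_limit(self, three_tip_tree):
        sp = kr.ChromStateSpace(4, 6)
        Q = kr.build_rate_matrix(kr.ChromParams(0.0, 0.0), sp)
        tips = {"A": 5, "B": 5, "C": 5}
        marg = kr.marginal_ancestral_states(three_tip_tree, tips, Q, "flat")
        for dist in marg.values():
            assert dist[sp.index(5)] == pytest.approx(1.0, abs=1e-12)

    def test_matches_enumeration(self, three_tip_tree):
        sp = kr.ChromStateSpace(2, 5)
        Q = kr.build_rate_matrix(kr.ChromParams(0.4, 0.6), sp)
        tips = {"A": 2, "B": 4, "C": 5}
        for mode in ("weighted", "flat"):
            got = kr.marginal_ancestral_states(three_tip_tree, tips, Q, mode)
            want = enumeration_marginals(three_tip_tree, tips, Q, mode)
            for node, dist in want.items():
                np.testing.assert_allclose(got[node], dist, atol=1e-8)

    def test_distributions_sum_to_one(self, balanced_four_tip_tree):
        sp = kr.ChromStateSpace(1, 7)
        Q = kr.build_rate_matrix(kr.ChromParams(0.9, 0.3), sp)
        tips = {"A": 2, "B": 3, "C": 6, "D": 7}
        marg = kr.marginal_ancestral_states(balanced_four_tip_tree, tips, Q)
        for dist in marg.values():
            assert dist.sum() == pytest.approx(1.0, abs=1e-9)

    def test_time_rescaling_symmetry(self, three_tip_tree):
        """Scaling branch lengths by c and rates by 1/c changes nothing."""
        c = 3.7
        sp = kr.ChromStateSpace(2, 6)
        tips = {"A": 2, "B": 4, "C": 6}
        Q1 = kr.build_rate_matrix(kr.ChromParams(0.4, 0.6), sp)
        Q2 = kr.build_rate_matrix(kr.ChromParams(0.4 / c, 0.6 / c), sp)
        scaled = three_tip_tree.clone(depth=1)
        for e in scaled.preorder_edge_iter():
            if e.length is not None:
                e.length = e.length * c
        m1 = kr.marginal_ancestral_states(three_tip_tree, tips, Q1)
        m2 = kr.marginal_ancestral_states(scaled, tips, Q2)
        np.testing.assert_allclose(m1[three_tip_tree.seed_node],
                                   m2[scaled.seed_node], atol=1e-10)


class TestLikelihoodClosures:
    def test_closure_matches_direct_call(self, balanced_four_tip_tree):
        tips = {"A": 4, "B": 5, "C": 6, "D": 5}
        model = ChromLikelihood(balanced_four_tip_tree, tips, pad=2)
        Q = model.rate_matrix([0.3, 0.5])
        direct = kr.pruning_likelihood(balanced_four_tip_tree, tips, Q)
        assert model([0.3, 0.5]) == pytest.approx(direct.log_likelihood,
                                                  abs=1e-9)

    def test_pad_insensitivity(self):
        """Enlarging the pad barely moves the log-likelihood when counts
        stay well inside the bounds."""
        tree = kr.simulate_tree(40, 0.5, 0.0, seed=5)
        counts = kr.simulate_chromosomes(tree, kr.ChromParams(0.05, 0.05),
                                         20, seed=6)
        lls = []
        for pad in (5, 10):
            model = ChromLikelihood(tree, counts, pad=pad)
            lls.append(model([0.05, 0.05]))
        assert abs(lls[0] - lls[1]) < 1e-4

    def test_linked_closure_matches_direct(self):
        tree = kr.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        tips = {"A": (4, 0), "B": (5, 1), "C": (6, None), "D": (5, 0)}
        model = LinkedChromLikelihood(tree, tips, pad=2)
        params = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        Q = model.rate_matrix(params)
        direct = kr.pruning_likelihood(tree, tips, Q)
        assert model(params) == pytest.approx(direct.log_likelihood,
                                              abs=1e-9)
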