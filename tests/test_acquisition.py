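import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grnactive.acquisition import (UndirectedMask, bald, direction_entropy,
                                   ebald, eces, edge_entropy,
                                   four_state_entropy, knockout_scores,
                                   node_uncertainty, sample_undirected_mask,
                                   select_interventions)
from grnactive.posterior import (EdgeStateDistribution, PdagStateDistribution,
                                 edge_state_distribution, ensemble_marginals,
                                 member_weights, pdag_state_distribution)
from oracles import random_dag


def dist3(p_fwd, p_rev, p_none):
    """2-node 3-state distribution with the given pair probabilities."""
    pf = np.array([[0.0, p_fwd], [p_rev, 0.0]])
    pn = np.array([[0.0, p_none], [p_none, 0.0]])
    return EdgeStateDistribution(pf, pn)


def dist4(p_fwd, p_rev, p_undir, p_none):
    pf = np.array([[0.0, p_fwd], [p_rev, 0.0]])
    pu = np.array([[0.0, p_undir], [p_undir, 0.0]])
    pn = np.array([[0.0, p_none], [p_none, 0.0]])
    return PdagStateDistribution(pf, pu, pn)


def full_mask(n, value):
    u = np.full((n, n), value, dtype=np.uint8)
    np.fill_diagonal(u, 0)
    return UndirectedMask(u)


class TestEdgeEntropy:
    @pytest.mark.parametrize("p, expected", [
        ((1.0, 0.0, 0.0), 0.0),            # degenerate: no uncertainty
        ((1 / 3, 1 / 3, 1 / 3), 1.0),      # uniform: normalised maximum
        ((0.5, 0.25, 0.25), 0.946395),     # 1.5 bits / log2(3)
    ])
    def test_values(self, p, expected):
        h = edge_entropy(dist3(*p))
        assert h[0, 1] == pytest.approx(expected, abs=1e-5)
        assert h[1, 0] == h[0, 1]
        assert np.all(np.diag(h) == 0)


class TestDirectionEntropy:
    @pytest.mark.parametrize("pf, pr, expected", [
        (0.2, 0.2, 1.0),        # symmetric orientation: maximal
        (0.3, 0.1, 0.811278),   # binary entropy of 3/4
        (0.0, 0.0, 0.0),        # no oriented mass: defined as 0
    ])
    def test_conditional_values(self, pf, pr, expected):
        d = dist4(pf, pr, 0.1, 1 - pf - pr - 0.1)
        h = direction_entropy(d)
        assert h[0, 1] == pytest.approx(expected, abs=1e-5)

    def test_unconditional_variant_uses_raw_marginals(self):
        d = dist4(0.5, 0.5, 0.0, 0.0)
        assert direction_entropy(d, conditional=False)[0, 1] == \
            pytest.approx(1.0)
        d2 = dist4(0.25, 0.25, 0.25, 0.25)
        # raw two-term entropy of (0.25, 0.25) = 1 bit, not the conditional 1
        assert direction_entropy(d2, conditional=False)[0, 1] == \
            pytest.approx(1.0)
        assert direction_entropy(d2, conditional=True)[0, 1] == \
            pytest.approx(1.0)


class TestFourStateEntropy:
    @pytest.mark.parametrize("p, expected", [
        ((0.25, 0.25, 0.25, 0.25), 1.0),
        ((1.0, 0.0, 0.0, 0.0), 0.0),
        ((0.3, 0.3, 0.0, 0.4), 0.785475),   # 1.570950 bits / 2
    ])
    def test_values(self, p, expected):
        h = four_state_entropy(dist4(*p))
        assert h[0, 1] == pytest.approx(expected, abs=1e-5)


class TestBald:
    def test_identical_members_score_zero(self):
        m = dist3(0.4, 0.3, 0.3)
        assert np.allclose(bald([m, m, m]), 0.0)

    def test_fully_disagreeing_members(self):
        score = bald([dist3(1, 0, 0), dist3(0, 1, 0)])
        # mean is (0.5, 0.5, 0): 1 bit / log2(3); member entropies are 0
        assert score[0, 1] == pytest.approx(0.630930, abs=1e-5)

    def test_single_member_is_zero(self):
        assert np.allclose(bald([dist3(0.4, 0.3, 0.3)]), 0.0)

    def test_empty_member_list_rejected(self):
        with pytest.raises(ValueError):
            bald([])

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_bounded_by_pooled_entropy_on_random_ensembles(self, seed):
        rng = np.random.default_rng(seed)
        gs = [random_dag(5, 0.4, rng) for _ in range(24)]
        from conftest import sample_set_from
        s = sample_set_from(gs)
        members = ensemble_marginals(s, 4)
        w = member_weights(s, 4)
        score = bald(members, w)
        pooled = edge_entropy(edge_state_distribution(s))
        assert np.all(score >= 0)
        assert np.all(score <= pooled + 1e-9)


class TestUndirectedMask:
    def test_degenerate_probabilities(self):
        all_zero = sample_undirected_mask(dist4(0.5, 0.2, 0.0, 0.3), seed=0)
        assert not all_zero.u.any()
        all_one = sample_undirected_mask(dist4(0.0, 0.0, 1.0, 0.0), seed=0)
        off = ~np.eye(2, dtype=bool)
        assert np.all(all_one.u[off] == 1)

    def test_bernoulli_rate(self):
        d = dist4(0.2, 0.2, 0.5, 0.1)
        draws = [sample_undirected_mask(d, seed=s).u[0, 1]
                 for s in range(4000)]
        assert np.mean(draws) == pytest.approx(0.5, abs=0.02)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        gs = [random_dag(6, 0.4, rng) for _ in range(10)]
        from conftest import sample_set_from
        d = pdag_state_distribution(sample_set_from(gs))
        a = sample_undirected_mask(d, seed=11)
        b = sample_undirected_mask(d, seed=11)
        assert np.array_equal(a.u, b.u)

    def test_symmetry_enforced(self):
        with pytest.raises(ValueError):
            UndirectedMask(np.array([[0, 1], [0, 0]], dtype=np.uint8))


class TestEces:
    def test_zero_mask_reduces_to_four_state_entropy(self):
        d = dist4(0.3, 0.3, 0.0, 0.4)
        score = eces(d, full_mask(2, 0))
        assert np.allclose(score, four_state_entropy(d))
        assert score[0, 1] == pytest.approx(0.785475, abs=1e-5)

    def test_one_mask_reduces_to_direction_entropy(self):
        d = dist4(0.3, 0.3, 0.2, 0.2)
        score = eces(d, full_mask(2, 1))
        assert np.allclose(score, direction_entropy(d))
        assert score[0, 1] == pytest.approx(1.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            eces(dist4(0.3, 0.3, 0.2, 0.2), full_mask(3, 0))


class TestEbald:
    def test_identical_members_zero(self):
        m = dist4(0.3, 0.2, 0.3, 0.2)
        assert np.allclose(ebald([m, m], full_mask(2, 1)), 0.0)
        assert np.allclose(ebald([m, m], full_mask(2, 0)), 0.0)

    def test_direction_branch_maximal_disagreement(self):
        a = dist4(0.5, 0.0, 0.25, 0.25)   # direction conditional (1, 0)
        b = dist4(0.0, 0.5, 0.25, 0.25)   # direction conditional (0, 1)
        score = ebald([a, b], full_mask(2, 1))
        assert score[0, 1] == pytest.approx(1.0)

    def test_zero_mask_equals_four_state_bald(self):
        rng = np.random.default_rng(2)
        gs = [random_dag(5, 0.4, rng) for _ in range(20)]
        from conftest import sample_set_from
        s = sample_set_from(gs)
        members = ensemble_marginals(s, 4, kind="pdag")
        w = member_weights(s, 4)
        score = ebald(members, full_mask(5, 0), w)
        pooled_minus_mean = np.clip(
            four_state_entropy(_mean4(members, w))
            - sum(wk * four_state_entropy(m) for wk, m in zip(w, members)),
            0.0, None)
        assert np.allclose(score, pooled_minus_mean)


def _mean4(members, w):
    pf = sum(wk * m.p_fwd for wk, m in zip(w, members))
    pu = sum(wk * m.p_undir for wk, m in zip(w, members))
    pn = sum(wk * m.p_none for wk, m in zip(w, members))
    return PdagStateDistribution(pf, pu, pn)


class TestNodeAndKnockoutScores:
    def test_node_uncertainty_is_column_sums(self):
        rng = np.random.default_rng(0)
        s = rng.random((6, 6))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 0)
        expected = [sum(s[i][j] for i in range(6)) for j in range(6)]
        assert np.allclose(node_uncertainty(s), expected)

    def test_single_uncertain_pair(self):
        s = np.zeros((4, 4))
        s[1, 2] = s[2, 1] = 0.7
        u = node_uncertainty(s)
        assert u[1] == u[2] == 0.7 and u[0] == u[3] == 0.0

    def test_certain_posterior_scores_zero(self):
        pair = np.zeros((3, 3))
        pf = np.array([[0, 1, 0], [0, 0, 1], [0, 0, 0]], dtype=float)
        d = EdgeStateDistribution(pf, 1.0 - pf - pf.T - np.eye(3))
        assert np.allclose(knockout_scores(pair, d), 0.0)

    def test_confident_parent_of_uncertain_child_wins(self):
        # gene 0 is a certain parent of gene 1; pair (1, 2) is uncertain
        pair = np.zeros((3, 3))
        pair[1, 2] = pair[2, 1] = 0.9
        pf = np.zeros((3, 3))
        pf[0, 1] = 1.0
        pn = 1.0 - pf - pf.T
        np.fill_diagonal(pn, 0)
        d = EdgeStateDistribution(pf, pn)
        scores = knockout_scores(pair, d)
        assert np.argmax(scores) == 0
        assert scores[0] == pytest.approx(0.9)

    def test_saturated_pair_scores_give_zero(self):
        pair = np.ones((3, 3))
        np.fill_diagonal(pair, 0)
        pf = np.zeros((3, 3))
        pf[0, 1] = 1.0
        pn = 1.0 - pf - pf.T
        np.fill_diagonal(pn, 0)
        d = EdgeStateDistribution(pf, pn)
        # (1 - 1) certainty factor wipes out every parent contribution
        assert np.allclose(knockout_scores(pair, d)[0], 0.0)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        from conftest import sample_set_from
        gs = [random_dag(5, 0.4, rng) for _ in range(15)]
        s = sample_set_from(gs)
        d = edge_state_distribution(s)
        pair = edge_entropy(d)
        base = knockout_scores(pair, d)
        perm = rng.permutation(5)
        pf_p = d.p_fwd[np.ix_(perm, perm)]
        pn_p = d.p_none[np.ix_(perm, perm)]
        d_p = EdgeStateDistribution(pf_p, pn_p)
        permuted = knockout_scores(edge_entropy(d_p), d_p)
        assert np.allclose(permuted, base[perm])


class TestSelectInterventions:
    def test_argmax_basic(self):
        assert select_interventions(np.array([0.1, 0.9, 0.5]), 1) == [1]

    def test_tie_break_smallest_index(self):
        assert select_interventions(np.ones(4), 2) == [0, 1]

    def test_uniform_frequencies(self):
        rng = np.random.default_rng(123)
        counts = np.zeros(16)
        n_draws = 8000
        for _ in range(n_draws):
            g = select_interventions(np.zeros(16), 1, rng=rng,
                                     mode="uniform")[0]
            counts[g] += 1
        assert np.allclose(counts / n_draws, 1 / 16, atol=0.015)

    def test_exclusion_and_bounds(self):
        with pytest.raises(ValueError):
            select_interventions(np.zeros(3), 4)
        got = select_interventions(np.array([0.9, 0.5, 0.1]), 1,
                                   exclude={0})
        assert got == [1]
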