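import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grnactive.graphs import (DirectedGraph, PartiallyDirectedGraph, ShdMode,
                              cpdag_from_dag, is_acyclic, meek_closure,
                              read_edge_list, read_pdag_edge_list,
                              repair_to_dag, shd, write_edge_list,
                              write_pdag_edge_list)
from oracles import all_dags, oracle_cpdag, random_dag


class TestGraphTypes:
    def test_rejects_self_loops_and_out_of_range(self):
        with pytest.raises(ValueError):
            DirectedGraph(3, {(1, 1)})
        with pytest.raises(ValueError):
            DirectedGraph(3, {(0, 3)})
        with pytest.raises(ValueError):
            DirectedGraph(2, {(0, 1)}, labels=("a", "a"))

    def test_pdag_rejects_conflicting_states(self):
        with pytest.raises(ValueError):
            PartiallyDirectedGraph(3, {(0, 1), (1, 0)})
        with pytest.raises(ValueError):
            PartiallyDirectedGraph(3, {(0, 1)}, {frozenset({0, 1})})

    def test_adjacency_roundtrip(self):
        g = DirectedGraph(4, {(0, 1), (2, 3), (3, 0)})
        assert DirectedGraph.from_adjacency(g.adjacency()) == g


class TestAcyclicity:
    @pytest.mark.parametrize("edges, expected", [
        (set(), True),                               # empty graph
        ({(0, 1), (1, 2), (2, 0)}, False),           # 3-cycle
        ({(0, 1), (0, 2), (1, 2)}, True),            # transitive triangle
    ])
    def test_small_cases(self, edges, expected):
        assert is_acyclic(DirectedGraph(5, edges)) is expected


class TestCpdag:
    def test_chain_is_fully_undirected(self, chain3):
        cp = cpdag_from_dag(chain3)
        assert cp.directed_edges == frozenset()
        assert cp.undirected_edges == {frozenset({0, 1}), frozenset({1, 2})}

    def test_collider_stays_compelled(self, collider3):
        cp = cpdag_from_dag(collider3)
        assert cp.directed_edges == {(0, 2), (1, 2)}
        assert cp.undirected_edges == frozenset()

    def test_meek_propagation_after_v_structure(self):
        # 0 -> 1 <- 2 compels both, and R1 then compels 1 -> 3
        g = DirectedGraph(4, {(0, 1), (2, 1), (1, 3)})
        cp = cpdag_from_dag(g)
        assert cp.directed_edges == {(0, 1), (2, 1), (1, 3)}
        assert cp.undirected_edges == frozenset()

    def test_rejects_cyclic_input(self):
        with pytest.raises(ValueError):
            cpdag_from_dag(DirectedGraph(3, {(0, 1), (1, 2), (2, 0)}))

    @pytest.mark.parametrize("n", [2, 3])
    def test_agrees_with_mec_oracle_exhaustively(self, n):
        """CPDAG = orientation intersection of the d-separation-defined MEC."""
        for g in all_dags(n):
            assert cpdag_from_dag(g) == oracle_cpdag(g)

    def test_markov_equivalent_dags_share_cpdag(self):
        a = DirectedGraph(3, {(0, 1), (1, 2)})
        b = DirectedGraph(3, {(1, 0), (1, 2)})
        c = DirectedGraph(3, {(2, 1), (1, 0)})
        assert cpdag_from_dag(a) == cpdag_from_dag(b) == cpdag_from_dag(c)


class TestMeekClosure:
    def test_r1_orients_downstream_edge(self):
        p = PartiallyDirectedGraph(3, {(0, 1)}, {frozenset({1, 2})})
        out = meek_closure(p)
        assert (1, 2) in out.directed_edges

    def test_undirected_triangle_unchanged(self):
        tri = {frozenset(e) for e in [(0, 1), (1, 2), (0, 2)]}
        p = PartiallyDirectedGraph(3, frozenset(), frozenset(tri))
        assert meek_closure(p) == p

    def test_rejects_cyclic_directed_part(self):
        with pytest.raises(ValueError):
            meek_closure(PartiallyDirectedGraph(3, {(0, 1), (1, 2), (2, 0)}))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_idempotent_and_monotone_on_random_pdags(self, seed):
        rng = np.random.default_rng(seed)
        dag = random_dag(8, 0.3, rng)
        cp = cpdag_from_dag(dag)
        once = meek_closure(cp)
        assert once.directed_edges >= cp.directed_edges
        assert once.skeleton() == cp.skeleton()
        assert meek_closure(once) == once

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_sound_under_true_background_orientation(self, seed):
        """Orienting one reversible edge as in the generating DAG and closing
        must only ever produce orientations the DAG actually has."""
        rng = np.random.default_rng(seed)
        dag = random_dag(7, 0.35, rng)
        cp = cpdag_from_dag(dag)
        if not cp.undirected_edges:
            return
        e = sorted(cp.undirected_edges, key=sorted)[0]
        i, j = sorted(e)
        if (i, j) not in dag.edges:
            i, j = j, i
        seeded = PartiallyDirectedGraph(
            cp.n_nodes, cp.directed_edges | {(i, j)},
            cp.undirected_edges - {frozenset(e)})
        closed = meek_closure(seeded)
        assert all(edge in dag.edges for edge in closed.directed_edges)


class TestRepairToDag:
    def test_identity_on_dags(self, chain3):
        dag, removed = repair_to_dag(chain3)
        assert dag == chain3 and removed == frozenset()

    def test_three_cycle_loses_exactly_one_edge(self):
        g = DirectedGraph(3, {(0, 1), (1, 2), (2, 0)})
        dag, removed = repair_to_dag(g)
        assert len(removed) == 1 and is_acyclic(dag)
        assert dag.edges == g.edges - removed

    def test_deterministic(self):
        g = DirectedGraph(5, {(0, 1), (1, 2), (2, 0), (2, 3), (3, 4), (4, 2)})
        assert repair_to_dag(g) == repair_to_dag(g)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_output_always_acyclic(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        base = random_dag(n, 0.3, rng)
        extra = {(j, i) for i, j in base.edges if rng.random() < 0.3}
        g = DirectedGraph(n, base.edges | frozenset(extra))
        dag, removed = repair_to_dag(g)
        assert is_acyclic(dag)
        assert dag.edges == g.edges - removed


class TestShd:
    def test_identical_graphs_zero(self, chain3):
        for mode in ShdMode:
            if mode is ShdMode.pdag:
                cp = cpdag_from_dag(chain3)
                assert shd(cp, cp, mode) == 0
            else:
                assert shd(chain3, chain3, mode) == 0

    def test_empty_vs_k_edges(self):
        g = DirectedGraph(4, {(0, 1), (1, 2), (2, 3)})
        empty = DirectedGraph(4)
        assert shd(empty, g, ShdMode.directed) == 3
        assert shd(empty, g, ShdMode.undirected) == 3
        assert shd(cpdag_from_dag(empty), cpdag_from_dag(g), ShdMode.pdag) == 3

    def test_reversal_counts_one_by_default(self):
        a = DirectedGraph(3, {(0, 1), (1, 2)})
        b = DirectedGraph(3, {(1, 0), (1, 2)})
        assert shd(a, b, ShdMode.directed) == 1
        assert shd(a, b, ShdMode.directed, reversal_cost=2) == 2
        assert shd(a, b, ShdMode.undirected) == 0

    def test_pdag_mode_distinguishes_undirected_state(self):
        a = PartiallyDirectedGraph(3, {(0, 1)}, {frozenset({1, 2})})
        b = PartiallyDirectedGraph(3, frozenset(),
                                   {frozenset({0, 1}), frozenset({1, 2})})
        assert shd(a, b, ShdMode.pdag) == 1

    def test_rejects_mismatched_node_sets(self):
        with pytest.raises(ValueError):
            shd(DirectedGraph(3), DirectedGraph(4))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_metric_properties(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = (random_dag(6, 0.4, rng) for _ in range(3))
        for mode in (ShdMode.directed, ShdMode.undirected):
            assert shd(a, b, mode) == shd(b, a, mode)
            assert shd(a, c, mode) <= shd(a, b, mode) + shd(b, c, mode)
        ca, cb, cc = map(cpdag_from_dag, (a, b, c))
        assert shd(ca, cb, ShdMode.pdag) == shd(cb, ca, ShdMode.pdag)
        assert shd(ca, cc, ShdMode.pdag) <= \
            shd(ca, cb, ShdMode.pdag) + shd(cb, cc, ShdMode.pdag)


class TestEdgeListIO:
    def test_directed_roundtrip(self, tmp_path):
        g = DirectedGraph(4, {(0, 1), (2, 3)}, labels=("a", "b", "c", "d"))
        path = tmp_path / "net.tsv"
        write_edge_list(g, path)
        back = read_edge_list(path, labels=g.labels)
        assert back == g

    def test_default_gene_names_roundtrip(self, tmp_path):
        g = DirectedGraph(5, {(0, 4), (3, 1)})
        path = tmp_path / "net.tsv"
        write_edge_list(g, path)
        back = read_edge_list(path, n_nodes=5)
        assert back.edges == g.edges

    def test_pdag_roundtrip(self, tmp_path):
        p = PartiallyDirectedGraph(4, {(0, 1)},
                                   {frozenset({1, 2}), frozenset({2, 3})})
        path = tmp_path / "pdag.tsv"
        write_pdag_edge_list(p, path)
        assert read_pdag_edge_list(path, n_nodes=4) == p
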