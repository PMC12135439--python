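"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the code paths they check: Markov equivalence is
decided by full d-separation signatures (networkx), not by skeleton /
v-structure comparison, and the oracle CPDAG is the orientation
intersection over the enumerated equivalence class.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import networkx as nx
import numpy as np

from grnactive.graphs import DirectedGraph, PartiallyDirectedGraph


@lru_cache(maxsize=8)
def all_dags(n: int) -> tuple[DirectedGraph, ...]:
    """Every DAG on n labelled nodes, by filtering all pair orientations."""
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    out = []
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        edges = set()
        for (i, j), s in zip(pairs, states):
            if s == 1:
                edges.add((i, j))
            elif s == 2:
                edges.add((j, i))
        g = DirectedGraph(n, frozenset(edges))
        if nx.is_directed_acyclic_graph(g.to_networkx()):
            out.append(g)
    return tuple(out)


def ci_signature(g: DirectedGraph) -> tuple[bool, ...]:
    """All conditional-independence statements entailed by the DAG."""
    ng = g.to_networkx()
    n = g.n_nodes
    sig = []
    for i in range(n):
        for j in range(i + 1, n):
            rest = [k for k in range(n) if k not in (i, j)]
            for r in range(len(rest) + 1):
                for z in itertools.combinations(rest, r):
                    sig.append(nx.is_d_separator(ng, {i}, {j}, set(z)))
    return tuple(sig)


@lru_cache(maxsize=8)
def mec_partition(n: int) -> dict[tuple[bool, ...], tuple[DirectedGraph, ...]]:
    """Markov equivalence classes of all DAGs on n nodes, via d-separation."""
    groups: dict[tuple[bool, ...], list[DirectedGraph]] = {}
    for g in all_dags(n):
        groups.setdefault(ci_signature(g), []).append(g)
    return {k: tuple(v) for k, v in groups.items()}


def oracle_cpdag(g: DirectedGraph) -> PartiallyDirectedGraph:
    """CPDAG as the orientation intersection over the brute-forced MEC."""
    members = mec_partition(g.n_nodes)[ci_signature(g)]
    skel = g.skeleton()
    directed = {(i, j) for i, j in g.edges
                if all((i, j) in m.edges for m in members)}
    undirected = frozenset(
        e for e in skel
        if tuple(sorted(e)) not in directed
        and tuple(sorted(e, reverse=True)) not in directed)
    return PartiallyDirectedGraph(g.n_nodes, frozenset(directed), undirected)


def random_dag(n: int, p_edge: float, rng: np.random.Generator) -> DirectedGraph:
    """Random DAG over a random topological order."""
    order = rng.permutation(n)
    pos = np.empty(n, dtype=int)
    pos[order] = np.arange(n)
    edges = {(i, j) for i in range(n) for j in range(n)
             if i != j and pos[i] < pos[j] and rng.random() < p_edge}
    return DirectedGraph(n, frozenset(edges))
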