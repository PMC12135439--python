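"""Synthetic regulatory networks and knockout expression data.

Ground truth is a sparse directed network (optionally cyclic, as curated
reference networks usually are); data comes from a linear-Gaussian
structural equation model over the acyclic repair of that network.  Each
observational "time series" is the network perturbed by a random per-gene
offset and then observed with independent noise, which preserves the
statistical structure of perturbation time-course experiments (structure
identifiable up to the Markov equivalence class from observational data,
orientations from knockouts) without kinetic ODE machinery.  A knockout
clamps the target gene's expression to a fixed value and severs its
incoming mechanism — a perfect intervention.

The default fixture mirrors a widely used in-silico benchmark layout:
64 genes, a 207-edge reference network whose DAG repair removes 21 edges,
10 observational series of 21 time points (210 samples), and one 21-sample
knockout series per gene (1,344 interventional samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import ExpressionDataset
from .graphs import (DirectedGraph, PartiallyDirectedGraph, cpdag_from_dag,
                     is_acyclic, repair_to_dag)

__all__ = [
    "GaussianSEM",
    "random_ground_truth",
    "random_sem",
    "simulate",
    "gnw_scale_fixture",
]


@dataclass
class GaussianSEM:
    """Linear-Gaussian structural equation model on a DAG.

    Gene j is generated as
    ``x_j = baseline_j + offset_j + sum_i weight[i, j] * x_i + eps_j`` with
    ``eps_j ~ N(0, noise_sd_j^2)``, evaluated in topological order.
    ``weight[i, j]`` is nonzero exactly on the edges of ``graph``.
    """

    graph: DirectedGraph
    weight: np.ndarray
    noise_sd: np.ndarray
    baseline: np.ndarray

    def __post_init__(self) -> None:
        if not is_acyclic(self.graph):
            raise ValueError("SEM graph must be acyclic")
        n = self.graph.n_nodes
        self.weight = np.asarray(self.weight, dtype=float)
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (n,)).copy()
        self.baseline = np.broadcast_to(
            np.asarray(self.baseline, dtype=float), (n,)).copy()
        if self.weight.shape != (n, n):
            raise ValueError("weight matrix shape mismatch")
        support = frozenset(zip(*map(list, np.nonzero(self.weight))))
        if support != self.graph.edges:
            raise ValueError("weights must be nonzero exactly on graph edges")
        if np.any(self.noise_sd <= 0):
            raise ValueError("noise_sd must be positive")

    @property
    def n_genes(self) -> int:
        return self.graph.n_nodes

    def covariance(self, offset_sd: float = 0.0) -> np.ndarray:
        """Closed-form stationary covariance (I - W^T)^-1 D (I - W^T)^-T.

        ``D`` holds the per-gene noise variances plus, when ``offset_sd``
        is nonzero, the variance of the per-series perturbation offsets.
        """
        n = self.n_genes
        m = np.linalg.inv(np.eye(n) - self.weight.T)
        d = np.diag(self.noise_sd ** 2 + offset_sd ** 2)
        return m @ d @ m.T


def random_ground_truth(n_nodes: int, n_edges: int, n_back_edges: int = 0,
                        seed: int | None = None) -> DirectedGraph:
    """Sparse random reference network: a DAG plus feedback edges.

    ``n_edges - n_back_edges`` forward edges are drawn uniformly over a
    random topological order; ``n_back_edges`` feedback edges are added as
    reversals of distinct forward edges, so each one closes at least one
    cycle (reference regulatory networks contain feedback loops).  Draws
    where the greedy DAG repair would not remove exactly ``n_back_edges``
    edges are rejected and redrawn, keeping the documented reference-network
    shape (repair removes exactly the feedback count) for every seed.
    Deterministic given ``seed``.
    """
    n_forward = n_edges - n_back_edges
    max_forward = n_nodes * (n_nodes - 1) // 2
    if n_back_edges < 0 or n_forward < 0 or n_forward > max_forward \
            or n_back_edges > n_forward:
        raise ValueError("infeasible edge counts")
    rng = np.random.default_rng(seed)
    labels = tuple(f"G{k + 1}" for k in range(n_nodes))
    for _ in range(1000):
        order = rng.permutation(n_nodes)
        pos = np.empty(n_nodes, dtype=int)
        pos[order] = np.arange(n_nodes)
        pairs = [(i, j) for i in range(n_nodes) for j in range(n_nodes)
                 if i != j and pos[i] < pos[j]]
        chosen = rng.choice(len(pairs), size=n_forward, replace=False)
        forward = [pairs[k] for k in chosen]
        back_idx = rng.choice(n_forward, size=n_back_edges, replace=False)
        back = [(j, i) for i, j in (forward[k] for k in back_idx)]
        g = DirectedGraph(n_nodes, frozenset(forward) | frozenset(back),
                          labels=labels)
        if g.n_edges != n_edges:
            continue
        if n_back_edges == 0:
            return g
        _, removed = repair_to_dag(g)
        if len(removed) == n_back_edges:
            return g
    raise RuntimeError("could not draw a clean reference network")


def random_sem(graph: DirectedGraph, seed: int | None = None, *,
               weight_range: tuple[float, float] = (0.5, 1.5),
               noise_sd: float = 1.0) -> GaussianSEM:
    """Random SEM on (the acyclic repair of) ``graph``.

    Edge coefficients are drawn uniformly from +-[lo, hi] — bounded away
    from zero so no edge is near-unidentifiable.  Cyclic inputs are
    repaired to a DAG first.
    """
    if not is_acyclic(graph):
        graph, _ = repair_to_dag(graph)
    rng = np.random.default_rng(seed)
    n = graph.n_nodes
    w = np.zeros((n, n))
    lo, hi = weight_range
    for i, j in sorted(graph.edges):
        w[i, j] = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
    return GaussianSEM(graph, w, np.full(n, noise_sd), np.zeros(n))


def simulate(sem: GaussianSEM, n_series: int, n_timepoints: int,
             intervention: int | None = None, seed: int | None = None, *,
             offset_sd: float = 0.25, clamp_value: float = 0.0) -> ExpressionDataset:
    """Generate perturbation series from the SEM, optionally under knockout.

    Each series draws one random perturbation offset per gene
    (``N(0, offset_sd^2)``), then emits ``n_timepoints`` independent draws
    of the SEM with that offset added to every baseline.  Under a knockout
    the target gene's column is clamped to ``clamp_value`` in every row and
    its own mechanism (baseline, offset, parents, noise) is inert; its
    value still feeds forward into its children.
    """
    if intervention is not None and not (0 <= intervention < sem.n_genes):
        raise ValueError("intervention gene out of range")
    rng = np.random.default_rng(seed)
    n = sem.n_genes
    topo_order = _topological_order(sem.graph)
    rows = np.empty((n_series * n_timepoints, n))
    series_id = np.repeat(np.arange(n_series), n_timepoints)
    time_index = np.tile(np.arange(n_timepoints), n_series)
    for s in range(n_series):
        offset = rng.normal(0.0, offset_sd, size=n) if offset_sd > 0 \
            else np.zeros(n)
        noise = rng.normal(0.0, 1.0, size=(n_timepoints, n)) * sem.noise_sd
        x = np.zeros((n_timepoints, n))
        for j in topo_order:
            if intervention == j:
                x[:, j] = clamp_value
                continue
            x[:, j] = sem.baseline[j] + offset[j] + noise[:, j]
            for i in np.flatnonzero(sem.weight[:, j]):
                x[:, j] += sem.weight[i, j] * x[:, i]
        rows[s * n_timepoints:(s + 1) * n_timepoints] = x
    interventions = np.full(rows.shape[0],
                            -1 if intervention is None else intervention)
    clamp = np.full(rows.shape[0],
                    clamp_value if intervention is not None else 0.0)
    return ExpressionDataset(rows, interventions=interventions,
                             clamp_values=clamp, series_id=series_id,
                             time_index=time_index,
                             gene_names=sem.graph.labels)


def _topological_order(g: DirectedGraph) -> list[int]:
    import networkx as nx
    return list(nx.topological_sort(g.to_networkx()))


def gnw_scale_fixture(seed: int = 0, *, n_nodes: int = 64, n_edges: int = 207,
                      n_back_edges: int = 21, n_series: int = 10,
                      n_timepoints: int = 21):
    """Benchmark-scale synthetic study: truth, reference PDAG, and data.

    Returns ``(truth, reference_pdag, observational, knockout_pool)``:

    * ``truth`` — the (cyclic) 207-edge reference network;
    * ``reference_pdag`` — essential graph of its DAG repair (Meek rules);
    * ``observational`` — 10 series x 21 time points = 210 samples;
    * ``knockout_pool`` — one 21-sample knockout series per gene
      (64 x 21 = 1,344 interventional samples in total).

    Fully deterministic given ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_truth, s_sem, s_obs, s_ko = (int(c.generate_state(1)[0] % (2 ** 31))
                                   for c in ss.spawn(4))
    truth = random_ground_truth(n_nodes, n_edges, n_back_edges, seed=s_truth)
    dag, _ = repair_to_dag(truth)
    reference_pdag = cpdag_from_dag(dag)
    sem = random_sem(dag, seed=s_sem)
    observational = simulate(sem, n_series, n_timepoints, seed=s_obs)
    ko_seeds = np.random.SeedSequence(s_ko).spawn(n_nodes)
    knockout_pool = {
        g: simulate(sem, 1, n_timepoints, intervention=g,
                    seed=int(ko_seeds[g].generate_state(1)[0] % (2 ** 31)))
        for g in range(n_nodes)
    }
    return truth, reference_pdag, observational, knockout_pool
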