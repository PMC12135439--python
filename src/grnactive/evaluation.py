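"""Posterior-quality metrics against a known ground-truth network.

All metrics are posterior expectations — weighted means over the sampled
graphs: structural Hamming distance to the true DAG (directed and on
skeletons), SHD between essential graphs (sample CPDAG vs the reference
PDAG), expected number of predicted edges (NNZ), and recall of the true
edges.  Directed/undirected SHD are taken against the acyclic repair of
the reference network; the PDAG SHD against its Meek-completed essential
graph.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .graphs import (DirectedGraph, PartiallyDirectedGraph, ShdMode,
                     cpdag_from_dag_cached, shd)
from .posterior import PosteriorSampleSet

__all__ = ["PosteriorMetrics", "evaluate_posterior"]


@dataclass(frozen=True)
class PosteriorMetrics:
    """Posterior-weighted expectations of the structure-quality metrics.

    ``recall`` counts true edges recovered with the correct orientation;
    ``skeleton_recall`` ignores orientation (the looser reading).
    """

    shd_directed: float
    shd_undirected: float
    shd_pdag: float
    nnz: float
    recall: float
    skeleton_recall: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.recall <= 1.0 and 0.0 <= self.skeleton_recall <= 1.0):
            raise ValueError("recall must lie in [0, 1]")
        if min(self.shd_directed, self.shd_undirected, self.shd_pdag,
               self.nnz) < 0:
            raise ValueError("SHDs and NNZ must be non-negative")

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in asdict(self).items()}


def evaluate_posterior(s: PosteriorSampleSet, truth: DirectedGraph,
                       reference_pdag: PartiallyDirectedGraph | None = None
                       ) -> PosteriorMetrics:
    """Expected SHDs, NNZ and recall of a posterior sample set.

    ``reference_pdag`` defaults to the essential graph of ``truth`` (which
    must then be acyclic).
    """
    if s.n_nodes != truth.n_nodes:
        raise ValueError("node sets do not match")
    if reference_pdag is None:
        reference_pdag = cpdag_from_dag_cached(truth)
    if reference_pdag.n_nodes != truth.n_nodes:
        raise ValueError("node sets do not match")

    t_adj = truth.adjacency().astype(np.int16)
    n_true = max(truth.n_edges, 1)

    # expectations over unique samples (sample sets repeat graphs heavily)
    uniq: dict[bytes, list] = {}
    for k in range(s.n_samples):
        key = s.adjacency[k].tobytes()
        rec = uniq.get(key)
        if rec is None:
            uniq[key] = [s.adjacency[k], s.weights[k]]
        else:
            rec[1] += s.weights[k]

    e_shd_d = e_shd_u = e_shd_p = e_nnz = e_rec = e_skel = 0.0
    for adj, w in uniq.values():
        g = DirectedGraph.from_adjacency(adj)
        e_shd_d += w * shd(g, truth, ShdMode.directed)
        e_shd_u += w * shd(g, truth, ShdMode.undirected)
        e_shd_p += w * shd(cpdag_from_dag_cached(g), reference_pdag,
                           ShdMode.pdag)
        a = adj.astype(np.int16)
        e_nnz += w * float(a.sum())
        e_rec += w * float((a & t_adj).sum()) / n_true
        e_skel += w * float((((a | a.T) & (t_adj | t_adj.T)).sum() // 2)) \
            / n_true
    return PosteriorMetrics(e_shd_d, e_shd_u, e_shd_p, e_nnz,
                            min(e_rec, 1.0), min(e_skel, 1.0))
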