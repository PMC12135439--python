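"""Edge-state distributions derived from sampled posterior graphs.

Structure samplers emit hard DAGs; every acquisition function instead
consumes per-gene-pair probabilities.  In DAG space a pair occupies one of
three states (i->j, i<-j, no edge); in essential-graph space a fourth,
undirected, state appears because reversible edges of a Markov equivalence
class carry no orientation.  This module turns a weighted collection of
sampled DAGs into those 3- and 4-state distributions, and into
ensemble-member marginals (one distribution per MCMC chain / sample block)
for the disagreement-based scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .graphs import DirectedGraph, cpdag_from_dag_cached, is_acyclic

__all__ = [
    "PosteriorSampleSet",
    "EdgeStateDistribution",
    "PdagStateDistribution",
    "edge_state_distribution",
    "pdag_state_distribution",
    "ensemble_marginals",
]

_ATOL = 1e-9


@dataclass
class PosteriorSampleSet:
    """Weighted collection of sampled DAGs over a shared gene set.

    Parameters
    ----------
    adjacency
        ``(n_samples, n, n)`` stack of 0/1 adjacency matrices, each acyclic.
    weights
        Non-negative sample weights; normalised to sum to 1.  Default uniform.
    group_ids
        Optional ensemble-member label per sample (e.g. MCMC chain index).
    """

    adjacency: np.ndarray
    weights: np.ndarray | None = None
    group_ids: np.ndarray | None = None
    labels: tuple[str, ...] | None = None
    validate: bool = True

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.uint8)
        if self.adjacency.ndim != 3 or \
                self.adjacency.shape[1] != self.adjacency.shape[2]:
            raise ValueError("adjacency must be (n_samples, n, n)")
        if self.adjacency.shape[0] == 0:
            raise ValueError("sample set may not be empty")
        s = self.adjacency.shape[0]
        if self.weights is None:
            self.weights = np.full(s, 1.0 / s)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (s,):
                raise ValueError("weights length must equal sample count")
            if np.any(self.weights < 0):
                raise ValueError("weights must be non-negative")
            total = self.weights.sum()
            if total <= 0:
                raise ValueError("weights must not all be zero")
            self.weights = self.weights / total
        if self.group_ids is not None:
            self.group_ids = np.asarray(self.group_ids)
            if self.group_ids.shape != (s,):
                raise ValueError("group_ids length must equal sample count")
        if self.validate:
            for g in self.unique_graphs():
                if not is_acyclic(g):
                    raise ValueError("every posterior sample must be a DAG")

    @classmethod
    def from_graphs(cls, graphs: Sequence[DirectedGraph], weights=None,
                    group_ids=None, **kw) -> "PosteriorSampleSet":
        adj = np.stack([g.adjacency() for g in graphs])
        labels = graphs[0].labels if graphs else None
        return cls(adj, weights, group_ids, labels=labels, **kw)

    @property
    def n_samples(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[1]

    def graphs(self) -> Iterator[DirectedGraph]:
        for k in range(self.n_samples):
            yield DirectedGraph.from_adjacency(self.adjacency[k],
                                               labels=self.labels)

    def unique_graphs(self) -> list[DirectedGraph]:
        seen: dict[bytes, DirectedGraph] = {}
        for k in range(self.n_samples):
            key = self.adjacency[k].tobytes()
            if key not in seen:
                seen[key] = DirectedGraph.from_adjacency(self.adjacency[k],
                                                         labels=self.labels)
        return list(seen.values())

    # -- persistence (stacked headerless CSV + JSON sidecar) -------------

    def save(self, path: str | Path) -> None:
        """Write stacked adjacency blocks as CSV, metadata as a sidecar."""
        path = Path(path)
        flat = self.adjacency.reshape(-1, self.n_nodes)
        np.savetxt(path, flat, fmt="%d", delimiter=",")
        meta = {
            "n_nodes": int(self.n_nodes),
            "n_samples": int(self.n_samples),
            "weights": self.weights.tolist(),
            "group_ids": None if self.group_ids is None
            else np.asarray(self.group_ids).tolist(),
            "labels": None if self.labels is None else list(self.labels),
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorSampleSet":
        path = Path(path)
        meta = json.loads(
            path.with_suffix(path.suffix + ".meta.json").read_text())
        flat = np.loadtxt(path, delimiter=",", dtype=np.uint8, ndmin=2)
        n = meta["n_nodes"]
        adj = flat.reshape(meta["n_samples"], n, n)
        return cls(adj, np.asarray(meta["weights"]),
                   None if meta["group_ids"] is None
                   else np.asarray(meta["group_ids"]),
                   labels=None if meta["labels"] is None
                   else tuple(meta["labels"]))


def _check_pair_probs(*mats: np.ndarray) -> None:
    total = sum(mats)
    n = total.shape[0]
    off = ~np.eye(n, dtype=bool)
    if not np.allclose(total[off], 1.0, atol=_ATOL):
        raise ValueError("pair-state probabilities must sum to 1")
    for m in mats:
        if np.any(m < -_ATOL) or np.any(m > 1 + _ATOL):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class EdgeStateDistribution:
    """Per-pair probabilities over the DAG-space states {i->j, i<-j, none}.

    ``p_fwd[i, j]`` is P(i -> j); ``p_rev`` is its transpose; ``p_none`` is
    symmetric.  For every off-diagonal pair the three sum to 1 because each
    sampled graph is a DAG (never both orientations at once).
    """

    p_fwd: np.ndarray
    p_none: np.ndarray

    def __post_init__(self) -> None:
        self.p_fwd = np.asarray(self.p_fwd, dtype=float)
        self.p_none = np.asarray(self.p_none, dtype=float)
        if not np.allclose(self.p_none, self.p_none.T, atol=_ATOL):
            raise ValueError("p_none must be symmetric")
        _check_pair_probs(self.p_fwd, self.p_fwd.T, self.p_none)

    @property
    def p_rev(self) -> np.ndarray:
        return self.p_fwd.T

    @property
    def n_nodes(self) -> int:
        return self.p_fwd.shape[0]

    def stacked(self) -> np.ndarray:
        """(3, n, n) array in state order fwd, rev, none."""
        return np.stack([self.p_fwd, self.p_rev, self.p_none])


@dataclass
class PdagStateDistribution:
    """Per-pair probabilities over the four essential-graph states.

    States: compelled i->j (``p_fwd``), compelled i<-j (transpose),
    undirected i - j (``p_undir``, symmetric), absent (``p_none``,
    symmetric).
    """

    p_fwd: np.ndarray
    p_undir: np.ndarray
    p_none: np.ndarray

    def __post_init__(self) -> None:
        self.p_fwd = np.asarray(self.p_fwd, dtype=float)
        self.p_undir = np.asarray(self.p_undir, dtype=float)
        self.p_none = np.asarray(self.p_none, dtype=float)
        for m in (self.p_undir, self.p_none):
            if not np.allclose(m, m.T, atol=_ATOL):
                raise ValueError("p_undir and p_none must be symmetric")
        _check_pair_probs(self.p_fwd, self.p_fwd.T, self.p_undir, self.p_none)

    @property
    def p_rev(self) -> np.ndarray:
        return self.p_fwd.T

    @property
    def n_nodes(self) -> int:
        return self.p_fwd.shape[0]

    def stacked(self) -> np.ndarray:
        """(4, n, n) array in state order fwd, rev, undirected, none."""
        return np.stack([self.p_fwd, self.p_rev, self.p_undir, self.p_none])


def edge_state_distribution(s: PosteriorSampleSet) -> EdgeStateDistribution:
    """Weighted per-pair frequencies of {i->j, i<-j, no edge} over samples."""
    w = s.weights[:, None, None]
    p_fwd = (w * s.adjacency).sum(axis=0)
    np.fill_diagonal(p_fwd, 0.0)
    p_none = 1.0 - p_fwd - p_fwd.T
    np.fill_diagonal(p_none, 0.0)
    # guard tiny negative rounding
    p_none = np.clip(p_none, 0.0, 1.0)
    return EdgeStateDistribution(p_fwd, p_none)


def pdag_state_distribution(s: PosteriorSampleSet) -> PdagStateDistribution:
    """Four-state per-pair frequencies after mapping each sample to its CPDAG."""
    n = s.n_nodes
    p_fwd = np.zeros((n, n))
    p_undir = np.zeros((n, n))
    cache: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}
    for k in range(s.n_samples):
        key = s.adjacency[k].tobytes()
        if key not in cache:
            g = DirectedGraph.from_adjacency(s.adjacency[k])
            cp = cpdag_from_dag_cached(g)
            dmat = np.zeros((n, n))
            umat = np.zeros((n, n))
            for i, j in cp.directed_edges:
                dmat[i, j] = 1.0
            for e in cp.undirected_edges:
                i, j = tuple(e)
                umat[i, j] = umat[j, i] = 1.0
            cache[key] = (dmat, umat)
        dmat, umat = cache[key]
        p_fwd += s.weights[k] * dmat
        p_undir += s.weights[k] * umat
    p_none = 1.0 - p_fwd - p_fwd.T - p_undir
    np.fill_diagonal(p_none, 0.0)
    p_none = np.clip(p_none, 0.0, 1.0)
    return PdagStateDistribution(p_fwd, p_undir, p_none)


def _group_slices(s: PosteriorSampleSet, n_groups: int) -> list[np.ndarray]:
    if n_groups < 1:
        raise ValueError("n_groups must be positive")
    if n_groups > s.n_samples:
        raise ValueError("n_groups exceeds the number of samples")
    if s.group_ids is not None:
        uniq = sorted(set(np.asarray(s.group_ids).tolist()))
        return [np.flatnonzero(s.group_ids == gid) for gid in uniq]
    idx = np.arange(s.n_samples)
    return [chunk for chunk in np.array_split(idx, n_groups)]


def ensemble_marginals(s: PosteriorSampleSet, n_groups: int = 8, *,
                       kind: str = "dag"):
    """Per-ensemble-member edge-state distributions.

    Members follow ``group_ids`` when present, otherwise the samples are
    split into ``n_groups`` contiguous blocks.  ``kind`` selects 3-state
    DAG-space (``"dag"``) or 4-state essential-graph (``"pdag"``)
    distributions.  The weight-weighted mean of the member distributions
    equals the pooled distribution.
    """
    maker = {"dag": edge_state_distribution,
             "pdag": pdag_state_distribution}[kind]
    out = []
    for rows in _group_slices(s, n_groups):
        if len(rows) == 0:
            continue
        sub = PosteriorSampleSet(s.adjacency[rows], s.weights[rows],
                                 labels=s.labels, validate=False)
        out.append(maker(sub))
    return out


def member_weights(s: PosteriorSampleSet, n_groups: int = 8) -> np.ndarray:
    """Total posterior weight carried by each ensemble member."""
    w = np.array([s.weights[rows].sum()
                  for rows in _group_slices(s, n_groups) if len(rows) > 0])
    return w / w.sum()
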