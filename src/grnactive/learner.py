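"""Reference Bayesian structure posterior samplers.

Two samplers stand behind the pluggable interface the acquisition layer
consumes: exact enumeration of every DAG (feasible up to five genes; the
oracle the stochastic sampler is validated against) and structure MCMC —
Metropolis-Hastings over DAG space with add / delete / reverse edge
proposals and a decomposable interventional Gaussian family score.

Knockouts enter through the truncated factorisation of perfect
interventions: a sample in which gene j was knocked out contributes
nothing to j's own local score (its value was set by the experimenter, not
its mechanism), while the clamped value still serves as a predictor for
j's children.  This is what makes edge directions identifiable: for a true
edge i -> j, knocking out i leaves the mechanism of j intact, whereas the
anticausal model j -> i must explain an i that no longer listens to j.

Scores: Gaussian BIC (default; no prior hyperparameters) and the BGe
marginal likelihood.  Both are score equivalent on purely observational
data, so the posterior then spreads over Markov equivalence classes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Protocol

import numpy as np
from scipy.special import gammaln

from .datasets import ExpressionDataset
from .posterior import PosteriorSampleSet

__all__ = [
    "LearnerConfig",
    "family_score",
    "exact_posterior",
    "mcmc_sample",
    "enumerate_dags",
    "StructureSampler",
    "MCMCSampler",
    "ExactSampler",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class LearnerConfig:
    """Sampler settings.

    max_parents
        Fan-in cap; regulatory networks are sparse, and the cap bounds the
        family-score search space.
    n_samples
        Posterior samples returned in total (split across chains).
    n_chains
        Independent MCMC chains; these double as the BALD ensemble members.
    burn_in, thinning
        Per-chain schedule: discarded leading moves, then one sample every
        ``thinning`` moves.
    score
        ``bic_gaussian`` (default) or ``bge``.
    """

    max_parents: int = 4
    n_samples: int = 800
    n_chains: int = 8
    burn_in: int = 1000
    thinning: int = 5
    seed: int = 0
    score: str = "bic_gaussian"

    def __post_init__(self) -> None:
        for name in ("max_parents", "n_samples", "n_chains", "thinning"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")
        if self.score not in ("bic_gaussian", "bge"):
            raise ValueError(f"unknown score {self.score!r}")


class StructureSampler(Protocol):
    """Anything that can turn expression data into posterior DAG samples.

    External samplers may implement this interface; the package ships the
    exact enumerator and the structure-MCMC reference implementations.
    """

    def fit(self, data: ExpressionDataset) -> PosteriorSampleSet:  # pragma: no cover
        ...


# ---------------------------------------------------------------------------
# Family scores
# ---------------------------------------------------------------------------

class _ScoreCache:
    """Decomposable local scores with memoisation per (node, parent set)."""

    def __init__(self, data: ExpressionDataset, score: str = "bic_gaussian"):
        self.x = data.values
        self.score = score
        self.n_genes = data.n_genes
        self.rows = [np.flatnonzero(data.interventions != j)
                     for j in range(self.n_genes)]
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}
        if score == "bge":
            self._bge = _BgeParams(self.n_genes)

    def family(self, node: int, parents: tuple[int, ...]) -> float:
        key = (node, parents)
        got = self._cache.get(key)
        if got is not None:
            return got
        val = self._compute(node, parents)
        self._cache[key] = val
        return val

    def _compute(self, node: int, parents: tuple[int, ...]) -> float:
        rows = self.rows[node]
        if rows.size == 0:
            return 0.0  # every sample intervened on this node
        if self.score == "bic_gaussian":
            val = _bic_family(self.x, rows, node, parents)
        else:
            val = self._bge.family(self.x, rows, node, parents)
        return val

    def graph_score(self, parent_sets: list[tuple[int, ...]]) -> float:
        return sum(self.family(j, ps) for j, ps in enumerate(parent_sets))


def _bic_family(x: np.ndarray, rows: np.ndarray, node: int,
                parents: tuple[int, ...]) -> float:
    """Gaussian BIC local score: max log-likelihood minus (k/2) log n."""
    n = rows.size
    k = len(parents) + 2  # coefficients + intercept + variance
    if n < k:
        return NEG_INF
    y = x[rows, node]
    if parents:
        design = np.column_stack([x[rows][:, list(parents)],
                                  np.ones(n)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
    else:
        resid = y - y.mean()
    var = float(resid @ resid) / n
    var = max(var, 1e-12)
    loglik = -0.5 * n * (math.log(2 * math.pi * var) + 1.0)
    return loglik - 0.5 * k * math.log(n)


class _BgeParams:
    """BGe marginal-likelihood local score (Gaussian-inverse-Wishart prior).

    Hyperparameters follow the common default: alpha_mu = 1,
    alpha_w = n + 2, prior scale T = t * I with
    t = alpha_mu (alpha_w - n - 1) / (alpha_mu + 1), prior mean at the
    sample mean.
    """

    def __init__(self, n_vars: int, alpha_mu: float = 1.0,
                 alpha_w: float | None = None):
        self.n = n_vars
        self.am = alpha_mu
        self.aw = alpha_w if alpha_w is not None else n_vars + 2.0
        self.t = self.am * (self.aw - self.n - 1.0) / (self.am + 1.0)

    def family(self, x: np.ndarray, rows: np.ndarray, node: int,
               parents: tuple[int, ...]) -> float:
        big_n = rows.size
        p = len(parents)
        if big_n < p + 2:
            return NEG_INF
        cols = list(parents) + [node]
        sub = x[rows][:, cols]
        centred = sub - sub.mean(axis=0)
        r = centred.T @ centred + self.t * np.eye(p + 1)
        n, am, aw, t = self.n, self.am, self.aw, self.t

        def log_det(m: np.ndarray) -> float:
            if m.size == 0:
                return 0.0
            sign, ld = np.linalg.slogdet(m)
            if sign <= 0:
                return NEG_INF
            return ld

        const = (0.5 * math.log(am / (am + big_n))
                 - 0.5 * big_n * math.log(math.pi))
        num = (gammaln(0.5 * (big_n + aw - n + p + 1))
               - gammaln(0.5 * (aw - n + p + 1))
               + 0.5 * (aw - n + 2 * p + 1) * math.log(t)
               - 0.5 * (big_n + aw - n + p + 1) * log_det(r))
        if p:
            num += 0.5 * (big_n + aw - n + p) * log_det(r[:p, :p])
        return const + num


def family_score(data: ExpressionDataset, node: int, parents, *,
                 score: str = "bic_gaussian") -> float:
    """Local score of ``node`` given ``parents`` under the truncated
    factorisation (samples intervening on ``node`` are excluded).

    Returns 0 when every sample intervenes on the node and ``-inf`` when
    too few samples remain to fit the regression.
    """
    parents = tuple(sorted(int(p) for p in parents))
    if node in parents:
        raise ValueError("a node cannot be its own parent")
    return _ScoreCache(data, score).family(node, parents)


# ---------------------------------------------------------------------------
# Exact enumeration
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def enumerate_dags(n_nodes: int) -> tuple[np.ndarray, ...]:
    """All DAG adjacency matrices on ``n_nodes`` labelled nodes (n <= 5)."""
    if n_nodes > 5:
        raise ValueError("exact enumeration supported for n_nodes <= 5 only")
    pairs = [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)]
    out = []
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        adj = np.zeros((n_nodes, n_nodes), dtype=np.uint8)
        for (i, j), s in zip(pairs, states):
            if s == 1:
                adj[i, j] = 1
            elif s == 2:
                adj[j, i] = 1
        if _acyclic_adj(adj):
            out.append(adj)
    return tuple(out)


def _acyclic_adj(adj: np.ndarray) -> bool:
    indeg = adj.sum(axis=0).astype(int)
    stack = [v for v in range(adj.shape[0]) if indeg[v] == 0]
    seen = 0
    while stack:
        v = stack.pop()
        seen += 1
        for w in np.flatnonzero(adj[v]):
            indeg[w] -= 1
            if indeg[w] == 0:
                stack.append(int(w))
    return seen == adj.shape[0]


def exact_posterior(data: ExpressionDataset,
                    config: LearnerConfig | None = None) -> PosteriorSampleSet:
    """Full posterior over every DAG on up to five genes.

    Each DAG is weighted by ``exp(sum of family scores)`` under a uniform
    structure prior, normalised over the complete support (25 DAGs for
    three genes, 543 for four).
    """
    config = config or LearnerConfig()
    n = data.n_genes
    if n > 5:
        raise ValueError("exact_posterior requires n_genes <= 5")
    cache = _ScoreCache(data, config.score)
    dags = enumerate_dags(n)
    logs = np.empty(len(dags))
    kept = []
    for k, adj in enumerate(dags):
        parent_sets = [tuple(np.flatnonzero(adj[:, j]).tolist())
                       for j in range(n)]
        if any(len(ps) > config.max_parents for ps in parent_sets):
            logs[k] = NEG_INF
        else:
            logs[k] = cache.graph_score(parent_sets)
        kept.append(adj)
    logs -= logs.max()
    w = np.exp(logs)
    w /= w.sum()
    return PosteriorSampleSet(np.stack(kept), w, labels=data.gene_names,
                              validate=False)


# ---------------------------------------------------------------------------
# Structure MCMC
# ---------------------------------------------------------------------------

def _has_path(children: list[set[int]], src: int, dst: int) -> bool:
    """Directed path src ~> dst by DFS over adjacency sets."""
    if src == dst:
        return True
    stack = [src]
    seen = {src}
    while stack:
        v = stack.pop()
        for w in children[v]:
            if w == dst:
                return True
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return False


def _run_chain(cache: _ScoreCache, config: LearnerConfig,
               rng: np.random.Generator, n_keep: int) -> np.ndarray:
    """One MH chain over DAG space; returns (n_keep, n, n) samples."""
    n = cache.n_genes
    if n == 1:
        return np.zeros((n_keep, 1, 1), dtype=np.uint8)
    children: list[set[int]] = [set() for _ in range(n)]
    parents: list[set[int]] = [set() for _ in range(n)]
    fam = [cache.family(j, ()) for j in range(n)]

    def family_of(j: int) -> float:
        return cache.family(j, tuple(sorted(parents[j])))

    def mh_accept(delta: float, log_q: float) -> bool:
        log_a = delta + log_q
        if log_a >= 0:
            return True
        if log_a == NEG_INF:
            return False
        return rng.random() < math.exp(log_a)

    out = np.zeros((n_keep, n, n), dtype=np.uint8)
    kept = 0
    total_moves = config.burn_in + n_keep * config.thinning
    for step in range(total_moves):
        i = int(rng.integers(n))
        j = int(rng.integers(n - 1))
        if j >= i:
            j += 1
        has = j in children[i]
        if has:
            move = "delete" if rng.random() < 0.5 else "reverse"
        else:
            move = "add"
        ok = True
        if move == "add":
            ok = (len(parents[j]) < config.max_parents
                  and not _has_path(children, j, i))
            log_q = math.log(0.5)  # q(del)/q(add) = (1/2N2)/(1/N2)
        elif move == "delete":
            log_q = math.log(2.0)
        else:  # reverse i->j into j->i
            children[i].discard(j)
            parents[j].discard(i)
            ok = (len(parents[i]) < config.max_parents
                  and not _has_path(children, i, j))
            children[i].add(j)
            parents[j].add(i)
            log_q = 0.0
        if ok:
            if move == "add":
                old = fam[j]
                parents[j].add(i)
                new = family_of(j)
                delta = new - old
                parents[j].discard(i)
                if mh_accept(delta, log_q):
                    parents[j].add(i)
                    children[i].add(j)
                    fam[j] = new
            elif move == "delete":
                old = fam[j]
                parents[j].discard(i)
                new = family_of(j)
                delta = new - old
                parents[j].add(i)
                if mh_accept(delta, log_q):
                    parents[j].discard(i)
                    children[i].discard(j)
                    fam[j] = new
            else:
                old = fam[i] + fam[j]
                parents[j].discard(i)
                parents[i].add(j)
                new_i, new_j = family_of(i), family_of(j)
                delta = new_i + new_j - old
                parents[i].discard(j)
                parents[j].add(i)
                if mh_accept(delta, log_q):
                    parents[j].discard(i)
                    children[i].discard(j)
                    parents[i].add(j)
                    children[j].add(i)
                    fam[i], fam[j] = new_i, new_j
        pos = step - config.burn_in + 1
        if pos > 0 and pos % config.thinning == 0 and kept < n_keep:
            for a in range(n):
                for b in children[a]:
                    out[kept, a, b] = 1
            kept += 1
    return out


def mcmc_sample(data: ExpressionDataset,
                config: LearnerConfig | None = None) -> PosteriorSampleSet:
    """Structure MCMC posterior samples.

    ``config.n_chains`` independent chains start from the empty graph;
    each contributes ``n_samples / n_chains`` post-burn-in, thinned
    samples.  ``group_ids`` records the chain index, which downstream
    disagreement scores use as the ensemble grouping.
    """
    config = config or LearnerConfig()
    cache = _ScoreCache(data, config.score)
    per_chain = max(1, config.n_samples // config.n_chains)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    blocks = []
    groups = []
    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        blocks.append(_run_chain(cache, config, rng, per_chain))
        groups.extend([c] * per_chain)
    adj = np.concatenate(blocks)
    return PosteriorSampleSet(adj, group_ids=np.asarray(groups),
                              labels=data.gene_names, validate=False)


@dataclass
class MCMCSampler:
    """Structure-MCMC sampler behind the pluggable interface."""

    config: LearnerConfig = field(default_factory=LearnerConfig)

    def fit(self, data: ExpressionDataset) -> PosteriorSampleSet:
        return mcmc_sample(data, self.config)

    def reseeded(self, seed: int) -> "MCMCSampler":
        return MCMCSampler(replace(self.config, seed=seed))


@dataclass
class ExactSampler:
    """Exact enumeration sampler (n_genes <= 5); the small-n oracle."""

    config: LearnerConfig = field(default_factory=LearnerConfig)

    def fit(self, data: ExpressionDataset) -> PosteriorSampleSet:
        return exact_posterior(data, self.config)

    def reseeded(self, seed: int) -> "ExactSampler":
        return ExactSampler(replace(self.config, seed=seed))
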