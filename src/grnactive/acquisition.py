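"""Acquisition functions for selecting single-gene knockout experiments.

Observational expression data identifies a regulatory network only up to
its Markov equivalence class; knockouts resolve edge directions.  Given an
edge-state posterior, these functions score every gene pair by how much an
experiment could teach us, then roll pair scores up into per-gene knockout
scores: a gene ranks highly when it is a confident, probable parent of
genes whose incoming edges are uncertain, so knocking it out
disambiguates its children's edges.

Four pair-level scores are provided:

``edge_entropy``
    Shannon entropy of the 3-state distribution {i->j, i<-j, none}.
``bald``
    Bayesian Active Learning by Disagreement: entropy of the ensemble-mean
    distribution minus the mean ensemble-member entropy (a mutual
    information between the model and the would-be observation).
``eces`` / ``ebald``
    Equivalence-class variants working on the 4-state essential-graph
    distribution (fwd / rev / undirected / absent).  A Bernoulli mask U,
    drawn per pair from the undirected-state probability, switches each
    pair between a direction-only entropy (when the pair is likely an
    undirected essential-graph edge, only its orientation is in question)
    and the full four-state entropy.

All entropies are normalised by log(#states) so scores live in [0, 1] and
the (1 - score) certainty factor of the knockout score is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from .posterior import EdgeStateDistribution, PdagStateDistribution

__all__ = [
    "UndirectedMask",
    "AcquisitionResult",
    "edge_entropy",
    "direction_entropy",
    "four_state_entropy",
    "bald",
    "sample_undirected_mask",
    "eces",
    "ebald",
    "node_uncertainty",
    "knockout_scores",
    "select_interventions",
]

ACQUISITION_FUNCTIONS = ("uniform", "entropy", "bald", "eces", "ebald")


def _normalized_entropy(stack: np.ndarray) -> np.ndarray:
    """-sum p log2 p over axis 0, divided by log2(#states); 0 log 0 := 0."""
    states = stack.shape[0]
    h = -xlogy(stack, stack).sum(axis=0) / np.log(2.0)
    h = h / np.log2(states)
    np.fill_diagonal(h, 0.0)
    return np.clip(h, 0.0, 1.0)


def edge_entropy(d: EdgeStateDistribution) -> np.ndarray:
    """Normalised 3-state entropy per pair; symmetric, diagonal 0."""
    return _normalized_entropy(d.stacked())


def four_state_entropy(d: PdagStateDistribution) -> np.ndarray:
    """Normalised 4-state entropy per pair of the essential-graph states."""
    return _normalized_entropy(d.stacked())


def direction_entropy(d: PdagStateDistribution, *,
                      conditional: bool = True) -> np.ndarray:
    """Entropy of the edge-direction distribution per pair.

    With ``conditional=True`` (default) the fwd/rev probabilities are
    renormalised to condition on the pair being an oriented edge, giving
    the binary entropy of P(fwd | oriented); pairs with no oriented mass
    score 0.  With ``conditional=False`` the raw marginals enter the
    two-term entropy unnormalised (the literal two-term reading).
    """
    pf, pr = d.p_fwd, d.p_rev
    if conditional:
        tot = pf + pr
        with np.errstate(invalid="ignore", divide="ignore"):
            q = np.where(tot > 0, pf / np.where(tot > 0, tot, 1.0), 0.0)
        h = -(xlogy(q, q) + xlogy(1 - q, 1 - q)) / np.log(2.0)
        h = np.where(tot > 0, h, 0.0)
    else:
        h = -(xlogy(pf, pf) + xlogy(pr, pr)) / np.log(2.0)
    np.fill_diagonal(h, 0.0)
    return np.clip(h, 0.0, 1.0)


def _mean_edge_distribution(members: list[EdgeStateDistribution],
                            weights: np.ndarray | None) -> EdgeStateDistribution:
    w = _member_weights(len(members), weights)
    p_fwd = sum(wk * m.p_fwd for wk, m in zip(w, members))
    p_none = sum(wk * m.p_none for wk, m in zip(w, members))
    return EdgeStateDistribution(p_fwd, p_none)


def _mean_pdag_distribution(members: list[PdagStateDistribution],
                            weights: np.ndarray | None) -> PdagStateDistribution:
    w = _member_weights(len(members), weights)
    p_fwd = sum(wk * m.p_fwd for wk, m in zip(w, members))
    p_undir = sum(wk * m.p_undir for wk, m in zip(w, members))
    p_none = sum(wk * m.p_none for wk, m in zip(w, members))
    return PdagStateDistribution(p_fwd, p_undir, p_none)


def _member_weights(k: int, weights) -> np.ndarray:
    if k == 0:
        raise ValueError("member list may not be empty")
    if weights is None:
        return np.full(k, 1.0 / k)
    w = np.asarray(weights, dtype=float)
    if w.shape != (k,):
        raise ValueError("weights length must match member count")
    return w / w.sum()


def bald(members: list[EdgeStateDistribution],
         weights: np.ndarray | None = None) -> np.ndarray:
    """Disagreement score: H(mean member) - mean member H, clipped at 0.

    Zero when all members agree; bounded above by the entropy of the
    pooled distribution.
    """
    w = _member_weights(len(members), weights)
    pooled = edge_entropy(_mean_edge_distribution(members, weights))
    avg = sum(wk * edge_entropy(m) for wk, m in zip(w, members))
    return np.clip(pooled - avg, 0.0, None)


@dataclass(frozen=True)
class UndirectedMask:
    """Symmetric 0/1 mask; ``u[i, j] = 1`` marks a pair treated as an
    undirected essential-graph edge for this acquisition round."""

    u: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=np.uint8)
        if u.ndim != 2 or u.shape[0] != u.shape[1]:
            raise ValueError("mask must be square")
        if not np.array_equal(u, u.T):
            raise ValueError("mask must be symmetric")
        if np.any(np.diag(u) != 0):
            raise ValueError("mask diagonal must be zero")
        object.__setattr__(self, "u", u)

    @property
    def n_nodes(self) -> int:
        return self.u.shape[0]


def sample_undirected_mask(d: PdagStateDistribution,
                           seed: int | None = None) -> UndirectedMask:
    """Draw U_ij ~ Bernoulli(P(i - j)) per unordered pair, mirrored."""
    rng = np.random.default_rng(seed)
    n = d.n_nodes
    draws = rng.random((n, n))
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    u = np.zeros((n, n), dtype=np.uint8)
    u[upper] = (draws[upper] < d.p_undir[upper]).astype(np.uint8)
    u = u + u.T
    return UndirectedMask(u, seed=seed)


def eces(d: PdagStateDistribution, mask: UndirectedMask, *,
         conditional_direction: bool = True) -> np.ndarray:
    """Equivalence Class Entropy Sampling score per pair.

    ``ECES = H_dir * U + H_4 * (1 - U)``: masked pairs contribute their
    direction entropy, unmasked pairs the full four-state entropy.
    """
    if mask.n_nodes != d.n_nodes:
        raise ValueError("mask dimension mismatch")
    u = mask.u.astype(float)
    h_dir = direction_entropy(d, conditional=conditional_direction)
    h4 = four_state_entropy(d)
    return h_dir * u + h4 * (1.0 - u)


def ebald(members: list[PdagStateDistribution], mask: UndirectedMask,
          weights: np.ndarray | None = None, *,
          conditional_direction: bool = True) -> np.ndarray:
    """Equivalence-class BALD: per-branch disagreement blended by the mask.

    The direction-entropy disagreement fills masked pairs, the four-state
    disagreement the rest; each branch is clipped at 0 before blending.
    """
    if mask.n_nodes != members[0].n_nodes:
        raise ValueError("mask dimension mismatch")
    w = _member_weights(len(members), weights)
    pooled = _mean_pdag_distribution(members, weights)

    h_dir_pool = direction_entropy(pooled, conditional=conditional_direction)
    h_dir_avg = sum(wk * direction_entropy(m, conditional=conditional_direction)
                    for wk, m in zip(w, members))
    dir_term = np.clip(h_dir_pool - h_dir_avg, 0.0, None)

    h4_pool = four_state_entropy(pooled)
    h4_avg = sum(wk * four_state_entropy(m) for wk, m in zip(w, members))
    four_term = np.clip(h4_pool - h4_avg, 0.0, None)

    u = mask.u.astype(float)
    return dir_term * u + four_term * (1.0 - u)


def node_uncertainty(pair_scores: np.ndarray) -> np.ndarray:
    """Total incoming-pair uncertainty per gene: column sums of the scores.

    Genes with many high-entropy incident pairs are the ones whose incoming
    edges an experiment should pin down.
    """
    return np.asarray(pair_scores, dtype=float).sum(axis=0)


def knockout_scores(pair_scores: np.ndarray, d) -> np.ndarray:
    """Per-gene knockout informativeness.

    ``score[i] = sum_j (1 - S[i, j]) * P(i -> j) * u[j]`` with ``u`` the
    node uncertainty vector: gene i is a good knockout target when it is a
    certain (low pair score), probable (high P(i -> j)) parent of genes j
    whose incident pairs are otherwise uncertain.  ``d`` supplies
    ``p_fwd`` and may be either the 3- or 4-state distribution.
    """
    s = np.asarray(pair_scores, dtype=float)
    p_fwd = np.asarray(d.p_fwd, dtype=float)
    if s.shape != p_fwd.shape:
        raise ValueError("pair score / distribution dimension mismatch")
    u = node_uncertainty(s)
    return ((1.0 - s) * p_fwd * u[None, :]).sum(axis=1)


def select_interventions(node_scores: np.ndarray, k: int,
                         rng: np.random.Generator | None = None,
                         mode: str = "argmax",
                         exclude: set[int] | None = None) -> list[int]:
    """Choose ``k`` knockout targets.

    ``argmax`` takes the k highest-scoring genes, ties broken by smallest
    index; ``uniform`` draws k genes uniformly without replacement using
    ``rng``.  ``exclude`` removes genes (e.g. already-intervened ones) from
    eligibility.
    """
    scores = np.asarray(node_scores, dtype=float)
    eligible = np.arange(scores.shape[0])
    if exclude:
        eligible = np.array([g for g in eligible if g not in exclude])
    if k < 1 or k > eligible.shape[0]:
        raise ValueError("k must be in [1, number of eligible genes]")
    if mode == "argmax":
        order = np.argsort(-scores[eligible], kind="stable")
        return eligible[order[:k]].tolist()
    if mode == "uniform":
        if rng is None:
            raise ValueError("uniform selection requires an rng")
        return rng.choice(eligible, size=k, replace=False).tolist()
    raise ValueError(f"unknown selection mode {mode!r}")


@dataclass
class AcquisitionResult:
    """One acquisition round: pair scores, gene scores, chosen knockouts."""

    function_name: str
    pair_scores: np.ndarray
    node_scores: np.ndarray
    selected: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.function_name not in ACQUISITION_FUNCTIONS:
            raise ValueError(f"unknown acquisition {self.function_name!r}")
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected genes must be unique")

    def to_dict(self) -> dict:
        return {
            "function": self.function_name,
            "selected": list(map(int, self.selected)),
            "node_scores": np.asarray(self.node_scores).tolist(),
        }
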