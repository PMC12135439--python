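"""The active-learning loop: pretrain, score, knock out, retrain.

One experiment: fit the structure learner on observational data, then for
each round compute the configured acquisition from the current posterior,
select a batch of knockout targets, fetch their simulated experiment
series from the environment, append them to the training set, refit, and
evaluate.  The loop stops at the round budget or when a monitored metric
crosses a threshold.  Every round is logged as a JSON-serialisable record
so learning curves can be reconstructed from the log alone.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from . import acquisition as acq
from .datasets import ExpressionDataset
from .evaluation import PosteriorMetrics, evaluate_posterior
from .graphs import DirectedGraph, PartiallyDirectedGraph
from .learner import LearnerConfig, MCMCSampler
from .posterior import (PosteriorSampleSet, edge_state_distribution,
                        ensemble_marginals, member_weights,
                        pdag_state_distribution)
from .simulator import gnw_scale_fixture

__all__ = [
    "LoopConfig",
    "RoundRecord",
    "KnockoutEnvironment",
    "run_active_loop",
    "acquire",
]


@dataclass(frozen=True)
class LoopConfig:
    """Experiment settings for one active-learning run.

    acquisition
        One of uniform / entropy / bald / eces / ebald.
    batch_size
        Knockout genes acquired per round (each contributes its full
        simulated series).
    stop_on_metric
        Optional ``(metric_name, threshold)``; the loop stops once the
        post-retraining value drops to or below the threshold.
    allow_repeats
        Whether already-knocked-out genes stay eligible in later rounds
        (a fresh replicate series is still informative).
    """

    acquisition: str = "entropy"
    batch_size: int = 1
    max_rounds: int = 5
    learner: LearnerConfig = field(default_factory=LearnerConfig)
    seed: int = 0
    stop_on_metric: tuple[str, float] | None = None
    allow_repeats: bool = True

    def __post_init__(self) -> None:
        if self.acquisition not in acq.ACQUISITION_FUNCTIONS:
            raise ValueError(f"unknown acquisition {self.acquisition!r}")
        if self.batch_size < 1 or self.max_rounds < 1:
            raise ValueError("batch_size and max_rounds must be >= 1")

    @classmethod
    def from_dict(cls, d: Mapping) -> "LoopConfig":
        d = dict(d)
        if "learner" in d and isinstance(d["learner"], Mapping):
            d["learner"] = LearnerConfig(**d["learner"])
        if d.get("stop_on_metric") is not None:
            name, thr = d["stop_on_metric"]
            d["stop_on_metric"] = (str(name), float(thr))
        return cls(**d)


@dataclass
class RoundRecord:
    """Audit record of one loop round."""

    round_index: int
    selected: list[int]
    node_scores: list[float]
    metrics_before: PosteriorMetrics | None
    metrics_after: PosteriorMetrics | None
    n_interventional: int
    elapsed_s: float

    def to_dict(self) -> dict:
        return {
            "round": self.round_index,
            "selected": list(map(int, self.selected)),
            "node_scores": [float(v) for v in self.node_scores],
            "metrics_before": None if self.metrics_before is None
            else self.metrics_before.to_dict(),
            "metrics_after": None if self.metrics_after is None
            else self.metrics_after.to_dict(),
            "n_interventional": int(self.n_interventional),
            "elapsed_s": float(self.elapsed_s),
        }


class KnockoutEnvironment:
    """Observational data plus a pool of pre-simulated knockout series.

    The loop's oracle: ``knockout(g)`` returns the experiment series for
    gene ``g`` and raises ``KeyError`` for genes without one.
    """

    def __init__(self, observational: ExpressionDataset,
                 knockout_pool: Mapping[int, ExpressionDataset],
                 truth: DirectedGraph | None = None,
                 reference_pdag: PartiallyDirectedGraph | None = None):
        self.observational = observational
        self.knockout_pool = dict(knockout_pool)
        self.truth = truth
        self.reference_pdag = reference_pdag

    @classmethod
    def gnw_scale(cls, seed: int = 0, **kw) -> "KnockoutEnvironment":
        truth, ref, obs, pool = gnw_scale_fixture(seed, **kw)
        from .graphs import repair_to_dag
        dag, _ = repair_to_dag(truth)
        return cls(obs, pool, truth=dag, reference_pdag=ref)

    @property
    def n_genes(self) -> int:
        return self.observational.n_genes

    def knockout(self, gene: int) -> ExpressionDataset:
        if gene not in self.knockout_pool:
            raise KeyError(f"no knockout experiment available for gene {gene}")
        return self.knockout_pool[gene]


def acquire(samples: PosteriorSampleSet, function: str, k: int, *,
            rng: np.random.Generator | None = None,
            mask_seed: int | None = None, n_groups: int = 8,
            exclude: set[int] | None = None) -> acq.AcquisitionResult:
    """Score the posterior with one acquisition function and pick ``k`` genes.

    Entropy and BALD work on the 3-state DAG-space distribution; ECES and
    EBALD on the 4-state essential-graph distribution with a fresh
    undirectedness mask drawn from ``mask_seed``; uniform ignores the
    posterior entirely.
    """
    n = samples.n_nodes
    if function == "uniform":
        node = np.zeros(n)
        pair = np.zeros((n, n))
        selected = acq.select_interventions(node, k, rng=rng, mode="uniform",
                                            exclude=exclude)
        return acq.AcquisitionResult("uniform", pair, node, selected)
    if function == "entropy":
        dist = edge_state_distribution(samples)
        pair = acq.edge_entropy(dist)
    elif function == "bald":
        members = ensemble_marginals(samples, n_groups, kind="dag")
        w = member_weights(samples, n_groups)
        pair = acq.bald(members, w)
        dist = edge_state_distribution(samples)
    elif function == "eces":
        dist = pdag_state_distribution(samples)
        mask = acq.sample_undirected_mask(dist, seed=mask_seed)
        pair = acq.eces(dist, mask)
    elif function == "ebald":
        members = ensemble_marginals(samples, n_groups, kind="pdag")
        w = member_weights(samples, n_groups)
        dist = pdag_state_distribution(samples)
        mask = acq.sample_undirected_mask(dist, seed=mask_seed)
        pair = acq.ebald(members, mask, w)
    else:
        raise ValueError(f"unknown acquisition {function!r}")
    node = acq.knockout_scores(pair, dist)
    selected = acq.select_interventions(node, k, mode="argmax",
                                        exclude=exclude)
    return acq.AcquisitionResult(function, pair, node, selected)


def run_active_loop(env: KnockoutEnvironment, config: LoopConfig,
                    sampler=None) -> list[RoundRecord]:
    """Run the full pretrain -> acquire -> intervene -> retrain cycle.

    ``sampler`` defaults to structure MCMC with ``config.learner``; any
    object with ``fit(data) -> PosteriorSampleSet`` and
    ``reseeded(seed)`` works.  Metrics are attached whenever the
    environment knows its ground truth.  Fully reproducible given
    ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    fit_ss, round_ss = ss.spawn(2)
    fit_seeds = [int(c.generate_state(1)[0] % (2 ** 31))
                 for c in fit_ss.spawn(config.max_rounds + 1)]
    round_seeds = [int(c.generate_state(1)[0] % (2 ** 31))
                   for c in round_ss.spawn(config.max_rounds + 1)]

    if sampler is None:
        sampler = MCMCSampler(replace(config.learner, seed=fit_seeds[0]))

    def metrics(s: PosteriorSampleSet) -> PosteriorMetrics | None:
        if env.truth is None:
            return None
        return evaluate_posterior(s, env.truth, env.reference_pdag)

    data = env.observational
    t0 = time.perf_counter()
    samples = sampler.reseeded(fit_seeds[0]).fit(data)
    records = [RoundRecord(0, [], [], None, metrics(samples),
                           data.n_interventional,
                           time.perf_counter() - t0)]
    seen: set[int] = set()
    for r in range(1, config.max_rounds + 1):
        t0 = time.perf_counter()
        rng = np.random.default_rng(round_seeds[r])
        result = acquire(samples, config.acquisition, config.batch_size,
                         rng=rng, mask_seed=round_seeds[r],
                         n_groups=config.learner.n_chains,
                         exclude=None if config.allow_repeats else set(seen))
        before = metrics(samples)
        parts = [data] + [env.knockout(g) for g in result.selected]
        data = ExpressionDataset.concat(parts)
        seen.update(result.selected)
        samples = sampler.reseeded(fit_seeds[r]).fit(data)
        after = metrics(samples)
        records.append(RoundRecord(r, result.selected,
                                   np.asarray(result.node_scores).tolist(),
                                   before, after, data.n_interventional,
                                   time.perf_counter() - t0))
        if config.stop_on_metric is not None and after is not None:
            name, thr = config.stop_on_metric
            if after.to_dict()[name] <= thr:
                break
    return records


def write_round_log(records: list[RoundRecord], path: str | Path) -> None:
    """One JSON record per line, one line per round."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_dict()) + "\n")


def plot_trajectories(records: list[RoundRecord], path: str | Path,
                      metrics: tuple[str, ...] = ("shd_directed", "nnz")) -> None:
    """Line plots of post-retraining metrics across rounds."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rounds = [r.round_index for r in records if r.metrics_after is not None]
    fig, axes = plt.subplots(1, len(metrics), figsize=(4 * len(metrics), 3))
    if len(metrics) == 1:
        axes = [axes]
    for ax, name in zip(axes, metrics):
        vals = [r.metrics_after.to_dict()[name] for r in records
                if r.metrics_after is not None]
        ax.plot(rounds, vals, marker="o")
        ax.set_xlabel("round")
        ax.set_ylabel(name)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
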