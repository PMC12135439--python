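# Methods

## Problem setting

A gene regulatory network is modelled as a directed acyclic graph over
genes; expression data are draws from a distribution that factorises over
the graph.  From observational data alone the structure is identifiable
only up to its Markov equivalence class, represented by the essential
graph (CPDAG): edges compelled by v-structures and their Meek-rule
consequences are directed, the rest undirected.  A single-gene knockout is
modelled as a perfect intervention — the target's expression is clamped
(default 0) and its incoming mechanism severed — and is what resolves the
remaining edge directions.  The package's task is sequential experiment
design: given a posterior over structures, choose the knockouts that
resolve the most uncertainty per experiment.

## Edge-state posteriors

Samplers emit hard DAGs.  For each unordered gene pair the weighted sample
frequencies give a three-state distribution (forward, reverse, no edge);
mapping every sample through its CPDAG first gives the four-state
essential-graph distribution (forward, reverse, undirected, absent).
CPDAG conversion is memoised on the graph because sample sets repeat
graphs heavily.

Disagreement-based scores need an ensemble of probability-bearing
members, but hard DAGs individually carry zero entropy, which would
collapse the mutual-information score to plain entropy.  Members are
therefore **groups of samples** — the MCMC chains by default (or
contiguous blocks when no chain labels exist) — whose within-group
frequencies are the member's edge probabilities.  The group count equals
`LearnerConfig.n_chains` (default 8).  The weighted mean of member
distributions equals the pooled distribution exactly, which the tests
assert to 1e-12.

## Acquisition functions

All entropies use base-2 logs, 0·log 0 := 0, and are normalised by
log(#states) so every score lies in [0, 1]; this makes the
(1 − score) certainty factor below meaningful for 3- and 4-state
entropies alike.

- Edge Entropy: normalised 3-state entropy per pair.
- BALD: H(pooled) − mean member H, clipped at 0 (finite-sample noise can
  push the difference marginally negative).  Bounded by the pooled
  entropy; zero when members agree.
- Direction entropy: binary entropy of P(forward | edge oriented), i.e.
  the forward/reverse masses are renormalised to condition on an oriented
  edge; pairs with no oriented mass score 0.  The literal unnormalised
  two-term reading is available via `conditional=False`.
- ECES: a Bernoulli mask U_ij ~ P(undirected) is drawn per pair and
  mirrored; masked pairs contribute direction entropy, unmasked pairs the
  full four-state entropy.  The non-undirected branch uses the four-state
  entropy because the score is defined in essential-graph space.  The mask
  is redrawn each acquisition round from a round-derived seed.
- EBALD: the same blend applied to the two disagreement terms, each
  clipped at 0 before blending.

Per-gene knockout scores are
`score[i] = Σ_j (1 − S_ij) · P(i→j) · u[j]` with `u` the per-gene column
sums of the pair scores: a knockout target should be a confident,
probable parent of genes whose incident pairs are uncertain.  Batch
selection is top-k with smallest-index tie-breaks; the uniform baseline
draws without replacement from a seeded generator.  Already-knocked-out
genes stay eligible by default (a fresh replicate series is still
informative); `LoopConfig.allow_repeats=False` excludes them.

## Reference samplers

The decomposable family score is Gaussian BIC by default: the maximised
log-likelihood of the node's linear regression on its parents minus
(k/2)·log n with k = |parents| + 2 (coefficients, intercept, variance).
The BGe marginal likelihood is available (`score="bge"`; alpha_mu = 1,
alpha_w = n + 2, prior scale t·I with the standard t, prior mean at the
sample mean).  Both are score equivalent on observational data — the test
suite asserts exact ties across Markov-equivalent DAGs — so the posterior
spreads over equivalence classes until interventions arrive.

Interventions enter through the truncated factorisation: samples that
intervene on a node are dropped from that node's own family score, while
the clamped value still predicts its children.  A family with fewer
usable rows than parameters scores −inf; a node intervened in every
sample contributes 0.  Structure priors are uniform.

`exact_posterior` enumerates every DAG (25 for three genes, 543 for four,
29,281 for five) and softmax-normalises the total scores; it is the oracle
the stochastic sampler is validated against, and the learner used in the
small identifiability tests.

`mcmc_sample` is Metropolis–Hastings over DAG space with add / delete /
reverse single-edge proposals, acyclicity and fan-in (`max_parents`,
default 4) constraints, and exact Hastings ratios for the asymmetric
proposal (delete and reverse share a coin flip when the picked pair holds
an edge).  Family scores are memoised per (node, parent set).  Chains
start from the empty graph.  Under a constant score the sampler's visit
frequencies over all 3-node DAGs are uniform within Monte-Carlo error
(detailed-balance smoke test); with data, edge marginals agree with exact
enumeration within total variation 0.05 at the tested schedules.  Thinning
matters at small n: at 4 genes a thinning of 5 with 5,000 burn-in steps
keeps the worst-pair total variation near 0.02, while a thinning of 2
leaves autocorrelation close to the 0.05 bound.

## Synthetic data generator

The generator replaces kinetic ODE simulators with a linear-Gaussian SEM
on the acyclic repair of a sparse random reference network.  What it
emulates: sparse connectivity; perturbation time series (each series
draws one per-gene offset, N(0, offset_sd²), shared by its time points);
knockout series with the target clamped and its mechanism severed; the
benchmark data shape (64 genes, 207 edges of which 21 close feedback
cycles, 10×21 observational samples, 64 single-knockout series of 21
samples).  What it does not: saturating kinetics, mRNA/protein layering,
autocorrelated within-series dynamics (time points are i.i.d. given the
series offset), measurement-specific noise models.  Passing tests
therefore demonstrate the statistical mechanism — MEC recovery from
observational data, orientation from knockouts — not performance on real
transcriptomes.

Parameter defaults and why:

- Edge weights uniform on ±[0.5, 1.5]: bounded away from 0 so no edge is
  near-unidentifiable.
- Noise sd 1, baselines 0.
- `offset_sd = 0.25`.  The offsets are per-series constants, so a study
  contributes only `n_series` independent draws of each; large offsets act
  as batch effects whose chance correlations (at 10 series) make spurious
  edges genuinely score-optimal — with offset_sd = 1 a 43-edge graph
  outscored the 20-edge truth on a 15-gene study regardless of sampler
  effort.  At 0.25 the perturbation mechanism is retained while the true
  graph remains score-optimal, preserving the generator's stated purpose.
- Feedback edges are reversals of distinct forward edges, so each closes
  at least one cycle (two-gene mutual regulation, common in curated
  networks).  Draws whose greedy repair would not remove exactly the
  feedback count are rejected and redrawn deterministically, so the
  documented reference-network shape (repair removes exactly 21 edges at
  benchmark scale) holds for every seed.

## Graph algorithms

- CPDAG conversion orients v-structures, then applies Meek rules R1–R4 to
  a fixpoint.  Correctness is checked exhaustively against an independent
  d-separation oracle (CI-signature grouping of all DAGs on up to four
  nodes) and by randomized soundness tests for the closure under
  background orientations.
- DAG repair removes, at each step, the edge whose deletion most shrinks
  the cyclic core (the edges internal to nontrivial strongly connected
  components), ties to the lexicographically smallest pair.  This greedy
  is deterministic and polynomial; per-edge simple-cycle counts were
  rejected because cycle enumeration is exponential in the number of
  interacting feedback edges and became infeasible at benchmark scale.
- Directed SHD charges a reversed edge 1 (one wrong pair state), matching
  the edge-operation reading; `reversal_cost=2` gives the
  delete-plus-insert convention.  Undirected SHD compares skeletons; PDAG
  SHD compares the four pair states.

## Active-learning loop and benchmark

Round 0 fits on observational data only.  Each round scores the current
posterior with the configured acquisition (entropy/BALD on the 3-state
distribution, ECES/EBALD on the 4-state one, uniform ignoring it),
acquires the selected genes' full 21-sample knockout series, refits, and
logs metrics before and after retraining, so learning curves come from
the log alone.  All randomness (fits, masks, uniform draws) derives from
the loop seed via seed-sequence spawning.

The paired-seed benchmark compares acquisitions on identical environments
(same truth, data, knockout pool, learner schedule), so differences
reflect experiment selection only.  Desk-scale defaults: 15 genes, 20
edges, 10 replicates, 5 rounds of batch 1, MCMC with 8 chains, 12,000
burn-in moves and 400 retained samples per fit — sized so the full sweep
runs in minutes on one CPU while the knockout-information effect remains
visible.  Expected directed SHD is the headline metric; under these
conditions the entropy and BALD medians fall below the uniform baseline's
median.

## Evaluation conventions

Directed and skeleton SHD are computed against the acyclic repair of the
reference network; PDAG SHD against its Meek-completed essential graph.
Recall counts orientation-correct true edges; because the undefined
looser reading is also common, a skeleton recall is logged alongside.
All metrics are posterior expectations (weighted means over samples).

## Known limitations

- The linear-Gaussian likelihood cannot express saturating or
  multiplicative regulation; discretised-data scores (multinomial) are
  not implemented.
- Structure MCMC with single-edge moves mixes slowly on larger gene sets;
  at 15 genes the posterior retains extra edges (NNZ above truth) even
  with interventional data.  The sampler interface is pluggable so
  stronger samplers can be swapped in.
- BALD-style scores depend on the chain grouping; with few chains the
  disagreement estimate is coarse.
- Interventional essential graphs (I-CPDAGs) are out of scope; the PDAG
  machinery covers observational equivalence classes only.
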