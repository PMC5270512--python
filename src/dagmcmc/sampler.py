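"""Metropolis-Hastings chain over DAG structures.

Each step proposes a multi-step transition, scores the endpoint through the
family cache, and accepts with probability

    min{1, exp(dlog P(D|G) + dlog P(G) + log q(G)/q(G'))}

where the last term is the telescoped Hastings ratio of the mixture
proposal.  Rejected proposals repeat the current state in the retained
sample (standard MH accounting).  Chains are deterministic given their seed;
ensembles of chains with random restarts are the unit the convergence
diagnostics operate on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .dag import DagStructure
from .proposal import (
    NeighborhoodCache,
    ProposalSpec,
    TransitionWalk,
    hastings_log_ratio,
    sample_transition,
)
from .scoring import BDeuScorer, DiscreteDataset, ScoreSettings


@dataclass
class ChainConfig:
    """Run protocol of a single chain.

    ``initial_dag`` may be a :class:`DagStructure`, the string ``"empty"``,
    or the string ``"random"`` (uniform topological order, each admissible
    edge included with probability 0.5 subject to the fan-in cap).
    """

    proposal: ProposalSpec
    burn_in: int = 0
    sample_size: int = 1
    thin: int = 1
    seed: int = 0
    initial_dag: Union[DagStructure, str] = "empty"
    score: ScoreSettings = field(default_factory=ScoreSettings)

    def __post_init__(self) -> None:
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if isinstance(self.initial_dag, str) and self.initial_dag not in (
            "empty",
            "random",
        ):
            raise ValueError("initial_dag must be a DagStructure, 'empty' or 'random'")


@dataclass
class ChainSample:
    """Retained states of one chain with acceptance bookkeeping.

    ``dags[i]`` is the i-th retained structure and ``log_scores[i]`` its
    log P(D|G); ``acceptance_count[t]`` / ``proposal_count[t]`` tally moves
    by transition length.
    """

    dags: list[DagStructure]
    log_scores: np.ndarray
    acceptance_count: dict[int, int]
    proposal_count: dict[int, int]
    config: ChainConfig

    def __post_init__(self) -> None:
        if len(self.dags) != len(self.log_scores):
            raise ValueError("dags and log_scores length mismatch")

    def __len__(self) -> int:
        return len(self.dags)

    @property
    def acceptance_rate(self) -> float:
        total = sum(self.proposal_count.values())
        return sum(self.acceptance_count.values()) / total if total else math.nan

    def acceptance_rates_by_length(self) -> dict[int, float]:
        return {
            t: self.acceptance_count.get(t, 0) / c
            for t, c in sorted(self.proposal_count.items())
            if c > 0
        }


def random_dag_uniform_order(
    n: int, rng: np.random.Generator, max_fanin: Optional[int] = None,
    edge_prob: float = 0.5,
) -> DagStructure:
    """Random DAG: uniform topological order, then independent edge
    inclusion subject to the fan-in cap."""
    order = rng.permutation(n)
    adj = np.zeros((n, n), dtype=bool)
    indeg = np.zeros(n, dtype=int)
    for j in range(1, n):
        v = order[j]
        for i in range(j):
            u = order[i]
            if max_fanin is not None and indeg[v] >= max_fanin:
                break
            if rng.random() < edge_prob:
                adj[u, v] = True
                indeg[v] += 1
    return DagStructure._from_adj(adj)


class _MHState:
    __slots__ = ("dag", "log_score")

    def __init__(self, dag: DagStructure, log_score: float):
        self.dag = dag
        self.log_score = log_score


def mh_step(
    state: _MHState,
    scorer: BDeuScorer,
    spec: ProposalSpec,
    rng: np.random.Generator,
    cache: Optional[NeighborhoodCache] = None,
    hastings: bool = True,
) -> tuple[_MHState, bool, int]:
    """One Metropolis-Hastings step.  Returns (state, accepted, walk length).

    ``hastings=False`` replaces the proposal-asymmetry correction with 1 —
    a deliberately broken variant used as a negative control in tests; it
    converges to a distribution tilted by the neighborhood sizes.
    """
    if cache is None:
        cache = NeighborhoodCache(spec.max_fanin)
    walk = sample_transition(state.dag, spec, rng, cache)
    t = walk.length
    if walk.end == state.dag:
        return state, True, t  # identity proposal: ratio is exactly 1
    new_score = scorer.graph_log_score(walk.end)
    log_alpha = new_score - state.log_score
    settings = scorer.settings
    if settings.log_structure_prior is not None:
        log_alpha += settings.log_prior(walk.end) - settings.log_prior(state.dag)
    if hastings:
        q_end = cache.size(walk.end)
        log_alpha += hastings_log_ratio(walk.q_start, q_end)
    if log_alpha >= 0 or rng.random() < math.exp(log_alpha):
        return _MHState(walk.end, new_score), True, t
    return state, False, t


def run_chain(
    config: ChainConfig,
    dataset: DiscreteDataset,
    scorer: Optional[BDeuScorer] = None,
    hastings: bool = True,
) -> ChainSample:
    """Run one chain: ``burn_in`` discarded steps, then ``sample_size``
    retained states keeping every ``thin``-th post-burn-in state."""
    rng = np.random.default_rng(config.seed)
    if scorer is None:
        scorer = BDeuScorer(dataset, config.score)
    spec = config.proposal
    n = dataset.n_variables
    if isinstance(config.initial_dag, DagStructure):
        dag = config.initial_dag
        if dag.n_nodes != n:
            raise ValueError("initial DAG node count does not match dataset")
    elif config.initial_dag == "random":
        dag = random_dag_uniform_order(n, rng, spec.max_fanin)
    else:
        dag = DagStructure(n)
    state = _MHState(dag, scorer.graph_log_score(dag))
    cache = NeighborhoodCache(spec.max_fanin)
    accept: dict[int, int] = {}
    propose: dict[int, int] = {}

    for _ in range(config.burn_in):
        state, acc, t = mh_step(state, scorer, spec, rng, cache, hastings)
        propose[t] = propose.get(t, 0) + 1
        if acc:
            accept[t] = accept.get(t, 0) + 1

    dags: list[DagStructure] = []
    scores = np.empty(config.sample_size)
    kept = 0
    step = 0
    while kept < config.sample_size:
        state, acc, t = mh_step(state, scorer, spec, rng, cache, hastings)
        propose[t] = propose.get(t, 0) + 1
        if acc:
            accept[t] = accept.get(t, 0) + 1
        step += 1
        if step % config.thin == 0:
            dags.append(state.dag)
            scores[kept] = state.log_score
            kept += 1
    return ChainSample(dags, scores, accept, propose, config)


def run_chain_ensemble(
    configs: Sequence[ChainConfig],
    dataset: DiscreteDataset,
    hastings: bool = True,
) -> list[ChainSample]:
    """Run independent chains (shared scorer cache, independent seeds)."""
    if len(configs) < 1:
        raise ValueError("need at least one chain config")
    seeds = [c.seed for c in configs]
    if len(set(seeds)) != len(seeds):
        warnings.warn("duplicate seeds across chains: trajectories will coincide")
    scorer = None
    samples = []
    for cfg in configs:
        if scorer is None or cfg.score is not configs[0].score:
            scorer = BDeuScorer(dataset, cfg.score)
        samples.append(run_chain(cfg, dataset, scorer, hastings))
    return samples


def pool_samples(samples: Sequence[ChainSample]) -> ChainSample:
    """Concatenate retained states of several chains into one sample."""
    if not samples:
        raise ValueError("nothing to pool")
    dags: list[DagStructure] = []
    scores = []
    accept: dict[int, int] = {}
    propose: dict[int, int] = {}
    for s in samples:
        dags.extend(s.dags)
        scores.append(s.log_scores)
        for t, c in s.acceptance_count.items():
            accept[t] = accept.get(t, 0) + c
        for t, c in s.proposal_count.items():
            propose[t] = propose.get(t, 0) + c
    return ChainSample(dags, np.concatenate(scores), accept, propose, samples[0].config)
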