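"""Exact posterior over all DAGs for small node counts.

The number of DAGs grows superexponentially (1, 3, 25, 543, 29281, ... for
n = 1..6), so exhaustive evaluation is only feasible for n <= 6; beyond that
sampling is the only option.  Within that range this module is the ground
truth the sampler is validated against: enumerate every structure, score it,
normalize by log-sum-exp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .dag import DagStructure
from .scoring import BDeuScorer, DiscreteDataset, ScoreSettings

MAX_EXACT_NODES = 6


@dataclass
class DagDistribution:
    """A complete list of DAGs with unnormalized log posterior weights."""

    dags: list[DagStructure]
    log_weights: np.ndarray

    def __post_init__(self) -> None:
        self.log_weights = np.asarray(self.log_weights, dtype=float)
        if len(self.dags) != len(self.log_weights):
            raise ValueError("dags / log_weights length mismatch")

    @property
    def probabilities(self) -> np.ndarray:
        logp = self.log_weights - logsumexp(self.log_weights)
        return np.exp(logp)

    def probability_of(self, dag: DagStructure) -> float:
        probs = self.probabilities
        for i, g in enumerate(self.dags):
            if g == dag:
                return float(probs[i])
        return 0.0

    def as_index(self) -> dict[DagStructure, int]:
        return {g: i for i, g in enumerate(self.dags)}


def enumerate_dags(n: int, max_fanin: Optional[int] = None) -> list[DagStructure]:
    """Every DAG on ``n`` nodes (each exactly once), optionally restricted to
    in-degree <= ``max_fanin``.

    Enumeration assigns each unordered node pair one of three states (no
    edge, u->v, v->u) depth-first, pruning cycles and fan-in violations as
    edges are placed, so each DAG is produced exactly once without
    deduplication.  Refuses n > 6.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > MAX_EXACT_NODES:
        raise ValueError(
            f"exact enumeration is limited to n <= {MAX_EXACT_NODES}; "
            f"got n = {n} (the DAG count grows superexponentially)"
        )
    pairs = [(u, v) for u in range(n) for v in range(u + 1, n)]
    adj = np.zeros((n, n), dtype=bool)
    indeg = np.zeros(n, dtype=int)
    out: list[DagStructure] = []

    # adjacency sets for a fast "does b reach a" check
    children: list[set[int]] = [set() for _ in range(n)]

    def reaches(a: int, b: int) -> bool:
        stack = [a]
        seen = {a}
        while stack:
            x = stack.pop()
            if x == b:
                return True
            for y in children[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return False

    def place(i: int) -> None:
        if i == len(pairs):
            out.append(DagStructure._from_adj(adj.copy()))
            return
        u, v = pairs[i]
        place(i + 1)  # no edge
        for a, b in ((u, v), (v, u)):  # a -> b
            if max_fanin is not None and indeg[b] >= max_fanin:
                continue
            if reaches(b, a):
                continue
            adj[a, b] = True
            indeg[b] += 1
            children[a].add(b)
            place(i + 1)
            adj[a, b] = False
            indeg[b] -= 1
            children[a].remove(b)

    place(0)
    return out


def exact_posterior(
    dataset: DiscreteDataset,
    settings: Optional[ScoreSettings] = None,
    max_fanin: Optional[int] = None,
) -> DagDistribution:
    """P(G|D) by direct enumeration: score every DAG, add the log structure
    prior, normalize by log-sum-exp."""
    n = dataset.n_variables
    dags = enumerate_dags(n, max_fanin)
    scorer = BDeuScorer(dataset, settings)
    weights = np.array(
        [scorer.graph_log_score(g) + scorer.settings.log_prior(g) for g in dags]
    )
    return DagDistribution(dags, weights)


def exact_edge_posteriors(distribution: DagDistribution) -> np.ndarray:
    """Entry (u, v): total posterior probability of DAGs containing u->v."""
    if not distribution.dags:
        raise ValueError("empty distribution")
    n = distribution.dags[0].n_nodes
    probs = distribution.probabilities
    out = np.zeros((n, n))
    for g, p in zip(distribution.dags, probs):
        out += p * g.adjacency
    np.fill_diagonal(out, 0.0)
    return out
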