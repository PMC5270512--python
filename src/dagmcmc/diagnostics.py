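"""Convergence diagnostics and sample characterization.

The workhorse statistic is the edge posterior matrix: the fraction of
retained DAGs containing each directed edge, a Monte-Carlo estimate of
P(edge | D).  Agreement of these matrices across independent chains is the
field's standard (necessary, not sufficient) convergence indicator; the
pairwise sum of squared differences (SSD) quantifies it.  Score traces,
unique-DAG counts, MAP and consensus graphs, and per-neighbor acceptance
maps characterize what a chain actually sampled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .dag import DagStructure, EdgeMove, enumerate_neighborhood
from .proposal import ProposalSpec, hastings_log_ratio
from .sampler import ChainSample
from .scoring import BDeuScorer, DiscreteDataset, ScoreSettings
from .dag import neighborhood_size


@dataclass
class EdgePosteriorMatrix:
    """n x n matrix of directed-edge posterior probabilities (diagonal 0)."""

    values: np.ndarray
    n_samples: int = 0
    chain_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("edge posterior matrix must be square")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("edge posteriors must lie in [0, 1]")
        if np.any(np.diagonal(self.values) != 0):
            raise ValueError("diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def edge_posteriors(sample: ChainSample | Sequence[DagStructure]) -> EdgePosteriorMatrix:
    """Fraction of retained DAGs containing each directed edge."""
    dags = sample.dags if isinstance(sample, ChainSample) else list(sample)
    if not dags:
        raise ValueError("empty sample")
    n = dags[0].n_nodes
    acc = np.zeros((n, n))
    # identical structures repeat heavily in MH output; count by identity
    counts: dict[bytes, tuple[np.ndarray, int]] = {}
    for g in dags:
        entry = counts.get(g._key)
        counts[g._key] = (g.adjacency, entry[1] + 1 if entry else 1)
    for adj, c in counts.values():
        acc += c * adj
    acc /= len(dags)
    np.fill_diagonal(acc, 0.0)
    return EdgePosteriorMatrix(acc, n_samples=len(dags))


def edge_posterior_ssd(
    a: EdgePosteriorMatrix | np.ndarray, b: EdgePosteriorMatrix | np.ndarray
) -> float:
    """Sum of squared differences over all ordered node pairs."""
    av = a.values if isinstance(a, EdgePosteriorMatrix) else np.asarray(a)
    bv = b.values if isinstance(b, EdgePosteriorMatrix) else np.asarray(b)
    if av.shape != bv.shape:
        raise ValueError("shape mismatch")
    return float(np.sum((av - bv) ** 2))


def pairwise_ssd_matrix(samples: Sequence[ChainSample]) -> np.ndarray:
    mats = [edge_posteriors(s) for s in samples]
    k = len(mats)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = edge_posterior_ssd(mats[i], mats[j])
    return out


def best_converged_pair(
    samples: Sequence[ChainSample],
) -> tuple[tuple[int, int], float]:
    """The unordered chain pair with the lowest edge-posterior SSD
    (ties broken toward the lowest indices)."""
    if len(samples) < 2:
        raise ValueError("need at least two chains to compare")
    mats = [edge_posteriors(s) for s in samples]
    best: Optional[tuple[int, int]] = None
    best_val = math.inf
    for i in range(len(mats)):
        for j in range(i + 1, len(mats)):
            v = edge_posterior_ssd(mats[i], mats[j])
            if v < best_val:
                best_val = v
                best = (i, j)
    return best, best_val


def mean_pairwise_ssd(samples: Sequence[ChainSample]) -> float:
    """Mean SSD over all unordered chain pairs — a scalar convergence score
    for an ensemble (lower = more mutually consistent chains)."""
    if len(samples) < 2:
        raise ValueError("need at least two chains")
    mat = pairwise_ssd_matrix(samples)
    k = mat.shape[0]
    iu = np.triu_indices(k, 1)
    return float(mat[iu].mean())


def unique_dag_count(sample: ChainSample) -> int:
    """Number of distinct structures among the retained states."""
    if not sample.dags:
        raise ValueError("empty sample")
    return len({g._key for g in sample.dags})


def unique_dag_trajectory(sample: ChainSample) -> np.ndarray:
    """Integer id of each retained state, ids assigned in order of first
    visit (for trajectory plots)."""
    ids: dict[bytes, int] = {}
    out = np.empty(len(sample.dags), dtype=int)
    for i, g in enumerate(sample.dags):
        out[i] = ids.setdefault(g._key, len(ids))
    return out


def map_dag(sample: ChainSample) -> tuple[DagStructure, float]:
    """Highest-scoring retained structure (first occurrence wins ties)."""
    if not sample.dags:
        raise ValueError("empty sample")
    idx = int(np.argmax(sample.log_scores))
    # argmax returns the first maximal index, matching the tie-break rule
    return sample.dags[idx], float(sample.log_scores[idx])


@dataclass
class ConsensusGraph:
    """Thresholded edge set; may be cyclic, hence not a DagStructure."""

    n_nodes: int
    edges: frozenset[tuple[int, int]]
    threshold: float
    is_acyclic: bool


def consensus_graph(
    posteriors: EdgePosteriorMatrix, threshold: float
) -> ConsensusGraph:
    """Edges with posterior strictly above ``threshold``.  Thresholding
    marginal edge probabilities can produce a cyclic graph; the result
    carries a flag rather than enforcing acyclicity."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    us, vs = np.nonzero(posteriors.values > threshold)
    edges = frozenset(zip(us.tolist(), vs.tolist()))
    from .dag import is_acyclic

    acyclic = is_acyclic(edges, posteriors.n_nodes)
    return ConsensusGraph(posteriors.n_nodes, edges, threshold, acyclic)


def neighborhood_acceptance_map(
    dag: DagStructure,
    dataset: DiscreteDataset,
    settings: Optional[ScoreSettings] = None,
    spec: Optional[ProposalSpec] = None,
    min_probability: float = 0.0,
) -> list[tuple[EdgeMove, float]]:
    """Acceptance probability of every one-step neighbor if it were
    proposed: min{1, exp(dlog score + log q(G)/q(G'))}.

    Useful for inspecting local maxima: a structure whose exits all have
    tiny acceptance probability traps a one-step chain.  Entries below
    ``min_probability`` are dropped.
    """
    max_fanin = spec.max_fanin if spec is not None else None
    scorer = BDeuScorer(dataset, settings)
    q_here = neighborhood_size(dag, max_fanin)
    out = []
    for move in enumerate_neighborhood(dag, max_fanin):
        from .dag import apply_move

        neighbor = apply_move(dag, move)
        delta = scorer.delta_log_score(dag, move)
        if scorer.settings.log_structure_prior is not None:
            delta += scorer.settings.log_prior(neighbor) - scorer.settings.log_prior(dag)
        log_alpha = delta + hastings_log_ratio(q_here, neighborhood_size(neighbor, max_fanin))
        prob = min(1.0, math.exp(min(log_alpha, 0.0)))
        if prob >= min_probability:
            out.append((move, prob))
    return out


def score_trace(sample: ChainSample, last_k: Optional[int] = None) -> np.ndarray:
    """(index, log score) pairs for the last ``last_k`` retained states."""
    n = len(sample.log_scores)
    if last_k is None:
        last_k = n
    if last_k > n:
        warnings.warn(f"last_k={last_k} exceeds sample size {n}; clipping")
        last_k = n
    idx = np.arange(n - last_k, n)
    return np.column_stack([idx, sample.log_scores[idx]])
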