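"""End-to-end validation experiments at desk scale.

Each function sets up a seeded synthetic study, runs the sampler (or
proposal machinery) from scratch and returns summary statistics.  They are
the package's own correctness benchmarks: the chain against the exact
enumeration oracle, the telescoped Hastings ratio against brute-force
proposal simulation, neighborhood counting against apply-and-check, the
constructive ergodicity walk, and the convergence benefit of mixture
proposals on multimodal (two-network pooled) data.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .dag import DagStructure, neighborhood_size
from .diagnostics import edge_posteriors, mean_pairwise_ssd
from .exact import exact_edge_posteriors, exact_posterior
from .proposal import NeighborhoodCache, ProposalSpec, sample_transition
from .sampler import ChainConfig, run_chain, run_chain_ensemble
from .scoring import DiscreteDataset
from .synthetic import combined_dataset, forward_sample, random_bn


def oracle_study_dataset(seed: int = 5, n_rows: int = 200) -> DiscreteDataset:
    """The small reference problem: 200 observational rows from a random
    3-node binary network, whose posterior over all 25 DAGs is exact."""
    rng = np.random.default_rng(seed)
    bn = random_bn(3, 0.5, arity=2, concentration=0.5, rng=rng)
    return forward_sample(bn, n_rows, rng)


def chain_vs_exact(
    dataset: DiscreteDataset,
    proposal: Sequence[float],
    retained: int = 200_000,
    burn_in: int = 20_000,
    seed: int = 42,
    hastings: bool = True,
) -> dict:
    """Run one chain and compare to exact enumeration.

    Returns total-variation distance between the empirical DAG frequencies
    and the exact posterior, and the max-abs error of the edge posteriors.
    """
    dist = exact_posterior(dataset)
    ep_exact = exact_edge_posteriors(dist)
    cfg = ChainConfig(
        ProposalSpec(tuple(proposal)),
        burn_in=burn_in,
        sample_size=retained,
        seed=seed,
        initial_dag="random",
    )
    sample = run_chain(cfg, dataset, hastings=hastings)
    idx = dist.as_index()
    counts = np.zeros(len(dist.dags))
    for g in sample.dags:
        counts[idx[g]] += 1
    emp = counts / counts.sum()
    tv = 0.5 * float(np.abs(emp - dist.probabilities).sum())
    err = float(np.abs(edge_posteriors(sample).values - ep_exact).max())
    return {"tv_distance": tv, "max_edge_posterior_error": err, "retained": retained}


def empirical_hastings_ratio(
    n_proposals: int = 1_000_000,
    seed: int = 7,
    proposal: Sequence[float] = (0.5, 0.5),
) -> dict:
    """Estimate Q(i|k)/Q(k|i) for a fixed 3-node DAG pair by simulating
    proposals, and compare with q(i)/q(k).

    The pair: a 2-edge DAG (q = 6) and the complete DAG covering it (q = 5).
    Returns the empirical ratio, the expected ratio and 3 Monte-Carlo SE.
    """
    gi = DagStructure(3, [(0, 1), (0, 2)])
    gk = DagStructure(3, [(0, 1), (0, 2), (1, 2)])
    qi, qk = neighborhood_size(gi), neighborhood_size(gk)
    spec = ProposalSpec(tuple(proposal))
    rng = np.random.default_rng(seed)
    cache = NeighborhoodCache(None)
    hit_ik = sum(
        sample_transition(gi, spec, rng, cache).end == gk for _ in range(n_proposals)
    )
    hit_ki = sum(
        sample_transition(gk, spec, rng, cache).end == gi for _ in range(n_proposals)
    )
    f_ik, f_ki = hit_ik / n_proposals, hit_ki / n_proposals
    ratio = f_ki / f_ik
    se = ratio * math.sqrt(
        (1 - f_ik) / (f_ik * n_proposals) + (1 - f_ki) / (f_ki * n_proposals)
    )
    return {
        "empirical_ratio": ratio,
        "expected_ratio": qi / qk,
        "three_se": 3 * se,
        "n_proposals": n_proposals,
    }


def neighborhood_agreement(
    n_dags: int = 500, seed: int = 13, fanins: Sequence[Optional[int]] = (None, 3)
) -> dict:
    """Fraction of random DAGs (n <= 6, with and without fan-in caps) whose
    neighborhood size matches exhaustive apply-and-check."""
    from .synthetic import random_dag

    rng = np.random.default_rng(seed)
    agree = 0
    total = 0
    for i in range(n_dags):
        fanin = fanins[i % len(fanins)]
        n = int(rng.integers(2, 7))
        g = random_dag(n, float(rng.random()), max_fanin=fanin, rng=rng)
        count = 0
        for u in range(n):
            for v in range(n):
                if u == v:
                    continue
                for kind in ("addition", "deletion", "reversal"):
                    count += _move_valid(g, kind, u, v, fanin)
        total += 1
        agree += count == neighborhood_size(g, fanin)
    return {"agreement": agree / total, "n_dags": total}


def _move_valid(g: DagStructure, kind: str, u: int, v: int, fanin) -> bool:
    """Apply-and-check on raw edge sets (independent of the enumerator)."""
    from .dag import is_acyclic

    edges = set(g.edges)
    if kind == "addition":
        if (u, v) in edges or (v, u) in edges:
            return False
        new = edges | {(u, v)}
        child = v
    elif kind == "deletion":
        return (u, v) in edges
    else:
        if (u, v) not in edges:
            return False
        new = (edges - {(u, v)}) | {(v, u)}
        child = u
    if not is_acyclic(new, g.n_nodes):
        return False
    if fanin is not None and sum(1 for (_, b) in new if b == child) > fanin:
        return False
    return True


def reachability_coverage(t_values: Sequence[int] = (1, 2, 3)) -> dict:
    """Verify the constructive walk connects every ordered DAG pair on
    n = 3 for each transition length, replaying every move with full
    validation.  Returns the fraction of pairs connected (1.0 = proof
    realized)."""
    from .exact import enumerate_dags
    from .proposal import reachability_walk

    dags = enumerate_dags(3)
    ok = 0
    total = 0
    for t in t_values:
        for a in dags:
            for b in dags:
                total += 1
                walks = reachability_walk(a, b, t)
                current = a
                valid = True
                for w in walks:
                    if w.length != t:
                        valid = False
                        break
                    current = w.replay()
                if valid and current == b:
                    ok += 1
    return {"connected_fraction": ok / total, "n_pairs": total}


def convergence_comparison(
    seed: int = 1000,
    n_replicates: int = 6,
    n_nodes: int = 10,
    n_each: int = 3000,
    chains: int = 3,
    burn_in: int = 40_000,
    sample_size: int = 20_000,
    proposals: Sequence[Sequence[float]] = ((1.0,), (0.8, 0.2)),
    max_fanin: int = 5,
) -> dict:
    """The two-network pooled-data convergence study at desk scale.

    For each replicate, draw two random discrete networks, pool their
    forward samples into one dataset, run an ensemble per proposal mixture
    and record the mean pairwise edge-posterior SSD across chains.  Returns
    the per-proposal means over replicates; lower SSD = better-agreeing
    chains.
    """
    results: dict[str, list[float]] = {}
    for vec in proposals:
        key = ",".join(str(p) for p in vec)
        spec = ProposalSpec(tuple(vec), max_fanin)
        ssds = []
        for rep in range(n_replicates):
            rng = np.random.default_rng(seed + rep)
            bn_a = random_bn(n_nodes, 0.3, rng=rng)
            bn_b = random_bn(n_nodes, 0.3, rng=rng)
            data = combined_dataset(bn_a, bn_b, n_each, rng)
            chain_seeds = np.random.SeedSequence(seed + 77_000 + rep).generate_state(
                chains
            ) % (2**31)
            cfgs = [
                ChainConfig(
                    spec,
                    burn_in=burn_in,
                    sample_size=sample_size,
                    seed=int(s),
                    initial_dag="random",
                )
                for s in chain_seeds
            ]
            samples = run_chain_ensemble(cfgs, data)
            ssds.append(mean_pairwise_ssd(samples))
        results[key] = ssds
    return {
        "per_replicate": results,
        "means": {k: float(np.mean(v)) for k, v in results.items()},
        "protocol": {
            "n_replicates": n_replicates,
            "chains": chains,
            "burn_in": burn_in,
            "sample_size": sample_size,
            "n_rows": 2 * n_each,
        },
    }
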