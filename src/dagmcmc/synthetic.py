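"""Ground-truth Bayesian networks and synthetic discrete data.

The experiments this package is built for rely on data whose generating
process is known: random discrete BNs sampled ancestrally, partly
interventional datasets (a fraction of rows has one variable clamped), and
the deliberately misspecified "two networks pooled into one dataset"
scenario that creates a multimodal posterior — the regime where multi-step
proposals earn their keep.  This module materializes the network parameters
(conditional probability tables); everywhere else they are integrated out.

Default arities are 3, mirroring a typical low/medium/high discretization of
signaling measurements; CPTs are symmetric-Dirichlet draws with strictly
positive entries, so every structure has positive likelihood (the positivity
that the chain's irreducibility argument assumes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .dag import DagStructure
from .sampler import random_dag_uniform_order
from .scoring import DiscreteDataset

DEFAULT_ARITY = 3


@dataclass
class GroundTruthBN:
    """A fully parameterized discrete Bayesian network.

    ``cpts[i]`` has shape ``(q_i, r_i)``: one categorical distribution per
    joint parent configuration, parent configurations indexed mixed-radix
    over the sorted parent tuple.
    """

    structure: DagStructure
    arities: np.ndarray
    cpts: list[np.ndarray]

    def __post_init__(self) -> None:
        self.arities = np.asarray(self.arities, dtype=np.int64)
        n = self.structure.n_nodes
        if self.arities.shape != (n,):
            raise ValueError("arities must have one entry per node")
        if len(self.cpts) != n:
            raise ValueError("one CPT per node required")
        for i, cpt in enumerate(self.cpts):
            parents = self.structure.parents(i)
            q = int(np.prod(self.arities[list(parents)])) if parents else 1
            if cpt.shape != (q, int(self.arities[i])):
                raise ValueError(
                    f"CPT of node {i} has shape {cpt.shape}, expected "
                    f"({q}, {self.arities[i]})"
                )
            if not np.allclose(cpt.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError(f"CPT rows of node {i} must sum to 1")

    @property
    def n_nodes(self) -> int:
        return self.structure.n_nodes

    def parent_config_index(self, node: int, row_values: np.ndarray) -> np.ndarray:
        """Mixed-radix index of the parent configuration for each row."""
        parents = self.structure.parents(node)
        codes = np.zeros(row_values.shape[0], dtype=np.int64)
        for p in parents:
            codes = codes * self.arities[p] + row_values[:, p]
        return codes

    # -- JSON round trip ---------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "n_nodes": self.n_nodes,
            "arities": self.arities.tolist(),
            "edges": [list(e) for e in self.structure.sorted_edges()],
            "cpts": [cpt.tolist() for cpt in self.cpts],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthBN":
        payload = json.loads(text)
        dag = DagStructure(
            payload["n_nodes"], [tuple(e) for e in payload["edges"]]
        )
        cpts = [np.asarray(c, dtype=float) for c in payload["cpts"]]
        return cls(dag, np.asarray(payload["arities"]), cpts)


def random_dag(
    n: int,
    edge_density: float,
    max_fanin: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> DagStructure:
    """Random DAG: draw a topological order uniformly, include each
    order-compatible edge independently with probability ``edge_density``,
    subject to the fan-in cap."""
    if not 0 <= edge_density <= 1:
        raise ValueError("edge_density must lie in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    return random_dag_uniform_order(n, rng, max_fanin, edge_prob=edge_density)


def random_cpts(
    structure: DagStructure,
    arities: Sequence[int],
    concentration: float = 0.5,
    rng: Optional[np.random.Generator] = None,
) -> GroundTruthBN:
    """Draw each conditional distribution from a symmetric
    Dirichlet(concentration).  Small concentrations give peaky, informative
    tables; large ones approach uniform (uninformative) conditionals."""
    if not concentration > 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng() if rng is None else rng
    arities = np.asarray(arities, dtype=np.int64)
    cpts = []
    for i in range(structure.n_nodes):
        parents = structure.parents(i)
        q = int(np.prod(arities[list(parents)])) if parents else 1
        r = int(arities[i])
        cpt = rng.dirichlet(np.full(r, concentration), size=q)
        # guard against numerically-zero entries; positivity is assumed
        # by the sampler's irreducibility argument
        cpt = np.clip(cpt, 1e-12, None)
        cpt /= cpt.sum(axis=1, keepdims=True)
        cpts.append(cpt)
    return GroundTruthBN(structure, arities, cpts)


def random_bn(
    n: int,
    edge_density: float = 0.3,
    arity: int = DEFAULT_ARITY,
    concentration: float = 0.5,
    max_fanin: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> GroundTruthBN:
    """Random structure plus random CPTs in one call."""
    rng = np.random.default_rng() if rng is None else rng
    dag = random_dag(n, edge_density, max_fanin, rng)
    return random_cpts(dag, np.full(n, arity), concentration, rng)


def _sample_rows(
    bn: GroundTruthBN,
    n_samples: int,
    rng: np.random.Generator,
    clamp_nodes: Optional[np.ndarray] = None,
    clamp_values: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Ancestral sampling; rows with a clamped node take the clamped value
    there and sample descendants conditional on it."""
    n = bn.n_nodes
    values = np.zeros((n_samples, n), dtype=np.int64)
    for node in bn.structure.topological_order():
        cpt = bn.cpts[node]
        codes = bn.parent_config_index(node, values)
        probs = cpt[codes]  # (n_samples, r)
        u = rng.random(n_samples)
        values[:, node] = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
        if clamp_nodes is not None:
            here = clamp_nodes == node
            if here.any():
                values[here, node] = clamp_values[here]
    return values


def forward_sample(
    bn: GroundTruthBN, n_samples: int, rng: Optional[np.random.Generator] = None
) -> DiscreteDataset:
    """Purely observational ancestral sample (all-false intervention mask)."""
    rng = np.random.default_rng() if rng is None else rng
    values = _sample_rows(bn, n_samples, rng)
    return DiscreteDataset(values, bn.arities.copy())


def interventional_sample(
    bn: GroundTruthBN,
    n_samples: int,
    intervention_fraction: float,
    rng: Optional[np.random.Generator] = None,
    target_nodes: Optional[Sequence[int]] = None,
    fixed_value: Optional[int] = None,
) -> DiscreteDataset:
    """Sample with a fraction of rows perturbed.

    Each intervened row has exactly one node (uniform over ``target_nodes``,
    default all nodes) clamped to a uniform random value (or ``fixed_value``);
    the mask marks the clamped cell and descendants are sampled conditional
    on it.
    """
    if not 0 <= intervention_fraction <= 1:
        raise ValueError("intervention_fraction must lie in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    n = bn.n_nodes
    n_int = int(round(intervention_fraction * n_samples))
    which = rng.permutation(n_samples)[:n_int]
    targets = np.asarray(target_nodes if target_nodes is not None else range(n))
    clamp_nodes = np.full(n_samples, -1, dtype=np.int64)
    clamp_nodes[which] = targets[rng.integers(len(targets), size=n_int)]
    clamp_values = np.zeros(n_samples, dtype=np.int64)
    if fixed_value is not None:
        clamp_values[which] = fixed_value
    else:
        # uniform over the clamped node's categories
        arities_at = bn.arities[clamp_nodes[which]]
        clamp_values[which] = np.floor(rng.random(n_int) * arities_at).astype(np.int64)
    values = _sample_rows(bn, n_samples, rng, clamp_nodes, clamp_values)
    mask = np.zeros((n_samples, n), dtype=bool)
    mask[which, clamp_nodes[which]] = True
    return DiscreteDataset(values, bn.arities.copy(), mask)


def combined_dataset(
    bn_a: GroundTruthBN,
    bn_b: GroundTruthBN,
    n_each: int,
    rng: Optional[np.random.Generator] = None,
) -> DiscreteDataset:
    """Pool ``n_each`` observational rows from each of two networks into one
    dataset with no provenance marker.

    No single DAG generates such data, so the structure posterior becomes
    multimodal — the stress test for proposal distributions.
    """
    if bn_a.n_nodes != bn_b.n_nodes or not np.array_equal(bn_a.arities, bn_b.arities):
        raise ValueError("the two networks must share node count and arities")
    rng = np.random.default_rng() if rng is None else rng
    da = forward_sample(bn_a, n_each, rng)
    db = forward_sample(bn_b, n_each, rng)
    return DiscreteDataset(
        np.vstack([da.values, db.values]), bn_a.arities.copy()
    )
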