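import numpy as np
import pytest

import dagmcmc as d


@pytest.fixture(scope="session")
def binary3_dataset():
    """200 observational rows from a random 3-node binary network: the
    standard small problem whose posterior is exactly enumerable."""
    rng = np.random.default_rng(5)
    bn = d.random_bn(3, 0.5, arity=2, concentration=0.5, rng=rng)
    return d.forward_sample(bn, 200, rng)


@pytest.fixture(scope="session")
def exact3(binary3_dataset):
    """Exact posterior over the 25 three-node DAGs for the fixture data."""
    return d.exact_posterior(binary3_dataset)


def random_dag_via_networkx_check(n, rng, p=0.4):
    """Random DAG by rejection-free construction (order + coin flips)."""
    return d.random_dag(n, p, rng=rng)


def brute_force_neighborhood(dag, max_fanin=None):
    """Independent apply-and-check oracle: try every conceivable single-edge
    modification, keep those whose result is acyclic (networkx check) and
    within the fan-in cap."""
    import networkx as nx

    n = dag.n_nodes
    edges = set(dag.edges)
    results = []

    def ok(new_edges, gaining_child):
        g = nx.DiGraph()
        g.add_nodes_from(range(n))
        g.add_edges_from(new_edges)
        if not nx.is_directed_acyclic_graph(g):
            return False
        if max_fanin is not None and gaining_child is not None:
            if sum(1 for (a, b) in new_edges if b == gaining_child) > max_fanin:
                return False
        return True

    for u in range(n):
        for v in range(n):
            if u == v:
                continue
            if (u, v) not in edges and (v, u) not in edges:
                if ok(edges | {(u, v)}, v):
                    results.append(("addition", (u, v)))
            if (u, v) in edges:
                results.append(("deletion", (u, v)))
                if ok((edges - {(u, v)}) | {(v, u)}, u):
                    results.append(("reversal", (u, v)))
    return sorted(results)
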