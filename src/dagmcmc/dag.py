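"""Directed acyclic graphs and their single-edge-move neighborhoods.

The Metropolis-Hastings sampler walks the space of DAGs by single edge
modifications (addition, deletion, reversal).  The set of modifications of a
DAG ``G`` that leave the graph acyclic and respect an optional fan-in cap is
its *neighborhood*; its cardinality ``q(G)`` enters the Hastings ratio, so
both the move list and the count must be exact.

Node identity is positional (0-based).  Optional string labels are carried
for I/O only and do not affect equality or hashing: two structures with the
same edge set compare equal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

ADDITION = "addition"
DELETION = "deletion"
REVERSAL = "reversal"

_KIND_ORDER = {ADDITION: 0, DELETION: 1, REVERSAL: 2}


@dataclass(frozen=True)
class EdgeMove:
    """A single edge modification: add, delete or reverse the ordered pair."""

    kind: str
    edge: tuple[int, int]

    def __post_init__(self) -> None:
        if self.kind not in _KIND_ORDER:
            raise ValueError(f"unknown move kind {self.kind!r}")
        u, v = self.edge
        if u == v:
            raise ValueError("self-edges are not allowed")

    def inverse(self) -> "EdgeMove":
        """The move undoing this one (add<->delete, reversal<->reversed reversal)."""
        u, v = self.edge
        if self.kind == ADDITION:
            return EdgeMove(DELETION, (u, v))
        if self.kind == DELETION:
            return EdgeMove(ADDITION, (u, v))
        return EdgeMove(REVERSAL, (v, u))


class DagStructure:
    """An immutable DAG over nodes ``0 .. n_nodes-1``.

    Parameters
    ----------
    n_nodes
        Number of nodes.
    edges
        Iterable of ``(parent, child)`` pairs.
    node_labels
        Optional display names, one per node.
    validate
        When True (default) the edge set is checked for self-edges,
        duplicates, antiparallel pairs and cycles.
    """

    __slots__ = ("n_nodes", "_adj", "_key", "_hash", "node_labels", "_reach")

    def __init__(
        self,
        n_nodes: int,
        edges: Iterable[tuple[int, int]] = (),
        node_labels: Optional[Sequence[str]] = None,
        validate: bool = True,
    ) -> None:
        if n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        adj = np.zeros((n_nodes, n_nodes), dtype=bool)
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-edge ({u},{v}) is not allowed")
            if not (0 <= u < n_nodes and 0 <= v < n_nodes):
                raise ValueError(f"edge ({u},{v}) out of range for n={n_nodes}")
            if validate and adj[u, v]:
                raise ValueError(f"duplicate edge ({u},{v})")
            adj[u, v] = True
        if validate:
            if np.any(adj & adj.T):
                raise ValueError("antiparallel edge pair present")
            if not is_acyclic_adjacency(adj):
                raise ValueError("edge set contains a directed cycle")
        if node_labels is not None and len(node_labels) != n_nodes:
            raise ValueError("node_labels length must equal n_nodes")
        self.n_nodes = n_nodes
        self._adj = adj
        adj.setflags(write=False)
        self._key = adj.tobytes()
        self._hash = hash((n_nodes, self._key))
        self.node_labels = tuple(node_labels) if node_labels is not None else None
        self._reach = None

    # -- fast internal constructor -------------------------------------------------
    @classmethod
    def _from_adj(cls, adj: np.ndarray, labels=None) -> "DagStructure":
        """Wrap an adjacency matrix known to be a valid DAG (no checks)."""
        self = object.__new__(cls)
        self.n_nodes = adj.shape[0]
        self._adj = adj
        adj.setflags(write=False)
        self._key = adj.tobytes()
        self._hash = hash((self.n_nodes, self._key))
        self.node_labels = labels
        self._reach = None
        return self

    # -- basic protocol ------------------------------------------------------------
    @property
    def adjacency(self) -> np.ndarray:
        """Read-only boolean adjacency matrix, ``[parent, child]``."""
        return self._adj

    @property
    def edges(self) -> frozenset[tuple[int, int]]:
        us, vs = np.nonzero(self._adj)
        return frozenset(zip(us.tolist(), vs.tolist()))

    def sorted_edges(self) -> list[tuple[int, int]]:
        us, vs = np.nonzero(self._adj)
        return sorted(zip(us.tolist(), vs.tolist()))

    @property
    def n_edges(self) -> int:
        return int(self._adj.sum())

    def parents(self, node: int) -> tuple[int, ...]:
        return tuple(np.nonzero(self._adj[:, node])[0].tolist())

    def children(self, node: int) -> tuple[int, ...]:
        return tuple(np.nonzero(self._adj[node])[0].tolist())

    def has_edge(self, u: int, v: int) -> bool:
        return bool(self._adj[u, v])

    def __eq__(self, other) -> bool:
        if not isinstance(other, DagStructure):
            return NotImplemented
        return self.n_nodes == other.n_nodes and self._key == other._key

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        return f"DagStructure(n_nodes={self.n_nodes}, edges={self.sorted_edges()})"

    # -- reachability --------------------------------------------------------------
    def reachability(self) -> np.ndarray:
        """Boolean closure matrix: entry ``[u, v]`` is True iff a directed
        path of length >= 1 leads from ``u`` to ``v``.  Cached."""
        if self._reach is None:
            self._reach = _transitive_closure(self._adj)
            self._reach.setflags(write=False)
        return self._reach

    def topological_order(self) -> list[int]:
        indeg = self._adj.sum(axis=0).astype(int)
        order: list[int] = []
        ready = [i for i in range(self.n_nodes) if indeg[i] == 0]
        while ready:
            u = ready.pop()
            order.append(u)
            for v in np.nonzero(self._adj[u])[0]:
                indeg[v] -= 1
                if indeg[v] == 0:
                    ready.append(int(v))
        if len(order) != self.n_nodes:
            raise RuntimeError("graph is not acyclic")
        return order


def _transitive_closure(adj: np.ndarray) -> np.ndarray:
    reach = adj.astype(np.uint8)
    while True:
        nxt = ((reach @ reach) > 0) | (reach > 0)
        nxt = nxt.astype(np.uint8)
        if np.array_equal(nxt, reach):
            break
        reach = nxt
    return reach.astype(bool)


def is_acyclic_adjacency(adj: np.ndarray) -> bool:
    """Kahn's algorithm on a boolean adjacency matrix."""
    n = adj.shape[0]
    indeg = adj.sum(axis=0).astype(int)
    ready = [i for i in range(n) if indeg[i] == 0]
    seen = 0
    while ready:
        u = ready.pop()
        seen += 1
        for v in np.nonzero(adj[u])[0]:
            indeg[v] -= 1
            if indeg[v] == 0:
                ready.append(int(v))
    return seen == n


def is_acyclic(edges: Iterable[tuple[int, int]], n_nodes: int) -> bool:
    """True iff the edge set over nodes ``0..n_nodes-1`` admits a topological order.

    Raises ``ValueError`` on a self-edge or out-of-range node.
    """
    adj = np.zeros((n_nodes, n_nodes), dtype=bool)
    for u, v in edges:
        if u == v:
            raise ValueError(f"self-edge ({u},{v}) is invalid input")
        if not (0 <= u < n_nodes and 0 <= v < n_nodes):
            raise ValueError(f"edge ({u},{v}) out of range")
        adj[u, v] = True
    return is_acyclic_adjacency(adj)


def apply_move(dag: DagStructure, move: EdgeMove) -> DagStructure:
    """Apply one edge modification, returning a new structure.

    Raises ``ValueError`` if the move is inapplicable (adding an existing or
    antiparallel edge, deleting/reversing a missing edge) or if the result
    would be cyclic.
    """
    u, v = move.edge
    n = dag.n_nodes
    if not (0 <= u < n and 0 <= v < n):
        raise ValueError(f"edge ({u},{v}) out of range")
    adj = dag._adj
    new = adj.copy()
    if move.kind == ADDITION:
        if adj[u, v] or adj[v, u]:
            raise ValueError(f"cannot add ({u},{v}): edge or its reverse present")
        if dag.reachability()[v, u]:
            raise ValueError(f"adding ({u},{v}) creates a cycle")
        new[u, v] = True
    elif move.kind == DELETION:
        if not adj[u, v]:
            raise ValueError(f"cannot delete missing edge ({u},{v})")
        new[u, v] = False
    else:  # reversal
        if not adj[u, v]:
            raise ValueError(f"cannot reverse missing edge ({u},{v})")
        new[u, v] = False
        if not is_acyclic_adjacency(new | _single_edge(n, v, u)):
            raise ValueError(f"reversing ({u},{v}) creates a cycle")
        new[v, u] = True
    return DagStructure._from_adj(new, dag.node_labels)


def _single_edge(n: int, u: int, v: int) -> np.ndarray:
    m = np.zeros((n, n), dtype=bool)
    m[u, v] = True
    return m


def _neighborhood_arrays(
    dag: DagStructure, max_fanin: Optional[int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized neighborhood: parallel arrays (kind code, u, v).

    Kind codes follow ``_KIND_ORDER`` (0=addition, 1=deletion, 2=reversal) and
    the triple is sorted by (kind, u, v), giving a deterministic move order.
    """
    adj = dag._adj
    n = dag.n_nodes
    reach = dag.reachability()
    indeg = adj.sum(axis=0)

    # additions: (u,v) with no edge either way, v not an ancestor of u, fan-in ok
    cand = ~adj & ~adj.T & ~reach.T
    np.fill_diagonal(cand, False)
    if max_fanin is not None:
        cand &= (indeg < max_fanin)[np.newaxis, :]
    add_u, add_v = np.nonzero(cand)

    eu, ev = np.nonzero(adj)  # row-major == sorted (u, v)

    # reversals: (u,v) -> (v,u); invalid if another u->v path exists
    # (any child w != v of u that reaches v), or fan-in cap hit at u.
    rev_ok = np.empty(len(eu), dtype=bool)
    for idx in range(len(eu)):
        u, v = eu[idx], ev[idx]
        via = adj[u] & reach[:, v]
        via[v] = False
        rev_ok[idx] = not via.any()
        if rev_ok[idx] and max_fanin is not None and indeg[u] >= max_fanin:
            rev_ok[idx] = False
    kinds = np.concatenate(
        [
            np.zeros(len(add_u), dtype=np.int8),
            np.ones(len(eu), dtype=np.int8),
            np.full(int(rev_ok.sum()), 2, dtype=np.int8),
        ]
    )
    us = np.concatenate([add_u, eu, eu[rev_ok]])
    vs = np.concatenate([add_v, ev, ev[rev_ok]])
    return kinds, us, vs


_KIND_NAMES = (ADDITION, DELETION, REVERSAL)


def enumerate_neighborhood(
    dag: DagStructure, max_fanin: Optional[int] = None
) -> list[EdgeMove]:
    """All single-edge moves whose application yields an acyclic DAG within
    the fan-in cap, in deterministic (kind, edge) order.

    A deletion is always admissible; an addition or reversal is admissible
    only if the gaining child stays at or below ``max_fanin`` parents, which
    keeps the neighborhood relation symmetric.
    """
    kinds, us, vs = _neighborhood_arrays(dag, max_fanin)
    return [
        EdgeMove(_KIND_NAMES[k], (int(u), int(v)))
        for k, u, v in zip(kinds.tolist(), us.tolist(), vs.tolist())
    ]


def neighborhood_size(dag: DagStructure, max_fanin: Optional[int] = None) -> int:
    """``q(G)``: the number of admissible single-edge moves from ``dag``."""
    kinds, _, _ = _neighborhood_arrays(dag, max_fanin)
    return len(kinds)


def apply_move_arrays(adj: np.ndarray, kind: int, u: int, v: int) -> np.ndarray:
    """Apply a move given by (kind code, u, v) to a writable adjacency copy."""
    new = adj.copy()
    if kind == 0:
        new[u, v] = True
    elif kind == 1:
        new[u, v] = False
    else:
        new[u, v] = False
        new[v, u] = True
    return new


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_edge_list(path, n_nodes: Optional[int] = None) -> DagStructure:
    """Read a DAG from a two-column ``parent<TAB>child`` file.

    A first line that does not parse as two integers is treated as a header.
    ``n_nodes`` defaults to (max index + 1).
    """
    edges = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            try:
                u, v = int(parts[0]), int(parts[1])
            except (ValueError, IndexError):
                if line_no == 0:
                    continue  # header
                raise ValueError(f"cannot parse edge line: {raw!r}")
            edges.append((u, v))
    if n_nodes is None:
        n_nodes = max((max(u, v) for u, v in edges), default=0) + 1
    return DagStructure(n_nodes, edges)


def write_edge_list(dag: DagStructure, path) -> None:
    with open(path, "w") as fh:
        fh.write("parent\tchild\n")
        for u, v in dag.sorted_edges():
            fh.write(f"{u}\t{v}\n")


def read_adjacency_csv(path) -> DagStructure:
    """Read a square 0/1 adjacency matrix (row = parent, column = child)."""
    mat = np.loadtxt(path, delimiter=",", dtype=int)
    mat = np.atleast_2d(mat)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError("adjacency matrix must be square")
    us, vs = np.nonzero(mat)
    return DagStructure(mat.shape[0], list(zip(us.tolist(), vs.tolist())))


def write_adjacency_csv(dag: DagStructure, path) -> None:
    np.savetxt(path, dag.adjacency.astype(int), fmt="%d", delimiter=",")


def to_dot(dag: DagStructure) -> str:
    """GraphViz DOT representation (labels used when present)."""
    labels = dag.node_labels or [str(i) for i in range(dag.n_nodes)]
    lines = ["digraph G {"]
    for i, lab in enumerate(labels):
        lines.append(f'  n{i} [label="{lab}"];')
    for u, v in dag.sorted_edges():
        lines.append(f"  n{u} -> n{v};")
    lines.append("}")
    return "\n".join(lines)
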