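"""Multi-step mixture proposals over DAG space.

A proposal of length ``t`` is a walk of ``t`` single-edge modifications,
each drawn uniformly from the neighborhood of the current intermediate
structure.  At every iteration the walk length is drawn from a mixture
vector ``[p_1, ..., p_max]``.  Although the probability of proposing a given
endpoint sums over many routes, forward and reverse routes pair up one-to-one
with identical interior factors, so the Hastings ratio telescopes to

    Q(start | end) / Q(end | start) = q(start) / q(end),

the ratio of the two endpoint neighborhood sizes.  Only ``q`` at the two
endpoints is ever needed, regardless of the walk length or mixture — this is
what makes long jumps affordable.

The chain built from this proposal is ergodic: :func:`reachability_walk`
constructs, for any ordered DAG pair and any transition length ``t``, an
explicit sequence of whole ``t``-transitions connecting them (irreducibility),
and self-returning routes of coprime transition counts exist via the empty
graph (aperiodicity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dag import (
    ADDITION,
    DELETION,
    REVERSAL,
    DagStructure,
    EdgeMove,
    _KIND_NAMES,
    _neighborhood_arrays,
    apply_move,
    apply_move_arrays,
)


@dataclass(frozen=True)
class ProposalSpec:
    """Mixture proposal: propose a transition of length ``t`` with
    probability ``length_probs[t-1]``; moves respect ``max_fanin``.

    The default jump-length cap is small (the vector rarely needs more than a
    few entries): very long jumps amount to sampling structures at random and
    make the chain inefficient.
    """

    length_probs: tuple[float, ...]
    max_fanin: Optional[int] = None

    MAX_RECOMMENDED_LENGTH = 5

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.length_probs)
        object.__setattr__(self, "length_probs", probs)
        if len(probs) < 1:
            raise ValueError("length_probs must have at least one entry")
        if any(p < 0 for p in probs):
            raise ValueError("length probabilities must be non-negative")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValueError("length probabilities must sum to 1")
        if self.max_fanin is not None and self.max_fanin < 1:
            raise ValueError("max_fanin must be >= 1")
        if len(probs) > self.MAX_RECOMMENDED_LENGTH:
            import warnings

            warnings.warn(
                f"jump lengths above {self.MAX_RECOMMENDED_LENGTH} amount to "
                "random sampling of the structure space and make the chain "
                "inefficient",
                stacklevel=2,
            )
        object.__setattr__(self, "_cum", np.cumsum(probs))

    @classmethod
    def from_string(cls, text: str, max_fanin: Optional[int] = None) -> "ProposalSpec":
        """Parse a comma list, e.g. ``"0.8,0.2"`` for ``[p_1=0.8, p_2=0.2]``."""
        return cls(tuple(float(x) for x in text.split(",")), max_fanin)

    @property
    def max_length(self) -> int:
        return len(self.length_probs)

    def draw_length(self, rng: np.random.Generator) -> int:
        return int(np.searchsorted(self._cum, rng.random(), side="right")) + 1


@dataclass
class TransitionWalk:
    """One sampled multi-step transition.

    ``q_values[j]`` is the neighborhood size of the structure *before* move
    ``j``; ``q_values[0]`` is therefore ``q(start)``, the quantity the
    Hastings ratio needs.
    """

    start: DagStructure
    moves: list[EdgeMove]
    q_values: list[int]
    end: DagStructure

    @property
    def length(self) -> int:
        return len(self.moves)

    @property
    def q_start(self) -> int:
        return self.q_values[0]

    def replay(self) -> DagStructure:
        """Re-apply the moves with full validation; returns the endpoint."""
        g = self.start
        for mv in self.moves:
            g = apply_move(g, mv)
        return g


class NeighborhoodCache:
    """Memo of neighborhoods keyed by adjacency bytes, bounded in size.

    Chains revisit the same structures constantly (small spaces, rejected
    moves, oscillation inside a mode); caching the move arrays makes
    sub-step sampling a dictionary lookup.
    """

    def __init__(self, max_fanin: Optional[int], max_entries: int = 200_000):
        self.max_fanin = max_fanin
        self.max_entries = max_entries
        self._store: dict[bytes, tuple] = {}

    def get(self, dag: DagStructure) -> tuple:
        entry = self._store.get(dag._key)
        if entry is None:
            entry = _neighborhood_arrays(dag, self.max_fanin)
            if len(self._store) < self.max_entries:
                self._store[dag._key] = entry
        return entry

    def size(self, dag: DagStructure) -> int:
        return len(self.get(dag)[0])


def sample_transition(
    dag: DagStructure,
    spec: ProposalSpec,
    rng: np.random.Generator,
    cache: Optional[NeighborhoodCache] = None,
) -> TransitionWalk:
    """Draw one multi-step transition from ``dag``.

    The random stream is consumed in a fixed order — one draw for the walk
    length, then one per sub-step — so runs are replayable from the seed.
    The endpoint may coincide with the start or with a nearer neighbor; such
    walks are legal (and improbable in large neighborhoods) and are kept.
    """
    if cache is None:
        cache = NeighborhoodCache(spec.max_fanin)
    t = spec.draw_length(rng)
    current = dag
    moves: list[EdgeMove] = []
    q_values: list[int] = []
    for _ in range(t):
        kinds, us, vs = cache.get(current)
        q = len(kinds)
        if q == 0:
            raise ValueError("empty neighborhood: the structure space is a single state")
        idx = int(rng.integers(q))
        k, u, v = int(kinds[idx]), int(us[idx]), int(vs[idx])
        moves.append(EdgeMove(_KIND_NAMES[k], (u, v)))
        q_values.append(q)
        current = DagStructure._from_adj(
            apply_move_arrays(current._adj, k, u, v), dag.node_labels
        )
    return TransitionWalk(dag, moves, q_values, current)


def hastings_log_ratio(q_start: int, q_end: int) -> float:
    """log [ Q(start|end) / Q(end|start) ] = log q(start) - log q(end).

    Valid for any transition length and for mixtures: every forward route
    carries the factor 1/q(start), its reverse the factor 1/q(end), and all
    interior factors coincide pairwise.
    """
    if q_start <= 0 or q_end <= 0:
        raise ValueError("neighborhood sizes must be positive")
    return math.log(q_start) - math.log(q_end)


def transition_log_probability(walk: TransitionWalk, spec: ProposalSpec) -> float:
    """Log probability of proposing this exact route:
    ``log p_t - sum_j log q(structure before step j)``.

    The sampler itself never needs this (endpoint q's suffice); it exists for
    verification, e.g. summing route probabilities to recover Q^t(end|start).
    """
    t = walk.length
    if t < 1 or t > spec.max_length:
        raise ValueError(f"walk length {t} outside proposal support")
    if len(walk.q_values) != t:
        raise ValueError("walk has inconsistent bookkeeping")
    p_t = spec.length_probs[t - 1]
    if p_t <= 0:
        return -math.inf
    return math.log(p_t) - sum(math.log(q) for q in walk.q_values)


# ---------------------------------------------------------------------------
# constructive ergodicity: an explicit walk between any two DAGs
# ---------------------------------------------------------------------------

def reachability_walk(
    g_from: DagStructure, g_to: DagStructure, t: int
) -> list[TransitionWalk]:
    """Construct whole ``t``-transitions carrying ``g_from`` to ``g_to``.

    Realizes the irreducibility argument: tear ``g_from`` down to the empty
    graph (deletions, with leftover steps of a partial transition spent
    reversing a final single edge), then build ``g_to`` edge by edge, using a
    parity-correcting first edge plus reversals to absorb the slack in the
    partial building transition.  Every intermediate structure is acyclic
    and each returned walk has exactly ``t`` moves.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if g_from.n_nodes != g_to.n_nodes:
        raise ValueError("node counts differ")
    n = g_from.n_nodes
    if n < 2 and (g_from.n_edges or g_to.n_edges):
        raise ValueError("single-node graphs admit no moves")

    moves: list[EdgeMove] = []

    # --- demolition: g_from -> empty graph -------------------------------
    edges = g_from.sorted_edges()
    e = len(edges)
    d_t = e // t
    for i in range(d_t * t):
        moves.append(EdgeMove(DELETION, edges[i]))
    m = e - d_t * t
    if m > 0:
        # partial transition: m-1 deletions, t-m reversals of the last
        # remaining edge, one final deletion
        for i in range(d_t * t, e - 1):
            moves.append(EdgeMove(DELETION, edges[i]))
        u, v = edges[e - 1]
        for _ in range(t - m):
            moves.append(EdgeMove(REVERSAL, (u, v)))
            u, v = v, u
        moves.append(EdgeMove(DELETION, (u, v)))

    # --- construction: empty graph -> g_to -------------------------------
    target = g_to.sorted_edges()
    e2 = len(target)
    a = e2 // t
    b = e2 - a * t
    if b > 0:
        # partial transition of t moves contributing the first b edges:
        # parity-correcting first addition, E-1 reversals, one reversal,
        # then t-E-1 further additions  (E = t - b leftover steps)
        E = t - b
        u, v = target[0]
        first = (u, v) if E % 2 == 0 else (v, u)
        moves.append(EdgeMove(ADDITION, first))
        cu, cv = first
        for _ in range(E - 1):
            moves.append(EdgeMove(REVERSAL, (cu, cv)))
            cu, cv = cv, cu
        moves.append(EdgeMove(REVERSAL, (cu, cv)))
        cu, cv = cv, cu
        assert (cu, cv) == (u, v)
        for i in range(1, b):
            moves.append(EdgeMove(ADDITION, target[i]))
    for i in range(b, e2):
        moves.append(EdgeMove(ADDITION, target[i]))

    assert len(moves) % t == 0
    return _package_transitions(g_from, moves, t)


def _package_transitions(
    start: DagStructure, moves: list[EdgeMove], t: int
) -> list[TransitionWalk]:
    """Slice a flat validated move list into whole t-transitions, recording
    the true q-values along the way."""
    from .dag import neighborhood_size

    walks: list[TransitionWalk] = []
    current = start
    for i in range(0, len(moves), t):
        chunk = moves[i : i + t]
        seg_start = current
        qs: list[int] = []
        for mv in chunk:
            qs.append(neighborhood_size(current))
            current = apply_move(current, mv)
        walks.append(TransitionWalk(seg_start, chunk, qs, current))
    return walks
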