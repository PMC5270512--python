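"""Multi-step proposals: sampling law, Hastings ratio, ergodicity walk."""

import math

import numpy as np
import pytest

import dagmcmc as d
from dagmcmc.proposal import NeighborhoodCache


class TestProposalSpec:
    def test_must_sum_to_one(self):
        with pytest.raises(ValueError):
            d.ProposalSpec((0.5, 0.4))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            d.ProposalSpec((1.5, -0.5))

    def test_from_string(self):
        spec = d.ProposalSpec.from_string("0.8,0.2", max_fanin=5)
        assert spec.length_probs == (0.8, 0.2)
        assert spec.max_fanin == 5

    def test_long_jump_warning(self):
        with pytest.warns(UserWarning):
            d.ProposalSpec((0.5, 0.1, 0.1, 0.1, 0.1, 0.1))


class TestSampleTransition:
    def test_single_step_comes_from_neighborhood(self):
        g = d.DagStructure(3, [(0, 1)])
        spec = d.ProposalSpec((1.0,))
        rng = np.random.default_rng(0)
        allowed = {d.apply_move(g, m) for m in d.enumerate_neighborhood(g)}
        for _ in range(50):
            w = d.sample_transition(g, spec, rng)
            assert w.length == 1
            assert w.end in allowed
            assert w.q_start == d.neighborhood_size(g)

    def test_two_step_routes_uniform_from_empty_two_node(self):
        """From the empty 2-node DAG a length-2 walk has 2 x 2 equally
        likely routes (first move 1 of 2 additions, second 1 of 2 moves)."""
        g = d.DagStructure(2)
        spec = d.ProposalSpec((0.0, 1.0))
        rng = np.random.default_rng(1)
        counts = {}
        n = 40_000
        for _ in range(n):
            w = d.sample_transition(g, spec, rng)
            key = tuple((m.kind, m.edge) for m in w.moves)
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 4
        for c in counts.values():
            assert c / n == pytest.approx(0.25, abs=0.01)

    def test_one_step_uniform_over_neighbors(self):
        """With p_1 = 1 the proposal is the classical uniform one-step law:
        each of the 5 neighbors of the complete 3-node DAG appears with
        frequency 1/5."""
        g = d.DagStructure(3, [(0, 1), (0, 2), (1, 2)])
        spec = d.ProposalSpec((1.0,))
        rng = np.random.default_rng(2)
        cache = NeighborhoodCache(None)
        counts = {}
        n = 100_000
        for _ in range(n):
            w = d.sample_transition(g, spec, rng, cache)
            counts[w.end] = counts.get(w.end, 0) + 1
        assert len(counts) == 5
        for c in counts.values():
            assert c / n == pytest.approx(0.2, abs=0.01)

    def test_walk_bookkeeping_replays(self):
        rng = np.random.default_rng(3)
        spec = d.ProposalSpec((0.3, 0.4, 0.3))
        g = d.DagStructure(4, [(0, 1), (2, 3)])
        for _ in range(100):
            w = d.sample_transition(g, spec, rng)
            assert w.replay() == w.end
            assert len(w.q_values) == w.length

    def test_single_node_raises(self):
        with pytest.raises(ValueError):
            d.sample_transition(
                d.DagStructure(1), d.ProposalSpec((1.0,)), np.random.default_rng(0)
            )

    def test_seed_determinism(self):
        g = d.DagStructure(3)
        spec = d.ProposalSpec((0.5, 0.5))
        a = [d.sample_transition(g, spec, np.random.default_rng(9)).end for _ in [0]]
        b = [d.sample_transition(g, spec, np.random.default_rng(9)).end for _ in [0]]
        assert a == b


class TestHastingsRatio:
    def test_equal_sizes_give_zero(self):
        assert d.hastings_log_ratio(7, 7) == 0.0

    def test_six_fifths(self):
        assert d.hastings_log_ratio(6, 5) == pytest.approx(math.log(6 / 5))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            d.hastings_log_ratio(0, 3)

    def test_empirical_ratio_matches_neighborhood_sizes(self):
        """Estimate Q(i|k) and Q(k|i) by simulation under the 50/50 mixture
        and check their ratio equals q(i)/q(k) within 3 Monte-Carlo SE."""
        gi = d.DagStructure(3, [(0, 1), (0, 2)])
        gk = d.DagStructure(3, [(0, 1), (0, 2), (1, 2)])
        qi, qk = d.neighborhood_size(gi), d.neighborhood_size(gk)
        spec = d.ProposalSpec((0.5, 0.5))
        rng = np.random.default_rng(7)
        cache = NeighborhoodCache(None)
        n = 200_000
        f_ik = sum(d.sample_transition(gi, spec, rng, cache).end == gk for _ in range(n)) / n
        f_ki = sum(d.sample_transition(gk, spec, rng, cache).end == gi for _ in range(n)) / n
        ratio = f_ki / f_ik
        se = ratio * math.sqrt((1 - f_ik) / (f_ik * n) + (1 - f_ki) / (f_ki * n))
        assert abs(ratio - qi / qk) < 3 * se


def enumerate_routes(start, end, t):
    """Exhaustive route enumeration: all length-t move sequences from
    ``start`` ending at ``end`` (test-side oracle)."""
    routes = []

    def extend(current, moves, qs):
        if len(moves) == t:
            if current == end:
                routes.append((list(moves), list(qs)))
            return
        nbh = d.enumerate_neighborhood(current)
        for mv in nbh:
            moves.append(mv)
            qs.append(len(nbh))
            extend(d.apply_move(current, mv), moves, qs)
            moves.pop()
            qs.pop()

    extend(start, [], [])
    return routes


class TestTransitionLogProbability:
    def test_single_step_from_empty(self):
        g = d.DagStructure(3)
        spec = d.ProposalSpec((0.4, 0.6))
        rng = np.random.default_rng(4)
        w = d.sample_transition(g, spec, rng)
        while w.length != 1:
            w = d.sample_transition(g, spec, rng)
        assert d.transition_log_probability(w, spec) == pytest.approx(
            math.log(0.4) - math.log(6)
        )

    def test_two_step_from_empty_two_node(self):
        g = d.DagStructure(2)
        spec = d.ProposalSpec((0.0, 1.0))
        w = d.sample_transition(g, spec, np.random.default_rng(5))
        assert d.transition_log_probability(w, spec) == pytest.approx(
            -math.log(2) - math.log(2)
        )

    def test_route_sum_recovers_endpoint_probability(self):
        """Sum of exp(route log probability) over all enumerated length-2
        routes i -> k equals the Monte-Carlo frequency of proposing k."""
        gi = d.DagStructure(3, [(0, 1)])
        gk = d.DagStructure(3, [(0, 1), (1, 2)])
        spec = d.ProposalSpec((0.0, 1.0))
        routes = enumerate_routes(gi, gk, 2)
        total = sum(
            math.exp(sum(-math.log(q) for q in qs)) for _, qs in routes
        )
        rng = np.random.default_rng(6)
        cache = NeighborhoodCache(None)
        n = 100_000
        freq = sum(d.sample_transition(gi, spec, rng, cache).end == gk for _ in range(n)) / n
        assert freq == pytest.approx(total, abs=0.005)

    def test_endpoint_ratio_telescopes_exactly(self):
        """Route-sum forward and reverse probabilities have exactly the
        ratio q(i)/q(k): the endpoint-only Hastings computation agrees with
        the exhaustive-route one."""
        gi = d.DagStructure(3, [(0, 1)])
        gk = d.DagStructure(3, [(0, 1), (1, 2)])
        for t in (1, 2, 3):
            fwd = sum(
                math.exp(sum(-math.log(q) for q in qs))
                for _, qs in enumerate_routes(gi, gk, t)
            )
            rev = sum(
                math.exp(sum(-math.log(q) for q in qs))
                for _, qs in enumerate_routes(gk, gi, t)
            )
            assert rev / fwd == pytest.approx(
                d.neighborhood_size(gi) / d.neighborhood_size(gk), rel=1e-9
            )

    def test_invalid_length_raises(self):
        g = d.DagStructure(3)
        spec1 = d.ProposalSpec((1.0,))
        w = d.sample_transition(g, d.ProposalSpec((0.0, 1.0)), np.random.default_rng(0))
        with pytest.raises(ValueError):
            d.transition_log_probability(w, spec1)


class TestReachabilityWalk:
    def test_single_edge_to_empty_t2(self):
        walks = d.reachability_walk(
            d.DagStructure(2, [(0, 1)]), d.DagStructure(2), 2
        )
        assert len(walks) == 1
        assert [(m.kind, m.edge) for m in walks[0].moves] == [
            ("reversal", (0, 1)),
            ("deletion", (1, 0)),
        ]

    def test_empty_to_empty_is_empty_sequence(self):
        assert d.reachability_walk(d.DagStructure(3), d.DagStructure(3), 2) == []

    @pytest.mark.parametrize("t", [1, 2, 3])
    def test_random_pairs_connect(self, t):
        rng = np.random.default_rng(8)
        for _ in range(25):
            a = d.random_dag(5, 0.5, rng=rng)
            b = d.random_dag(5, 0.5, rng=rng)
            walks = d.reachability_walk(a, b, t)
            current = a
            for w in walks:
                assert w.length == t
                current = w.replay()  # validates acyclicity of every step
            assert current == b

    def test_aperiodicity_filler_transition(self):
        """From the empty graph a t-transition can return to it by add,
        reverse t-2 times, delete — so self-returning routes of both s and
        s+1 transitions exist."""
        g = d.DagStructure(3)
        for t in (2, 3, 4):
            moves = [d.EdgeMove("addition", (0, 1))]
            u, v = 0, 1
            for _ in range(t - 2):
                moves.append(d.EdgeMove("reversal", (u, v)))
                u, v = v, u
            moves.append(d.EdgeMove("deletion", (u, v)))
            current = g
            for mv in moves:
                current = d.apply_move(current, mv)
            assert current == g

    def test_invalid_t_rejected(self):
        with pytest.raises(ValueError):
            d.reachability_walk(d.DagStructure(3), d.DagStructure(3), 0)

    def test_node_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            d.reachability_walk(d.DagStructure(3), d.DagStructure(4), 2)
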