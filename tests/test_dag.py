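"""DAG representation, moves and neighborhood enumeration."""

import numpy as np
import pytest

import dagmcmc as d
from dagmcmc.dag import ADDITION, DELETION, REVERSAL

from conftest import brute_force_neighborhood


class TestAcyclicity:
    @pytest.mark.parametrize(
        "edges,n,expected",
        [
            ([], 3, True),
            ([(0, 1), (1, 0)], 2, False),
            ([(0, 1), (1, 2), (0, 2)], 3, True),
            ([(0, 1), (1, 2), (2, 0)], 3, False),
        ],
    )
    def test_examples(self, edges, n, expected):
        assert d.is_acyclic(edges, n) is expected

    def test_self_edge_rejected(self):
        with pytest.raises(ValueError):
            d.is_acyclic([(1, 1)], 3)

    def test_matches_networkx_on_random_digraphs(self):
        import networkx as nx

        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(2, 7))
            pairs = [(u, v) for u in range(n) for v in range(n) if u != v]
            k = int(rng.integers(0, len(pairs) + 1))
            idx = rng.choice(len(pairs), size=k, replace=False)
            edges = [pairs[i] for i in idx]
            g = nx.DiGraph()
            g.add_nodes_from(range(n))
            g.add_edges_from(edges)
            assert d.is_acyclic(edges, n) == nx.is_directed_acyclic_graph(g)


class TestDagStructure:
    def test_equality_is_by_edge_set(self):
        a = d.DagStructure(3, [(0, 1), (1, 2)])
        b = d.DagStructure(3, [(1, 2), (0, 1)])
        assert a == b and hash(a) == hash(b)

    def test_cyclic_rejected(self):
        with pytest.raises(ValueError):
            d.DagStructure(3, [(0, 1), (1, 2), (2, 0)])

    def test_antiparallel_rejected(self):
        with pytest.raises(ValueError):
            d.DagStructure(2, [(0, 1), (1, 0)])

    def test_adjacency_is_readonly(self):
        g = d.DagStructure(2, [(0, 1)])
        with pytest.raises(ValueError):
            g.adjacency[0, 1] = False


class TestApplyMove:
    def test_addition(self):
        g = d.apply_move(d.DagStructure(2), d.EdgeMove(ADDITION, (0, 1)))
        assert g.edges == {(0, 1)}

    def test_reversal(self):
        g = d.apply_move(d.DagStructure(2, [(0, 1)]), d.EdgeMove(REVERSAL, (0, 1)))
        assert g.edges == {(1, 0)}

    def test_deletion(self):
        g = d.apply_move(d.DagStructure(2, [(0, 1)]), d.EdgeMove(DELETION, (0, 1)))
        assert g.edges == frozenset()

    def test_input_unchanged(self):
        g = d.DagStructure(2, [(0, 1)])
        d.apply_move(g, d.EdgeMove(DELETION, (0, 1)))
        assert g.edges == {(0, 1)}

    @pytest.mark.parametrize(
        "edges,move",
        [
            ([(0, 1)], d.EdgeMove(ADDITION, (0, 1))),  # already present
            ([(0, 1)], d.EdgeMove(ADDITION, (1, 0))),  # antiparallel
            ([], d.EdgeMove(DELETION, (0, 1))),  # missing
            ([], d.EdgeMove(REVERSAL, (0, 1))),  # missing
        ],
    )
    def test_inapplicable_moves_raise(self, edges, move):
        with pytest.raises(ValueError):
            d.apply_move(d.DagStructure(3, edges), move)

    def test_cycle_creating_moves_raise(self):
        g = d.DagStructure(3, [(0, 1), (1, 2)])
        with pytest.raises(ValueError):
            d.apply_move(g, d.EdgeMove(ADDITION, (2, 0)))
        g2 = d.DagStructure(3, [(0, 1), (1, 2), (0, 2)])
        with pytest.raises(ValueError):
            d.apply_move(g2, d.EdgeMove(REVERSAL, (0, 2)))

    def test_move_then_inverse_restores(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            g = d.random_dag(5, 0.4, rng=rng)
            for mv in d.enumerate_neighborhood(g):
                back = d.apply_move(d.apply_move(g, mv), mv.inverse())
                assert back == g


class TestNeighborhood:
    def test_empty_dag_all_additions(self):
        moves = d.enumerate_neighborhood(d.DagStructure(3))
        assert len(moves) == 6
        assert all(m.kind == ADDITION for m in moves)

    def test_complete_three_node(self):
        g = d.DagStructure(3, [(0, 1), (0, 2), (1, 2)])
        moves = d.enumerate_neighborhood(g)
        kinds = sorted(m.kind for m in moves)
        assert len(moves) == 5
        assert kinds.count(DELETION) == 3
        # reversing the covering edge (0,2) would create a cycle
        assert {m.edge for m in moves if m.kind == REVERSAL} == {(0, 1), (1, 2)}

    def test_single_edge_two_nodes(self):
        moves = d.enumerate_neighborhood(d.DagStructure(2, [(0, 1)]))
        assert {(m.kind, m.edge) for m in moves} == {
            (DELETION, (0, 1)),
            (REVERSAL, (0, 1)),
        }

    @pytest.mark.parametrize("n,expected", [(3, 6), (11, 110)])
    def test_empty_dag_size_formula(self, n, expected):
        assert d.neighborhood_size(d.DagStructure(n)) == n * (n - 1)

    def test_deterministic_order(self):
        g = d.DagStructure(4, [(0, 1), (2, 3)])
        a = d.enumerate_neighborhood(g)
        b = d.enumerate_neighborhood(g)
        assert a == b
        keys = [(m.kind, m.edge) for m in a]
        assert keys == sorted(keys)

    @pytest.mark.parametrize("max_fanin", [None, 1, 2])
    def test_matches_brute_force_oracle(self, max_fanin):
        rng = np.random.default_rng(3)
        for _ in range(60):
            n = int(rng.integers(2, 7))
            g = d.random_dag(n, float(rng.random()), rng=rng, max_fanin=max_fanin)
            mine = sorted((m.kind, m.edge) for m in d.enumerate_neighborhood(g, max_fanin))
            assert mine == brute_force_neighborhood(g, max_fanin)
            assert d.neighborhood_size(g, max_fanin) == len(mine)

    @pytest.mark.parametrize("max_fanin", [None, 2])
    def test_neighborhood_symmetry(self, max_fanin):
        """G' one move from G iff G one move from G' (with or without cap)."""
        rng = np.random.default_rng(4)
        for _ in range(30):
            g = d.random_dag(5, 0.4, rng=rng, max_fanin=max_fanin)
            for mv in d.enumerate_neighborhood(g, max_fanin):
                h = d.apply_move(g, mv)
                back = {
                    d.apply_move(h, m2) for m2 in d.enumerate_neighborhood(h, max_fanin)
                }
                assert g in back

    def test_all_results_acyclic_and_capped(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            g = d.random_dag(6, 0.5, rng=rng, max_fanin=2)
            for mv in d.enumerate_neighborhood(g, 2):
                h = d.apply_move(g, mv)  # apply_move validates acyclicity
                assert int(h.adjacency.sum(axis=0).max()) <= 2


class TestIO:
    def test_edge_list_round_trip(self, tmp_path):
        g = d.DagStructure(4, [(0, 1), (2, 3), (0, 3)])
        path = tmp_path / "dag.tsv"
        from dagmcmc.dag import read_edge_list, write_edge_list

        write_edge_list(g, path)
        assert read_edge_list(path, n_nodes=4) == g

    def test_adjacency_round_trip(self, tmp_path):
        from dagmcmc.dag import read_adjacency_csv, write_adjacency_csv

        g = d.DagStructure(3, [(0, 2), (1, 2)])
        path = tmp_path / "adj.csv"
        write_adjacency_csv(g, path)
        assert read_adjacency_csv(path) == g

    def test_dot_export_mentions_edges(self):
        from dagmcmc.dag import to_dot

        text = to_dot(d.DagStructure(2, [(0, 1)], node_labels=["A", "B"]))
        assert "n0 -> n1" in text and '"A"' in text
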