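import numpy as np
import networkx as nx
import pytest

from dnfe.data_io import ExpressionMatrix
from dnfe.local_modules import (
    NeighborScore,
    crossover_strength,
    extract_module,
    perturbed_pcc_weight,
    select_local_network,
)
from conftest import eq4_weight_bruteforce, random_expression


def digraph(edges):
    g = nx.DiGraph()
    g.add_edges_from(edges)
    return g


class TestExtractModule:
    def test_chain(self):
        m = extract_module(digraph([("a", "b"), ("b", "c")]), "b")
        assert m.out_neighbors == ["c"] and m.in_neighbors == ["a"]
        assert m.second_order_in["a"] == []  # center excluded
        assert m.second_order_out["a"] == []

    def test_star_center(self):
        edges = [("hub", f"n{i}") for i in range(4)]
        m = extract_module(digraph(edges), "hub")
        assert len(m.out_neighbors) == 4 and m.in_neighbors == []

    def test_matches_breadth_two_traversal_oracle(self, rng):
        nodes = [f"v{i}" for i in range(12)]
        edges = [(a, b) for a in nodes for b in nodes
                 if a != b and rng.random() < 0.2]
        net = digraph(edges)
        net.add_nodes_from(nodes)
        out_of = {v: {b for a, b in edges if a == v} for v in nodes}
        in_of = {v: {a for a, b in edges if b == v} for v in nodes}
        for center in nodes:
            m = extract_module(net, center)
            assert set(m.out_neighbors) == out_of[center]
            assert set(m.in_neighbors) == in_of[center]
            for nb in set(m.out_neighbors) | set(m.in_neighbors):
                assert set(m.second_order_out[nb]) == out_of[nb] - {center}
                assert set(m.second_order_in[nb]) == in_of[nb] - {center}
        with pytest.raises(KeyError):
            extract_module(net, "missing")


class TestPerturbedPccWeight:
    def test_case_at_reference_means_leaves_pcc_unchanged(self, rng):
        ref = random_expression(rng, 2, 8)
        case = {g: float(ref.values[i].mean()) for i, g in enumerate(ref.gene_ids)}
        w = perturbed_pcc_weight(ref.gene_ids[0], ref.gene_ids[1], ref, case)
        assert w == pytest.approx(0.0, abs=1e-12)

    def test_matches_from_scratch_oracle(self, rng):
        for _ in range(10):
            ref = random_expression(rng, 2, 8)
            case = rng.uniform(0.5, 3.0, 2)
            got = perturbed_pcc_weight("g0", "g1", ref, case)
            want = eq4_weight_bruteforce(ref.values[0], ref.values[1],
                                         case[0], case[1])
            assert got == pytest.approx(want, rel=1e-9)

    def test_collinear_reference_clamps_denominator(self):
        ref = ExpressionMatrix(["a", "b"], [f"s{i}" for i in range(5)],
                               np.array([[1, 2, 3, 4, 5.0],
                                         [2, 4, 6, 8, 10.0]]))
        with pytest.warns(UserWarning, match="clamped"):
            w = perturbed_pcc_weight("a", "b", ref, {"a": 10.0, "b": 3.0})
        assert np.isfinite(w) and w >= 0


class TestCrossoverStrength:
    def test_unit_directional_sums_give_unit_strength(self):
        # lambda = 1/5; neighbor with edges in both directions has
        # D_in = D_out = 1, hence D = 1
        net = digraph([("c", "j"), ("u", "j"), ("j", "w"), ("j", "z")])
        m = extract_module(net, "c")
        score = crossover_strength(m, "j", lambda a, b: 2.5, lam=0.2)
        assert (score.D_in, score.D_out, score.D) == (1.0, 1.0, 1.0)

    def test_no_second_order_edges_gives_zero(self):
        m = extract_module(digraph([("c", "j")]), "c")
        score = crossover_strength(m, "j", {}, lam=0.2)
        assert score.D == 0.0

    def test_hand_summed_normalized_weights(self):
        # neighbor j: 2 second-order in-edges, 3 out-edges; each directional
        # weight set normalizes to sum 1 regardless of the raw weights
        net = digraph([("c", "j"), ("a", "j"), ("b", "j"),
                       ("j", "x"), ("j", "y"), ("j", "z")])
        m = extract_module(net, "c")
        weights = {("a", "j"): 0.7, ("b", "j"): 0.3,
                   ("j", "x"): 5.0, ("j", "y"): 1.0, ("j", "z"): 4.0}
        score = crossover_strength(m, "j", weights, lam=0.2)
        assert score.D_in == pytest.approx(0.7 / 1.0 + 0.3 / 1.0)
        assert score.D_out == pytest.approx((5 + 1 + 4) / 10.0)
        assert score.D == pytest.approx(0.2 * 1.0 + 0.8 * 1.0)

    def test_strength_bounded_in_unit_interval(self, rng):
        nodes = [f"v{i}" for i in range(10)]
        edges = [(a, b) for a in nodes for b in nodes
                 if a != b and rng.random() < 0.25]
        net = digraph(edges)
        m = extract_module(net, nodes[0])
        for nb in m.first_order:
            d = crossover_strength(m, nb, lambda a, b: rng.uniform(0.1, 5), 0.2).D
            assert 0.0 <= d <= 1.0


class TestSelectLocalNetwork:
    def test_keeps_all_when_fewer_than_l(self):
        net = digraph([("c", "a"), ("c", "b"), ("d", "c")])
        m = extract_module(net, "c")
        scores = [NeighborScore(g, 1, 1, 0.2) for g in m.first_order]
        ln = select_local_network(m, scores, l=5)
        assert ln.a_k + ln.b_k == 3

    def test_ties_break_lexicographically(self):
        net = digraph([("c", "b"), ("c", "a"), ("c", "d")])
        m = extract_module(net, "c")
        scores = [NeighborScore(g, 0.5, 0.5, 0.2) for g in m.first_order]
        ln = select_local_network(m, scores, l=2)
        assert ln.out_selected == ["a", "b"]

    def test_matches_full_sort_oracle_and_input_order_invariance(self, rng):
        nodes = [f"v{i:02d}" for i in range(11)]
        center = nodes[0]
        edges = [(center, g) for g in nodes[1:6]] + [(g, center) for g in nodes[6:]]
        m = extract_module(digraph(edges), center)
        d_values = {g: float(rng.random()) for g in m.first_order}
        scores = [NeighborScore(g, d_values[g], d_values[g], 0.5)
                  for g in m.first_order]
        ln = select_local_network(m, scores, l=4)
        ranked = sorted(m.first_order, key=lambda g: (-d_values[g], g))[:4]
        assert sorted(ln.out_selected + ln.in_selected) == sorted(ranked)
        shuffled = list(scores)
        rng.shuffle(shuffled)
        ln2 = select_local_network(m, shuffled, l=4)
        assert (ln2.out_selected, ln2.in_selected) == (ln.out_selected, ln.in_selected)
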