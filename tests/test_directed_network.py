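import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dnfe.data_io import ExpressionMatrix
from dnfe.directed_network import (
    build_backbone,
    direction_index,
    mutual_information,
    orient_edges,
)
from conftest import mi_bruteforce, pearson_bruteforce, random_expression


class TestMutualInformation:
    def test_perfect_separation_is_log_two(self):
        # all case values above all reference values, equal group sizes,
        # 2 bins split at the gap
        x = [1.0, 1.1, 1.2, 1.3, 9.0, 9.1, 9.2, 9.3]
        y = [0, 0, 0, 0, 1, 1, 1, 1]
        assert mutual_information(x, y, bins=2) == pytest.approx(math.log(2), abs=1e-12)

    def test_independent_profile_gives_zero(self):
        # identical value multiset within both label groups
        x = [1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0]
        y = [0, 0, 0, 0, 1, 1, 1, 1]
        assert mutual_information(x, y, bins=2) == pytest.approx(0.0, abs=1e-12)

    def test_matches_joint_count_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.integers(0, 2, 12)
            if y.min() == y.max():
                continue
            got = mutual_information(x, y, bins=3)
            assert got == pytest.approx(mi_bruteforce(x, y, 3), rel=1e-9, abs=1e-12)

    def test_constant_profile_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            assert mutual_information([2.0] * 8, [0, 1] * 4, bins=3) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            mutual_information([1.0, 2.0, 3.0, 4.0], [0, 1, 0], bins=2)

    def test_invariant_under_monotone_relabeling(self, rng):
        x = rng.normal(size=15)
        y = rng.integers(0, 2, 15)
        base = mutual_information(x, y, bins=4)
        for f in (np.exp, lambda v: v ** 3, lambda v: 10 * v + 2):
            assert mutual_information(f(x), y, bins=4) == pytest.approx(base, abs=1e-12)

    def test_invariant_under_joint_permutation(self, rng):
        x = rng.normal(size=14)
        y = rng.integers(0, 2, 14)
        perm = rng.permutation(14)
        assert mutual_information(x[perm], y[perm], bins=4) == pytest.approx(
            mutual_information(x, y, bins=4), abs=1e-12
        )


class TestDirectionIndex:
    def test_identical_profiles_give_zero(self, rng):
        u = rng.normal(size=10)
        y = np.array([0] * 5 + [1] * 5)
        assert direction_index(u, u, y, bins=3) == pytest.approx(0.0, abs=1e-12)

    def test_constant_phenotype_gives_zero(self, rng):
        u, v = rng.normal(size=10), rng.normal(size=10)
        assert direction_index(u, v, np.zeros(10, dtype=int), bins=3) == 0.0

    def test_sharpening_partner_gives_positive_omega(self):
        # u alone barely separates y; averaging with v cancels the noise
        # component and sharpens the separation
        y = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        noise = np.array([1.0, -1.0, 1.5, -1.5, 0.5, -0.5, 1.2, -1.2, 0.8, -0.8])
        u = y * 1.0 + noise
        v = y * 1.0 - noise
        omega = direction_index(u, v, y, bins=2)
        assert omega > 0
        expected = mi_bruteforce((u + v) / 2, y, 2) - mi_bruteforce(u, y, 2)
        assert omega == pytest.approx(expected, rel=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_omega_asymmetry_identity(self, seed):
        # omega_ij - omega_ji == MI(V, y) - MI(U, y), both sides independent
        rng = np.random.default_rng(seed)
        u, v = rng.normal(size=12), rng.normal(size=12)
        y = np.array([0] * 6 + [1] * 6)
        lhs = direction_index(u, v, y, 3) - direction_index(v, u, y, 3)
        rhs = mi_bruteforce(v, y, 3) - mi_bruteforce(u, y, 3)
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-12)


class TestBackbone:
    def test_perfect_correlation_kept_any_power(self):
        expr = ExpressionMatrix(["a", "b"], [f"s{i}" for i in range(5)],
                                np.array([[1, 2, 3, 4, 5.0],
                                          [2, 4, 6, 8, 10.0]]))
        for power in (1, 2, 6, 12):
            g = build_backbone(expr, power=power, cutoff=0.99)
            assert g.has_edge("a", "b")
            assert g.edges["a", "b"]["weight"] == pytest.approx(1.0)

    def test_zero_correlation_gives_no_edge(self):
        expr = ExpressionMatrix(["a", "b"], [f"s{i}" for i in range(4)],
                                np.array([[1, -1, 1, -1.0],
                                          [1, 1, -1, -1.0]]))
        assert build_backbone(expr, power=2, cutoff=0.01).number_of_edges() == 0

    def test_matches_all_pairs_oracle_and_is_symmetric(self, rng):
        expr = random_expression(rng, 6, 10)
        g = build_backbone(expr, power=2.0, cutoff=0.3)
        for i, gi in enumerate(expr.gene_ids):
            for j, gj in enumerate(expr.gene_ids):
                if i >= j:
                    continue
                a = abs(pearson_bruteforce(expr.values[i], expr.values[j])) ** 2
                assert g.has_edge(gi, gj) == (a >= 0.3)
                assert g.has_edge(gi, gj) == g.has_edge(gj, gi)

    def test_zero_variance_gene_excluded_with_warning(self, rng):
        expr = random_expression(rng, 4, 8)
        expr.values[2] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            g = build_backbone(expr, power=2, cutoff=0.1)
        assert expr.gene_ids[2] not in g


class TestOrientEdges:
    def test_rule_matches_brute_force_on_toy(self, rng):
        expr = random_expression(rng, 5, 12)
        y = np.array([0] * 6 + [1] * 6)
        backbone = build_backbone(expr, power=1.0, cutoff=0.0)
        net = orient_edges(backbone, expr, y, bins=3)
        pos = {g: i for i, g in enumerate(expr.gene_ids)}
        for gi, gj in backbone.edges:
            u, v = expr.values[pos[gi]], expr.values[pos[gj]]
            omega_ij = mi_bruteforce((u + v) / 2, y, 3) - mi_bruteforce(u, y, 3)
            omega_ji = mi_bruteforce((u + v) / 2, y, 3) - mi_bruteforce(v, y, 3)
            assert net.has_edge(gi, gj) == (omega_ij > 0)
            assert net.has_edge(gj, gi) == (omega_ji > 0)
            if net.has_edge(gi, gj):
                assert net.edges[gi, gj]["omega"] == pytest.approx(omega_ij, rel=1e-9)

    def test_isolated_nodes_are_retained(self, rng):
        expr = random_expression(rng, 4, 8)
        backbone = build_backbone(expr, power=6, cutoff=1.0)  # no edges survive
        net = orient_edges(backbone, expr, np.array([0] * 4 + [1] * 4))
        assert set(net.nodes) == set(expr.gene_ids)
        assert net.number_of_edges() == 0
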