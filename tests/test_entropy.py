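import math

import numpy as np
import pytest

from dnfe.entropy import (
    LocalScore,
    directional_entropy,
    entropy_weights,
    global_dnfe,
    local_dnfe,
    normalize_neighbor_expression,
)
from dnfe.local_modules import LocalNetwork
from conftest import directional_entropy_bruteforce, random_expression


class TestNormalizeNeighborExpression:
    def test_constant_profile_becomes_uniform(self):
        np.testing.assert_allclose(
            normalize_neighbor_expression([2.0, 2.0, 2.0, 2.0]), [0.25] * 4
        )

    def test_all_zero_falls_back_to_uniform(self):
        np.testing.assert_allclose(
            normalize_neighbor_expression([0.0, 0.0, 0.0, 0.0]), [0.25] * 4
        )

    def test_random_positive_profile_sums_to_one(self, rng):
        x = rng.uniform(0.1, 5, 9)
        out = normalize_neighbor_expression(x)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(out, x / x.sum())

    def test_negative_values_shifted_before_scaling(self):
        out = normalize_neighbor_expression([-1.0, 0.0, 3.0])
        np.testing.assert_allclose(out, [0.0, 1 / 5, 4 / 5])


class TestEntropyWeights:
    def test_proportional_to_delta_w(self):
        np.testing.assert_allclose(entropy_weights([1.0, 3.0]), [0.25, 0.75])

    def test_equal_deltas_give_uniform(self):
        np.testing.assert_allclose(entropy_weights([0.7] * 4), [0.25] * 4)

    def test_all_zero_falls_back_to_uniform(self):
        np.testing.assert_allclose(entropy_weights([0.0, 0.0]), [0.5, 0.5])


class TestDirectionalEntropy:
    def test_single_neighbor_collapses_to_profile_entropy(self, rng):
        ref = random_expression(rng, 2, 6)
        case = rng.uniform(0.5, 3.0, 2)
        got = directional_entropy("g0", ["g1"], ref, case)
        xn = ref.values[1] / ref.values[1].sum()
        want = -np.sum(xn * np.log(xn + 1e-12)) / ref.n_samples
        assert got == pytest.approx(want, rel=1e-12)

    def test_empty_side_scores_zero(self, rng):
        ref = random_expression(rng, 2, 6)
        assert directional_entropy("g0", [], ref, np.ones(2)) == 0.0

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(10):
            ref = random_expression(rng, 4, 8)
            case = rng.uniform(0.5, 3.0, 4)
            got = directional_entropy("g0", ["g1", "g2", "g3"], ref, case)
            want = directional_entropy_bruteforce(
                ref.values[0], case[0],
                [ref.values[1], ref.values[2], ref.values[3]],
                [case[1], case[2], case[3]],
            )
            assert got == pytest.approx(want, rel=1e-9)

    def test_non_negative_on_random_instances(self, rng):
        for _ in range(20):
            ref = random_expression(rng, 5, 7)
            case = rng.uniform(0.0, 4.0, 5)
            assert directional_entropy("g0", ["g1", "g2", "g3", "g4"], ref, case) >= 0

    def test_scale_invariance(self, rng):
        ref = random_expression(rng, 4, 8)
        case = rng.uniform(0.5, 3.0, 4)
        base = directional_entropy("g0", ["g1", "g2"], ref, case)
        scaled_ref = random_expression(rng, 4, 8)
        scaled_ref.values[:] = ref.values * 37.5
        got = directional_entropy("g0", ["g1", "g2"], scaled_ref, case * 37.5)
        assert got == pytest.approx(base, rel=1e-9)

    def test_uniform_weights_maximize_entropy_for_identical_profiles(self, rng):
        # with identical neighbor profiles the score reduces to
        # (H_x + H(P)) / (n a_k), maximized by the uniform P — checked
        # against random points on the probability simplex
        from dnfe.entropy import _nfe

        profile = normalize_neighbor_expression(rng.uniform(0.5, 3.0, 8))
        xnorm = np.tile(profile, (3, 1))
        best = _nfe(xnorm, np.full(3, 1 / 3))
        for _ in range(200):
            p = rng.dirichlet([1.0, 1.0, 1.0])
            assert _nfe(xnorm, p) <= best + 1e-9


class TestLocalAndGlobalScores:
    def test_empty_local_network_scores_zero(self, rng):
        ref = random_expression(rng, 3, 6)
        ln = LocalNetwork("g0", [], [], l=10)
        assert local_dnfe(ln, ref, np.ones(3)).dnfe_local == 0.0

    def test_out_only_network_equals_out_entropy(self, rng):
        ref = random_expression(rng, 3, 6)
        case = rng.uniform(0.5, 3.0, 3)
        ln = LocalNetwork("g0", ["g1", "g2"], [], l=10)
        score = local_dnfe(ln, ref, case)
        assert score.dnfe_local == score.nfe_out
        assert score.nfe_in == 0.0

    def test_local_is_sum_of_directional_entropies(self, rng):
        ref = random_expression(rng, 5, 8)
        case = rng.uniform(0.5, 3.0, 5)
        ln = LocalNetwork("g0", ["g1", "g3"], ["g2", "g4"], l=10)
        score = local_dnfe(ln, ref, case)
        assert score.dnfe_local == pytest.approx(
            directional_entropy("g0", ["g1", "g3"], ref, case)
            + directional_entropy("g0", ["g2", "g4"], ref, case)
        )

    def test_global_mean(self, rng):
        assert global_dnfe([LocalScore("g", 0.3, 0.4)]) == pytest.approx(0.7)
        assert global_dnfe([0.5] * 7) == pytest.approx(0.5)
        vals = rng.uniform(0, 1, 50)
        assert global_dnfe(list(vals)) == pytest.approx(float(np.mean(vals)))

    def test_global_requires_scorable_genes(self):
        with pytest.raises(ValueError, match="m = 0"):
            global_dnfe([])
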