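import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import jensenshannon

from pvtree.distance import (
    DistanceMatrix,
    distance_matrix,
    js_distance,
    kl_divergence,
    normalize,
    read_phylip,
    write_phylip,
)
from pvtree.vectorize import PatternVector


def prob(*values):
    return normalize(np.array(values, dtype=float))


def random_prob_pairs(rng, n_pairs, dim=4):
    for _ in range(n_pairs):
        yield (
            normalize(rng.random(dim)),
            normalize(rng.random(dim)),
        )


class TestNormalize:
    def test_uniform(self):
        assert prob(2.0, 2.0).values.tolist() == [0.5, 0.5]

    def test_proportions(self):
        assert prob(3.0, 0.0, 1.0).values.tolist() == [0.75, 0.0, 0.25]

    def test_all_zero_flagged(self):
        p = prob(0.0, 0.0)
        assert p.is_zero and p.values.tolist() == [0.0, 0.0]

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            normalize(np.array([1.0, -0.5]))


class TestKL:
    def test_self_divergence_zero(self):
        p = prob(0.3, 0.7)
        assert kl_divergence(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_vs_uniform(self):
        assert kl_divergence(prob(1.0, 0.0), prob(0.5, 0.5)) == pytest.approx(1.0)

    def test_high_precision_value(self):
        # 0.5*log2(0.5/0.75) + 0.5*log2(0.5/0.25), evaluated independently
        expected = 0.5 * math.log2(0.5 / 0.75) + 0.5 * math.log2(0.5 / 0.25)
        got = kl_divergence(prob(0.5, 0.5), prob(0.75, 0.25))
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.2075187496, abs=1e-9)

    def test_zero_in_m_where_p_positive_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence(prob(0.5, 0.5), prob(1.0, 0.0))


class TestJS:
    def test_identity(self):
        p = prob(0.2, 0.8)
        assert js_distance(p, p) == 0.0

    def test_disjoint_supports_maximal(self):
        assert js_distance(prob(1.0, 0.0), prob(0.0, 1.0)) == 1.0

    def test_derived_value_against_direct_evaluation(self):
        # ½KL(P,M) + ½KL(Q,M) with M=(P+Q)/2, all in log2
        p, q = prob(0.5, 0.5), prob(1.0, 0.0)
        m = prob(0.75, 0.25)
        expected = 0.5 * kl_divergence(p, m) + 0.5 * kl_divergence(q, m)
        assert js_distance(p, q) == pytest.approx(expected, abs=1e-12)
        assert js_distance(p, q) == pytest.approx(0.3112781245, abs=1e-9)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(0)
        for p, q in random_prob_pairs(rng, 50):
            ours = js_distance(p, q)
            scipys = jensenshannon(p.values, q.values, base=2) ** 2
            assert ours == pytest.approx(scipys, abs=1e-9)

    def test_all_zero_conventions(self):
        z, nz = prob(0.0, 0.0), prob(0.5, 0.5)
        assert js_distance(z, nz) == 1.0
        assert js_distance(z, z) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            js_distance(prob(1.0), prob(0.5, 0.5))

    @given(st.integers(0, 10_000))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        p, q = next(random_prob_pairs(rng, 1))
        d1, d2 = js_distance(p, q), js_distance(q, p)
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert 0.0 <= d1 <= 1.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_sqrt_js_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        p = normalize(rng.random(5))
        q = normalize(rng.random(5))
        r = normalize(rng.random(5))
        ab = js_distance(p, q, sqrt=True)
        bc = js_distance(q, r, sqrt=True)
        ac = js_distance(p, r, sqrt=True)
        assert ac <= ab + bc + 1e-9

    def test_identity_of_indiscernibles(self):
        rng = np.random.default_rng(3)
        p = normalize(rng.random(6))
        q = normalize(p.values.copy())
        assert js_distance(p, q) <= 1e-12
        r = normalize(rng.random(6))
        assert js_distance(p, r) > 1e-9


class TestDistanceMatrix:
    def _vectors(self, rows, ids=None):
        return [
            PatternVector(sequence_id=ids[i] if ids else f"v{i}", values=np.array(r, dtype=float))
            for i, r in enumerate(rows)
        ]

    def test_identical_vectors_zero(self):
        m = distance_matrix(self._vectors([[1.0, 2.0], [1.0, 2.0]]))
        assert np.allclose(m.d, 0.0)

    def test_disjoint_supports_give_ones(self):
        m = distance_matrix(self._vectors([[1.0, 0.0], [0.0, 3.0]]))
        assert m.d[0, 1] == 1.0

    def test_entries_match_pairwise_calls(self):
        rng = np.random.default_rng(11)
        rows = rng.random((3, 6))
        m = distance_matrix(self._vectors(rows.tolist()))
        for i in range(3):
            for j in range(3):
                expected = js_distance(normalize(rows[i]), normalize(rows[j]))
                assert m.d[i, j] == pytest.approx(expected, abs=1e-12)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            distance_matrix(self._vectors([[1.0]]))

    def test_symmetry_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(labels=["a", "b"], d=np.array([[0.0, 1.0], [0.5, 0.0]]))

    def test_phylip_round_trip(self, tmp_path):
        m = distance_matrix(
            self._vectors([[1.0, 0.0, 1.0], [0.0, 2.0, 1.0], [1.0, 1.0, 0.0]],
                          ids=["alpha", "beta", "gamma"])
        )
        path = tmp_path / "dist.phy"
        write_phylip(m, path)
        again = read_phylip(path)
        assert again.labels == m.labels
        assert np.allclose(again.d, m.d, atol=1e-6)
        assert path.read_text().splitlines()[0] == "3"
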