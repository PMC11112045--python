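"""Structure learner: metric, sparsification, fusion, propagation, iteration."""

import numpy as np
import pytest

from gslmpp import (fuse_adjacency, gsl_iterate, micro_fixture, propagate,
                    sparsify, weighted_cosine)
from gslmpp.autodiff import Tensor
from gslmpp.exceptions import ConfigurationError


class TestWeightedCosine:
    def test_self_similarity_one(self):
        h = np.array([[1.0, 2.0], [1.0, 2.0]])
        s = weighted_cosine(h, np.ones((1, 2)))
        assert s[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_vectors_zero(self):
        h = np.array([[1.0, 0.0], [0.0, 1.0]])
        s = weighted_cosine(h, np.ones((1, 2)))
        assert s[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_two_perspectives_average_hand_case(self):
        h = np.array([[1.0, 1.0], [1.0, 0.0]])
        w = np.array([[1.0, 1.0], [2.0, 0.5]])

        def cos(a, b):
            return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

        expected = 0.5 * (cos(w[0] * h[0], w[0] * h[1]) +
                          cos(w[1] * h[0], w[1] * h[1]))
        s = weighted_cosine(h, w)
        assert s[0, 1] == pytest.approx(expected, abs=1e-9)

    def test_matches_double_loop_oracle(self, rng):
        """Naive per-pair cosine evaluation on random matrices up to 20 x 8."""
        for _ in range(20):
            n, d, m = rng.integers(2, 21), rng.integers(2, 9), rng.integers(1, 4)
            h = rng.standard_normal((n, d))
            w = rng.uniform(0.5, 2.0, size=(m, d))
            s = weighted_cosine(h, w)
            for i in range(n):
                for j in range(n):
                    vals = []
                    for p in range(m):
                        a, b = w[p] * h[i], w[p] * h[j]
                        vals.append(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
                    assert abs(s[i, j] - np.mean(vals)) < 1e-6

    def test_unit_weights_reduce_to_plain_cosine(self, rng):
        h = rng.standard_normal((15, 6))
        s = weighted_cosine(h, np.ones((1, 6)))
        hn = h / np.linalg.norm(h, axis=1, keepdims=True)
        assert np.max(np.abs(s - hn @ hn.T)) < 1e-6

    def test_zero_row_gets_zero_similarity(self):
        h = np.array([[0.0, 0.0], [1.0, 1.0]])
        s = weighted_cosine(h, np.ones((1, 2)))
        assert s[0, 1] == pytest.approx(0.0, abs=1e-5)


class TestSparsify:
    def test_zero_threshold_removes_negatives_only(self):
        s = np.array([[0.0, 0.5, -0.2], [0.5, 0.0, 0.0], [-0.2, 0.0, 0.0]])
        out = sparsify(s, 0.0)
        assert out[0, 1] == 0.5 and out[0, 2] == 0.0 and out[1, 2] == 0.0

    def test_hand_thresholding(self):
        s = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, -0.4], [0.1, -0.4, 1.0]])
        out = sparsify(s, 0.2)
        assert out[0, 1] == 0.9
        assert out[0, 2] == 0.0 and out[1, 2] == 0.0
        assert np.all(np.diag(out) == 0.0)  # diagonal always zeroed

    def test_threshold_above_one_empties(self, rng):
        h = rng.standard_normal((6, 4))
        s = weighted_cosine(h, np.ones((1, 4)))
        assert not sparsify(s, 1.1).any()

    def test_edge_set_monotone_in_threshold(self, rng):
        s = weighted_cosine(rng.standard_normal((10, 4)), np.ones((1, 4)))
        prev = None
        for eps in (0.0, 0.2, 0.5, 0.9):
            edges = set(zip(*np.nonzero(sparsify(s, eps))))
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_negative_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            sparsify(np.zeros((2, 2)), -0.1)


class TestFuseAdjacency:
    def setup_method(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(0, 1, size=(6, 6))
        self.a0 = (base + base.T) / 2
        np.fill_diagonal(self.a0, 0)
        self.a1 = sparsify(weighted_cosine(rng.standard_normal((6, 3)),
                                           np.ones((1, 3))), 0.1)
        self.at = sparsify(weighted_cosine(rng.standard_normal((6, 3)),
                                           np.ones((1, 3))), 0.1)

    def test_lambda_one_returns_a0(self):
        np.testing.assert_array_equal(
            fuse_adjacency(self.a0, self.a1, self.at, 1.0, 0.3), self.a0)

    def test_lambda_zero_eta_one_returns_at(self):
        np.testing.assert_array_equal(
            fuse_adjacency(self.a0, self.a1, self.at, 0.0, 1.0), self.at)

    def test_scalar_hand_case(self):
        # 0.8*1 + 0.2*(0.5*0.5 + 0.5*0.3) = 0.88
        out = fuse_adjacency(np.array([[1.0]]), np.array([[0.3]]),
                             np.array([[0.5]]), 0.8, 0.5)
        assert out[0, 0] == pytest.approx(0.88)

    def test_convex_combination_stays_in_range_and_symmetric(self):
        out = fuse_adjacency(self.a0, self.a1, self.at, 0.7, 0.4)
        assert np.all(out >= 0.0) and np.all(out <= 1.0)
        np.testing.assert_allclose(out, out.T)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ConfigurationError):
            fuse_adjacency(self.a0, self.a1, np.zeros((3, 3)), 0.5, 0.5)

    def test_invalid_weights_raise(self):
        with pytest.raises(ConfigurationError):
            fuse_adjacency(self.a0, self.a1, self.at, 1.2, 0.5)


class TestPropagate:
    def test_identity_adjacency_is_relu(self):
        x = np.array([[1.0, -2.0], [3.0, -4.0]])
        out = propagate(x, np.eye(2), [np.eye(2)], normalize=False)
        np.testing.assert_array_equal(out, np.maximum(x, 0.0))

    def test_zero_adjacency_annihilates(self):
        x = np.ones((3, 2))
        out = propagate(x, np.zeros((3, 3)), [np.eye(2)], normalize=False)
        assert not out.any()

    def test_two_node_swap(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        adj = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = propagate(x, adj, [np.eye(2)], normalize=False)
        np.testing.assert_array_equal(out, x[::-1])

    def test_zero_layers_raise(self):
        with pytest.raises(ConfigurationError):
            propagate(np.ones((2, 2)), np.eye(2), [], normalize=False)

    def test_normalized_mode_bounded_on_dense_graph(self, rng):
        x = rng.uniform(0, 1, size=(30, 8))
        adj = rng.uniform(0, 1, size=(30, 30))
        adj = (adj + adj.T) / 2
        np.fill_diagonal(adj, 0)
        out = propagate(x, adj, [np.eye(8)] * 3, normalize=True)
        assert np.all(np.isfinite(out)) and np.max(out) < x.max() * 2


class TestGslIterate:
    def _inputs(self, rng, n=5, d=3):
        x = rng.standard_normal((n, d))
        a0 = rng.uniform(0, 1, size=(n, n))
        a0 = (a0 + a0.T) / 2
        np.fill_diagonal(a0, 0)
        return x, a0

    def test_t1_fusion_collapses_eta(self, rng):
        """At T = 1, eta drops out: fused = lam*A0 + (1-lam)*A1 for any eta."""
        x, a0 = self._inputs(rng)
        kw = dict(perspective_weights=np.ones((1, 3)), epsilon_sparsify=0.2,
                  lam=0.8, layer_weights=[np.eye(3)], T=1, normalize=False)
        out_a = gsl_iterate(x, a0, eta=0.1, **kw)
        out_b = gsl_iterate(x, a0, eta=0.9, **kw)
        np.testing.assert_allclose(out_a.A_fused, out_b.A_fused, atol=1e-12)
        expected = 0.8 * a0 + 0.2 * out_a.A1
        np.testing.assert_allclose(out_a.A_fused, expected, atol=1e-12)

    def test_deterministic(self, rng):
        x, a0 = self._inputs(rng)
        kw = dict(perspective_weights=np.ones((2, 3)) * 1.1, epsilon_sparsify=0.1,
                  lam=0.7, eta=0.4, layer_weights=[np.eye(3), np.eye(3)], T=2)
        a = gsl_iterate(x, a0, **kw)
        b = gsl_iterate(x, a0, **kw)
        np.testing.assert_array_equal(a.H_r, b.H_r)
        np.testing.assert_array_equal(a.A_fused, b.A_fused)

    def test_fused_symmetric_in_unit_range_every_round(self, rng):
        x, a0 = self._inputs(rng, n=8, d=4)
        state = gsl_iterate(x, a0, np.ones((2, 4)), 0.1, 0.6, 0.5,
                            [np.eye(4)], T=3, record_trace=True)
        for info in state.trace:
            fused = info["A_fused"]
            np.testing.assert_allclose(fused, fused.T, atol=1e-12)
            assert np.all(fused >= 0.0) and np.all(fused <= 1.0 + 1e-12)

    def test_gradient_flows_through_iteration(self, rng):
        x_arr, a0 = self._inputs(rng)
        x = Tensor(x_arr, requires_grad=True)
        w = Tensor(np.ones((1, 3)), requires_grad=True)
        state = gsl_iterate(x, a0, w, 0.1, 0.5, 0.5,
                            [Tensor(np.eye(3), requires_grad=True)], T=2)
        loss = state.H_r.sum()
        loss.backward()
        assert x.grad is not None and np.any(x.grad != 0)
        assert w.grad is not None


class TestMicroFixtureTrace:
    """Full T = 2 refinement trace against a straight-line oracle."""

    @staticmethod
    def straight_line_oracle(fx):
        """Independent loop-free re-derivation of the two-round recurrence."""
        x_r, a0 = fx["X_r"], fx["A0"]
        lam, eta, eps = fx["lam"], fx["eta"], fx["epsilon_sparsify"]
        trace = []
        h = x_r
        a1 = None
        for t in (1, 2):
            norm = np.sqrt((h ** 2).sum(axis=1))
            s = (h @ h.T) / np.outer(norm, norm)
            a_t = np.where(s >= eps, s, 0.0)
            np.fill_diagonal(a_t, 0.0)
            if t == 1:
                a1 = a_t
            a_f = lam * a0 + (1 - lam) * (eta * a_t + (1 - eta) * a1)
            h = np.maximum(a_f @ np.maximum(a_f @ x_r, 0.0), 0.0)
            trace.append({"A_t": a_t, "A_fused": a_f, "H": h})
        return trace

    def test_fixture_a0_symmetric_zero_diagonal(self):
        a0 = micro_fixture()["A0"]
        np.testing.assert_array_equal(a0, a0.T)
        assert np.all(np.diag(a0) == 0.0)

    def test_t1_fused_matches_collapsed_fusion(self):
        fx = micro_fixture()
        state = gsl_iterate(fx["X_r"], fx["A0"], fx["perspective_weights"],
                            fx["epsilon_sparsify"], fx["lam"], fx["eta"],
                            fx["layer_weights"], T=1, normalize=False,
                            record_trace=True)
        expected = fx["lam"] * fx["A0"] + (1 - fx["lam"]) * state.A1
        np.testing.assert_allclose(state.A_fused, expected, atol=1e-12)

    def test_full_trace_matches_oracle_and_frozen_values(self):
        fx = micro_fixture()
        state = gsl_iterate(fx["X_r"], fx["A0"], fx["perspective_weights"],
                            fx["epsilon_sparsify"], fx["lam"], fx["eta"],
                            fx["layer_weights"], fx["T"], normalize=fx["normalize"],
                            record_trace=True)
        oracle = self.straight_line_oracle(fx)
        assert len(state.trace) == len(oracle) == len(fx["expected_trace"]) == 2
        for got, exp_oracle, exp_frozen in zip(state.trace, oracle,
                                               fx["expected_trace"]):
            for key in ("A_t", "A_fused", "H"):
                np.testing.assert_allclose(got[key], exp_oracle[key], atol=1e-6)
                np.testing.assert_allclose(got[key], exp_frozen[key], atol=1e-6)
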