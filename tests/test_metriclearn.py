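"""Kernel-metric optimisation: cost, gradient, PSD projection, alternation."""

import numpy as np
import pytest

from dtiseg import (OptimizerParams, adapt_step, cost, learn, make_phantom,
                    metric_gradient, psd_project)
from dtiseg.graph import normalized_laplacian, weights_learned
from dtiseg.metriclearn import learn_on_graph
from dtiseg.simulate import PhantomSpec


def random_psd4(rng, scale=1.0):
    a = rng.normal(size=(4, 4))
    return scale * (a @ a.T) / 4.0


def random_edge_structure(rng, n):
    """Connected random graph with random distance vectors in [0, 1]."""
    edges = {(int(min(i, j)), int(max(i, j)))
             for i, j in ((k, rng.integers(0, k)) for k in range(1, n))}
    for _ in range(n):
        i, j = rng.integers(0, n, 2)
        if i != j:
            edges.add((int(min(i, j)), int(max(i, j))))
    edges = np.array(sorted(edges))
    dvecs = rng.random((len(edges), 4))
    return edges, dvecs


def cost_of_metric(f, edges, dvecs, M, n):
    W = weights_learned(edges, dvecs, M, n=n)
    return cost(f, normalized_laplacian(W))


class TestCost:
    def test_constant_scores_on_connected_graph(self, rng):
        n = 6
        edges, dvecs = random_edge_structure(rng, n)
        W = weights_learned(edges, dvecs, np.eye(4), n=n)
        L = normalized_laplacian(W)
        deg = np.asarray(W.sum(1)).ravel()
        # the Laplacian null vector: degree-scaled constants cost nothing
        f = np.sqrt(deg)
        assert abs(cost(f, L)) < 1e-10

    def test_zero_metric_equals_unit_weight_graph(self, rng):
        n = 6
        edges, dvecs = random_edge_structure(rng, n)
        f = rng.normal(size=n)
        from dtiseg.graph import _weights_to_sparse
        W_unit = _weights_to_sparse(edges, np.ones(len(edges)), n)
        direct = cost(f, normalized_laplacian(W_unit))
        via_metric = cost_of_metric(f, edges, dvecs, np.zeros((4, 4)), n)
        assert np.isclose(via_metric, direct, rtol=1e-12)

    def test_nonnegative(self, rng):
        n = 8
        edges, dvecs = random_edge_structure(rng, n)
        for _ in range(5):
            f = rng.normal(size=n)
            assert cost_of_metric(f, edges, dvecs, random_psd4(rng), n) >= 0


class TestMetricGradient:
    def finite_difference(self, f, edges, dvecs, M, n, h=1e-6):
        # symmetric-pair perturbation: the cost depends on M only through
        # d^T M d, so this recovers the per-entry derivative exactly
        G = np.zeros((4, 4))
        for k in range(4):
            for l in range(4):
                E = np.zeros((4, 4))
                E[k, l] += h / 2
                E[l, k] += h / 2
                up = cost_of_metric(f, edges, dvecs, M + E, n)
                dn = cost_of_metric(f, edges, dvecs, M - E, n)
                G[k, l] = (up - dn) / (2 * h)
        return G

    def test_zero_scores_zero_gradient(self, rng):
        edges, dvecs = random_edge_structure(rng, 6)
        G = metric_gradient(np.zeros(6), edges, dvecs, np.eye(4))
        np.testing.assert_allclose(G, 0.0)

    def test_matches_finite_differences(self, rng):
        """Central-difference oracle on random graphs (the correctness gate)."""
        for _ in range(8):
            n = int(rng.integers(4, 15))
            edges, dvecs = random_edge_structure(rng, n)
            f = rng.normal(size=n)
            M = random_psd4(rng) + 0.1 * np.eye(4)
            G = metric_gradient(f, edges, dvecs, M)
            G_fd = self.finite_difference(f, edges, dvecs, M, n)
            denom = max(np.abs(G_fd).max(), 1e-12)
            assert np.abs(G - G_fd).max() / denom < 1e-5

    def test_frozen_degree_variant_on_single_edge(self):
        """One edge, f = (1, -1), M = I, d = e1: hand-computed gradient.

        With degrees frozen at d0 = d1 = w the off-diagonal coupling is
        S = 2 w g0 g1 = -2 (g = f / sqrt(w)), so dJ/dw through the direct
        path alone is -dS/dw = 2/w, and chaining dw/dM = -w d d^T gives
        dJ/dM = -2 d d^T exactly, independent of w.
        """
        edges = np.array([[0, 1]])
        d = np.array([[1.0, 0.0, 0.0, 0.0]])
        G = metric_gradient(np.array([1.0, -1.0]), edges, d, np.eye(4),
                            freeze_degree=True)
        np.testing.assert_allclose(G, -2.0 * np.outer(d[0], d[0]),
                                   rtol=1e-10)
        # the exact gradient is zero: a single normalized edge has
        # cost 4 regardless of its weight
        G_exact = metric_gradient(np.array([1.0, -1.0]), edges, d, np.eye(4))
        np.testing.assert_allclose(G_exact, 0.0, atol=1e-12)

    def test_weight_derivative_hand_value(self):
        """dw/dM_11 at M = I, d = e1 is -e^{-1} (differentiating
        exp(-d^T M d) by hand); checked by finite differences of w."""
        d = np.array([1.0, 0.0, 0.0, 0.0])
        h = 1e-7

        def w(M):
            return np.exp(-d @ M @ d)

        E = np.zeros((4, 4))
        E[0, 0] = h
        fd = (w(np.eye(4) + E) - w(np.eye(4) - E)) / (2 * h)
        assert np.isclose(fd, -np.exp(-1.0), rtol=1e-6)


class TestPsdProject:
    def test_psd_fixed_point(self, rng):
        M = random_psd4(rng)
        np.testing.assert_allclose(psd_project(M), M, atol=1e-12)

    def test_diagonal_clamp(self):
        np.testing.assert_allclose(psd_project(np.diag([2.0, -1.0, 0.0, 3.0])),
                                   np.diag([2.0, 0.0, 0.0, 3.0]), atol=1e-12)

    def test_nearest_point_property(self, rng):
        A = rng.normal(size=(4, 4))
        M = (A + A.T) / 2.0
        P0 = psd_project(M)
        d0 = np.linalg.norm(M - P0)
        for _ in range(100):
            P = random_psd4(rng, scale=rng.uniform(0.1, 3.0))
            assert d0 <= np.linalg.norm(M - P) + 1e-12

    def test_symmetrises_input(self):
        M = np.diag([1.0, 1.0, 1.0, 1.0])
        M[0, 1] = 0.4  # asymmetric
        out = psd_project(M)
        np.testing.assert_allclose(out, out.T)
        assert np.isclose(out[0, 1], 0.2)


class TestAdaptStep:
    def test_decrease_doubles(self):
        assert adapt_step(5.0, 4.0, 0.01) == (0.02, True)

    def test_increase_halves_and_rejects(self):
        assert adapt_step(4.0, 5.0, 0.02) == (0.01, False)

    def test_tie_rejects(self):
        alpha, ok = adapt_step(4.0, 4.0, 0.02)
        assert not ok and alpha == 0.01


class TestLearn:
    def test_orientation_only_contrast_upweights_orientation(self):
        """ROI differs from background only in principal orientation: the
        learned metric concentrates weight on the orientation component."""
        spec = PhantomSpec(roi_eigenvalues=(1.7e-3, 0.3e-3, 0.3e-3),
                           bg_eigenvalues=(1.7e-3, 0.3e-3, 0.3e-3),
                           roi_orientations=(90.0,), bg_orientations=(0.0,))
        field, truth, seeds = make_phantom(spec)
        res = learn(field, seeds)
        share0 = 0.25  # identity initialisation
        assert res.M[3, 3] / np.trace(res.M) > share0
        assert np.array_equal(res.seg, truth)

    def test_converges_quickly_on_clean_phantom(self, phantom):
        field, truth, seeds = phantom
        res = learn(field, seeds)
        assert res.converged
        assert res.n_iter <= 15

    def test_accepted_costs_non_increasing(self, phantom):
        field, truth, seeds = phantom
        res = learn(field, seeds)
        costs = res.trace.accepted_costs()
        assert np.all(np.diff(costs) <= 1e-12)

    def test_metric_stays_psd(self, phantom):
        field, truth, seeds = phantom
        res = learn(field, seeds)
        for ev in res.trace.metric_eigenvalues:
            assert np.min(ev) >= -1e-10

    def test_immediate_stop_when_already_optimal(self):
        """Maximally separable phantom: the initial solve is already at a
        near-zero cost, so the first alternation's decrease is < eps."""
        spec = PhantomSpec(roi_orientations=(90.0,), bg_orientations=(0.0,))
        field, truth, seeds = make_phantom(spec)
        res = learn(field, seeds)
        assert res.converged
        assert res.n_iter <= 2

    def test_deterministic(self, phantom):
        field, truth, seeds = phantom
        r1 = learn(field, seeds)
        r2 = learn(field, seeds)
        np.testing.assert_array_equal(r1.M, r2.M)
        np.testing.assert_array_equal(r1.f, r2.f)

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            OptimizerParams(alpha0=-1.0)
        with pytest.raises(ValueError):
            OptimizerParams(eps=0.0)
        with pytest.raises(ValueError):
            OptimizerParams(M0=np.diag([1.0, 1.0, 1.0, -1.0]))
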