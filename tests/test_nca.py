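"""Neighbourhood component analysis: objective, gradient, fitting, selection."""

import numpy as np
import pytest

from gaitkinetics.nca import (
    NcaFeatureSelector,
    fit_nca,
    nca_gradient,
    nca_objective,
    select_features,
)


def brute_force_objective(w, X, y, sigma, lam):
    """Independent pair-by-pair evaluation of the NCA objective."""
    n, p = X.shape
    w2 = np.asarray(w) ** 2
    total = 0.0
    for i in range(n):
        ks, losses = [], []
        for j in range(n):
            if j == i:
                continue
            d = sum(w2[r] * abs(X[i, r] - X[j, r]) for r in range(p))
            ks.append(np.exp(-d / sigma))
            losses.append(abs(y[i] - y[j]))
        ksum = sum(ks)
        total += sum(k / ksum * l for k, l in zip(ks, losses))
    return total / n + lam * float(np.sum(w2))


class TestObjective:
    def test_two_point_hand_example(self):
        # w = 0: all distances vanish, k(0) = 1, each point picks the
        # other with probability 1, loss |0 - 1| = 1, so F = 1
        X = np.array([[0.0, 5.0], [3.0, -2.0]])
        y = np.array([0.0, 1.0])
        br = nca_objective(np.zeros(2), X, y, sigma=1.0, lambda_reg=0.0)
        assert br.objective == pytest.approx(1.0, abs=1e-15)
        assert br.p_ij[0, 1] == pytest.approx(1.0)
        assert br.p_ij[1, 0] == pytest.approx(1.0)
        assert np.allclose(br.l_i, 1.0)

    def test_weighted_distance_arithmetic(self):
        # d_w = 2^2 * |1-0| + 1^2 * |0-2| = 6
        X = np.array([[1.0, 0.0], [0.0, 2.0]])
        br = nca_objective(np.array([2.0, 1.0]), X, np.array([0.0, 1.0]))
        assert br.d_w[0, 1] == pytest.approx(6.0)

    def test_probability_rows_sum_to_one(self, rng):
        X = rng.standard_normal((9, 4))
        y = rng.standard_normal(9)
        br = nca_objective(rng.uniform(0, 2, 4), X, y, sigma=0.7, lambda_reg=0.1)
        assert np.allclose(br.p_ij.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(br.p_ij >= 0)
        assert np.all(br.l_i >= 0)

    def test_matches_brute_force_oracle(self, rng):
        for n in (4, 6, 8):
            X = rng.standard_normal((n, 3))
            y = rng.standard_normal(n)
            w = rng.uniform(0, 1.5, 3)
            ours = nca_objective(w, X, y, sigma=1.3, lambda_reg=0.2).objective
            ref = brute_force_objective(w, X, y, 1.3, 0.2)
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_single_sample_raises(self):
        with pytest.raises(ValueError, match="2 samples"):
            nca_objective(np.ones(2), np.ones((1, 2)), np.ones(1))

    def test_non_finite_raises(self):
        X = np.array([[np.nan, 0.0], [1.0, 2.0]])
        with pytest.raises(ValueError, match="non-finite"):
            nca_objective(np.ones(2), X, np.array([0.0, 1.0]))


class TestGradient:
    def test_penalty_term_contribution(self):
        # identical rows: the loss term is flat in w, leaving 2*lambda*w
        X = np.ones((2, 3))
        y = np.array([0.0, 1.0])
        w = np.array([0.7, -0.3, 1.1])
        g = nca_gradient(w, X, y, sigma=1.0, lambda_reg=1.0)
        assert np.allclose(g, 2.0 * w, atol=1e-12)

    def test_matches_central_differences(self, rng):
        X = rng.standard_normal((6, 3))
        y = rng.standard_normal(6)
        w = rng.uniform(0.5, 1.5, 3)
        g = nca_gradient(w, X, y, sigma=1.0, lambda_reg=0.3)
        h = 1e-5
        for r in range(3):
            wp, wm = w.copy(), w.copy()
            wp[r] += h
            wm[r] -= h
            fd = (nca_objective(wp, X, y, 1.0, 0.3).objective
                  - nca_objective(wm, X, y, 1.0, 0.3).objective) / (2 * h)
            assert abs(g[r] - fd) / max(abs(fd), 1e-8) < 1e-5

    def test_duplicated_rows_zero_loss_gradient_at_zero(self):
        X = np.vstack([np.eye(3), np.eye(3)])
        y = np.arange(6.0)
        g = nca_gradient(np.zeros(3), X, y, sigma=1.0, lambda_reg=0.0)
        assert np.allclose(g, 0.0, atol=1e-12)


class TestFit:
    def test_objective_trace_is_monotone(self, rng):
        X = rng.standard_normal((40, 5))
        y = X[:, 1] + 0.2 * rng.standard_normal(40)
        sel = fit_nca(X, y)
        trace = np.array(sel.objective_trace_)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_strong_regularisation_shrinks_noise_weights(self):
        # y independent of X: with a strong penalty every weight
        # collapses well below the all-ones initialisation
        hits = 0
        for seed in range(5):
            r = np.random.default_rng(100 + seed)
            X = r.standard_normal((150, 5))
            y = r.standard_normal(150)
            sel = fit_nca(X, y, lambda_reg=0.2)
            hits += np.max(np.abs(sel.weights_)) < 0.1
        assert hits >= 4

    def test_informative_feature_recovery_single_instance(self):
        r = np.random.default_rng(0)
        X = r.standard_normal((200, 6))
        y = 2.0 * X[:, 3] + 0.1 * r.standard_normal(200)
        sel = fit_nca(X, y)
        assert 3 in np.flatnonzero(sel.get_support())

    def test_feature_scale_equivariance(self, rng):
        X = rng.standard_normal((80, 4))
        y = X[:, 2] + 0.1 * rng.standard_normal(80)
        s1 = fit_nca(X, y)
        X2 = X.copy()
        X2[:, 0] *= 10.0
        s2 = fit_nca(X2, y)
        assert np.array_equal(s1.get_support(), s2.get_support())
        assert s1.objective_ == pytest.approx(s2.objective_, abs=1e-10)

    def test_sklearn_transform_contract(self, rng):
        X = rng.standard_normal((60, 5))
        y = X[:, 0] + 0.05 * rng.standard_normal(60)
        sel = NcaFeatureSelector().fit(X, y)
        Xt = sel.transform(X)
        assert Xt.shape == (60, sel.get_support().sum())
        params = sel.get_params()
        assert params["fraction"] == 0.01


class TestSelectFeatures:
    def test_one_percent_rule(self):
        # threshold 0.008: features 1 and 2 (1-based) survive
        idx = select_features(np.array([0.8, 0.02, 0.004]))
        assert idx.tolist() == [0, 1]

    def test_single_feature(self):
        assert select_features(np.array([1.0])).tolist() == [0]

    def test_all_equal_selects_all(self):
        assert select_features(np.full(4, 0.3)).tolist() == [0, 1, 2, 3]

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="zero"):
            select_features(np.zeros(3))


class TestProbabilityProperty:
    from hypothesis import given, settings, strategies as st

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 2**16), scale=st.floats(0.01, 100.0))
    def test_rows_sum_to_one_for_any_weights(self, seed, scale):
        r = np.random.default_rng(seed)
        n, p = int(r.integers(2, 12)), int(r.integers(1, 5))
        X = r.standard_normal((n, p))
        y = r.standard_normal(n)
        w = scale * r.uniform(-1, 1, p)
        br = nca_objective(w, X, y, sigma=float(r.uniform(0.2, 3.0)))
        assert np.allclose(br.p_ij.sum(axis=1), 1.0, atol=1e-9)
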