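"""Whitening, FastICA-style rotation fitting, artifact selection/removal."""

import warnings

import numpy as np
import pytest
from scipy import stats

from mdte.ica import (
    ICAConvergenceError,
    auto_select_artifacts,
    fit_ica,
    remove_components,
    whiten,
)


def _mixture(rng, n=10_000):
    """Three independent uniform sources through a known random mixing."""
    S = rng.uniform(-1.0, 1.0, (3, n))
    A = rng.standard_normal((3, 3))
    return A @ S, A, S


def _match_components(Y, S):
    """Max |corr| of each true source against its best-matching component."""
    C = np.abs(np.corrcoef(np.vstack([Y, S]))[: len(Y), len(Y):])
    return C.max(axis=0)


def _amari_index(P):
    """Amari permutation distance of P = W·A from a scaled permutation."""
    P = np.abs(P)
    m = P.shape[0]
    rows = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    cols = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return (rows.sum() + cols.sum()) / (2.0 * m * (m - 1))


class TestWhiten:
    def test_identity_covariance_output(self, rng):
        X = rng.standard_normal((4, 5000)) * np.array([[3.0], [1.0], [0.2], [7.0]])
        Z, Q, means = whiten(X)
        cov = (Z @ Z.T) / (Z.shape[1] - 1)
        np.testing.assert_allclose(cov, np.eye(4), atol=1e-6)

    def test_white_input_gives_orthogonal_q(self, rng):
        n = 200_000  # large n so the sample covariance is ≈ identity
        X = rng.standard_normal((3, n))
        _, Q, _ = whiten(X)
        np.testing.assert_allclose(Q @ Q.T, np.eye(3), atol=5e-2)

    def test_duplicated_channel_rejected(self, rng):
        x = rng.standard_normal(1000)
        with pytest.raises(ValueError, match="rank-deficient"):
            whiten(np.vstack([x, x, rng.standard_normal(1000)]))

    def test_reduced_components_on_deficient_data(self, rng):
        X = rng.standard_normal((4, 5000))
        X -= X.mean(axis=0, keepdims=True)  # rank 3, like CAR output
        Z, Q, _ = whiten(X, n_components=3)
        assert Z.shape[0] == 3
        cov = (Z @ Z.T) / (Z.shape[1] - 1)
        np.testing.assert_allclose(cov, np.eye(3), atol=1e-6)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="samples"):
            whiten(rng.standard_normal((5, 4)))


class TestFitICA:
    def test_source_recovery(self, rng):
        X, A, S = _mixture(rng)
        d = fit_ica(X, seed=0)
        assert d.converged
        assert np.all(_match_components(d.sources, S) > 0.95)

    def test_mixing_recovered_up_to_permutation_and_scale(self, rng):
        X, A, S = _mixture(rng)
        d = fit_ica(X, seed=0)
        P = d.W @ A
        # one dominant entry per row/column, off-pattern entries small
        mask = np.abs(P) == np.abs(P).max(axis=1, keepdims=True)
        assert mask.sum() == 3
        assert np.abs(P[~mask]).max() < 0.1

    def test_deterministic_given_seed(self, rng):
        X, _, _ = _mixture(rng)
        d1 = fit_ica(X, seed=3)
        d2 = fit_ica(X, seed=3)
        np.testing.assert_array_equal(d1.W, d2.W)

    def test_gaussian_pair_unidentifiable_but_valid(self, rng):
        X = rng.standard_normal((2, 10_000)) * np.array([[2.0], [0.5]])
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            d = fit_ica(X, seed=0, max_iter=100)
        # a valid decomposition is returned regardless of identifiability
        np.testing.assert_allclose(d.B.T @ d.B, np.eye(2), atol=1e-8)
        np.testing.assert_allclose(d.W @ d.A_hat, np.eye(2), atol=1e-6)
        if not d.converged:
            assert any("near-Gaussian" in str(w.message) for w in caught)

    def test_nonconvergence_raises_by_default(self, rng):
        # heavy-tailed mixture with a 1-iteration budget cannot converge
        X, _, _ = _mixture(rng)
        with pytest.raises(ICAConvergenceError, match="1 iterations"):
            fit_ica(X, seed=0, max_iter=1, tol=1e-12)

    def test_nonconvergence_warns_when_requested(self, rng):
        X, _, _ = _mixture(rng)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            fit_ica(X, seed=0, max_iter=1, tol=1e-12, on_fail="warn")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_decomposition_invariants(self, seed):
        rng = np.random.default_rng(seed)
        X, _, _ = _mixture(rng, n=4000)
        d = fit_ica(X, seed=seed)
        m = d.n_components
        np.testing.assert_allclose(d.B.T @ d.B, np.eye(m), atol=1e-8)
        np.testing.assert_allclose(d.W, d.B.T @ d.Q, atol=1e-8)
        np.testing.assert_allclose(d.W @ d.A_hat, np.eye(m), atol=1e-6)
        Z = d.Q @ (X - d.channel_means[:, None])
        cov = (Z @ Z.T) / (Z.shape[1] - 1)
        np.testing.assert_allclose(cov, np.eye(m), atol=1e-6)

    def test_amari_distance_shrinks_with_samples(self):
        def run(n, seed):
            rng = np.random.default_rng(seed)
            X, A, _ = _mixture(rng, n=n)
            d = fit_ica(X, seed=seed)
            return _amari_index(d.W @ A)

        small = np.mean([run(1_000, s) for s in range(4)])
        large = np.mean([run(10_000, s) for s in range(4)])
        assert large < small


class TestRemoveComponents:
    def test_empty_rejection_is_identity(self, rng):
        X, _, _ = _mixture(rng)
        d = fit_ica(X, seed=0)
        X_clean = remove_components(d, [])
        rel = np.linalg.norm(X_clean - X) / np.linalg.norm(X)
        assert rel < 1e-6

    def test_reject_all_leaves_channel_means(self, rng):
        X = _mixture(rng)[0] + 5.0
        d = fit_ica(X, seed=0)
        X_clean = remove_components(d, range(d.n_components))
        np.testing.assert_allclose(X_clean, d.channel_means[:, None] * np.ones_like(X), atol=1e-8)

    def test_out_of_range_index(self, rng):
        X, _, _ = _mixture(rng)
        d = fit_ica(X, seed=0)
        with pytest.raises(IndexError):
            remove_components(d, [17])

    def test_rejecting_heavy_tail_component_reduces_variance(self, rng):
        # sparse high-amplitude transients on one source: the classic
        # ocular-artifact situation
        n = 10_000
        S = rng.uniform(-1, 1, (3, n))
        spikes = np.zeros(n)
        spikes[rng.integers(0, n, 40)] = 25.0
        S[0] += spikes
        X = rng.standard_normal((3, 3)) @ S
        d = fit_ica(X, seed=0)
        idx = [int(np.argmax(stats.kurtosis(d.sources, axis=1)))]
        X_clean = remove_components(d, idx)
        assert X_clean.var() < X.var()


class TestAutoSelect:
    def test_gaussian_components_never_selected(self, rng):
        X = rng.standard_normal((3, 20_000))
        d = fit_ica(X, seed=0, max_iter=50, on_fail="warn")
        assert auto_select_artifacts(d, threshold=5.0) == []

    def test_planted_spiky_component_selected(self, rng):
        n = 10_000
        S = rng.uniform(-1, 1, (3, n))
        spikes = np.zeros(n)
        spikes[rng.integers(0, n, 30)] = 30.0
        S[2] += spikes
        X = rng.standard_normal((3, 3)) @ S
        d = fit_ica(X, seed=0)
        idx = auto_select_artifacts(d, threshold=5.0)
        assert idx == [int(np.argmax(stats.kurtosis(d.sources, axis=1)))]

    def test_infinite_threshold_selects_nothing(self, rng):
        X, _, _ = _mixture(rng)
        d = fit_ica(X, seed=0)
        assert auto_select_artifacts(d, threshold=np.inf) == []
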