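"""Tests for point-estimate RSA, whitening and the analytic bias theory."""

import numpy as np
import pandas as pd
import pytest
from numpy.testing import assert_allclose
from scipy.linalg import toeplitz

from bayesrsa.classic import (
    PatternEstimate,
    cross_run_similarity,
    delta6_patterns,
    euclidean_bias,
    euclidean_rdm,
    glm_by_run,
    glm_point_estimate,
    pearson_similarity,
    spatial_whiten,
    theoretical_bias,
    within_run_rsa,
)
from bayesrsa.likelihood import TaskDesign


def _design(X, n_runs=1, drift=False, TR=1.0):
    n_T = X.shape[0]
    run_index = np.repeat(np.arange(n_runs), n_T // n_runs)
    drift_basis = None if drift else np.zeros((n_T, 0))
    return TaskDesign(X=X, run_index=run_index, TR=TR, drift_basis=drift_basis)


class TestGlmPointEstimate:
    @pytest.mark.parametrize("estimator", ["ols", "gls_ar1"])
    def test_noiseless_recovery_is_exact(self, rng, estimator):
        X = rng.standard_normal((40, 3))
        beta = rng.standard_normal((3, 7))
        design = _design(X)
        est = glm_point_estimate(X @ beta, design, estimator=estimator)
        assert_allclose(est.beta_hat, beta, atol=1e-9)

    def test_ols_sampling_covariance_matches_theory(self, rng):
        # orthogonal design, white noise: cov(beta_hat) = sigma^2 (X'X)^{-1}
        Q, _ = np.linalg.qr(rng.standard_normal((30, 3)))
        design = _design(Q)
        noise = 2.0 * rng.standard_normal((30, 4000))  # draws as voxels
        est = glm_point_estimate(noise, design, estimator="ols")
        emp = est.beta_hat @ est.beta_hat.T / 4000
        assert_allclose(emp, 4.0 * np.eye(3), atol=0.3)

    def test_gls_beats_ols_under_ar1_noise(self, rng):
        X = rng.standard_normal((60, 2))
        design = _design(X)
        rho = 0.5
        n_draws = 500
        innov = rng.standard_normal((60, n_draws))
        noise = np.empty_like(innov)
        noise[0] = innov[0] / np.sqrt(1 - rho**2)
        for t in range(1, 60):
            noise[t] = rho * noise[t - 1] + innov[t]
        ols = glm_point_estimate(noise, design, estimator="ols").beta_hat
        gls = glm_point_estimate(noise, design, estimator="gls_ar1").beta_hat
        assert gls.var(axis=1).mean() <= ols.var(axis=1).mean()

    def test_rank_deficiency_names_columns(self, rng):
        X = rng.standard_normal((10, 2))
        design = TaskDesign(X=X, run_index=np.zeros(10), TR=1.0,
                            drift_basis=X[:, :1])  # drift collinear with X
        with pytest.raises(ValueError, match="collinear"):
            glm_point_estimate(np.zeros((10, 3)), design)


class TestPearsonSimilarity:
    def test_identical_rows_give_unit_similarity(self):
        beta = np.vstack([[1.0, 2.0, 3.0]] * 2)
        p = PatternEstimate(beta_hat=beta, estimator="ols", residuals=None)
        assert pearson_similarity(p).C[0, 1] == pytest.approx(1.0)

    def test_reversed_rows_give_minus_one(self):
        p = PatternEstimate(
            beta_hat=np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]),
            estimator="ols", residuals=None,
        )
        assert pearson_similarity(p).C[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        p = PatternEstimate(
            beta_hat=np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 1.0]]),
            estimator="ols", residuals=None,
        )
        assert pearson_similarity(p).C[0, 1] == pytest.approx(-0.5)

    def test_zero_variance_row_rejected(self):
        p = PatternEstimate(
            beta_hat=np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]]),
            estimator="ols", residuals=None,
        )
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_similarity(p)

    def test_bounds_and_symmetry(self, rng):
        p = PatternEstimate(beta_hat=rng.standard_normal((5, 50)),
                            estimator="ols", residuals=None)
        C = pearson_similarity(p).C
        assert_allclose(C, C.T)
        assert_allclose(np.diag(C), 1.0)
        assert np.all(np.abs(C) <= 1 + 1e-12)


class TestCrossRunSimilarity:
    def _mk(self, beta, run_id):
        return PatternEstimate(beta_hat=beta, estimator="ols",
                               residuals=None, run_id=run_id)

    def test_identical_noiseless_patterns_reduce_to_within_run(self, rng):
        beta = rng.standard_normal((4, 30))
        res = cross_run_similarity([self._mk(beta, 0), self._mk(beta, 1)])
        within = pearson_similarity(self._mk(beta, 0))
        assert_allclose(res.C, within.C, atol=1e-12)
        assert_allclose(np.diag(res.C), 1.0)

    def test_independent_noise_concentrates_near_zero(self, rng):
        a = self._mk(rng.standard_normal((4, 500)), 0)
        b = self._mk(rng.standard_normal((4, 500)), 1)
        C = cross_run_similarity([a, b]).C
        assert np.mean(np.abs(C[np.triu_indices(4, 1)])) < 0.1

    def test_anticorrelated_noise_gives_negative_diagonal(self, rng):
        beta = rng.standard_normal((3, 40))
        res = cross_run_similarity([self._mk(beta, 0), self._mk(-beta, 1)])
        assert np.all(np.diag(res.C) < 0)

    def test_single_run_rejected(self, rng):
        with pytest.raises(ValueError, match="more than one run"):
            cross_run_similarity([self._mk(rng.standard_normal((3, 10)), 0)])


class TestSpatialWhiten:
    def test_identity_covariance_leaves_patterns_unchanged_up_to_scale(self, rng):
        beta = rng.standard_normal((4, 30))
        resid = rng.standard_normal((600, 30))
        p = PatternEstimate(beta_hat=beta, estimator="ols", residuals=resid)
        (w,) = spatial_whiten([p], resid)
        # direction preserved: rows stay highly correlated with originals
        for i in range(4):
            r = np.corrcoef(beta[i], w.beta_hat[i])[0, 1]
            assert r > 0.95

    def test_whitening_moves_residual_covariance_toward_identity(self, rng):
        # two blocks of strongly correlated voxels
        n_V = 20
        base = rng.standard_normal((500, 2))
        resid = np.repeat(base, n_V // 2, axis=1) + 0.3 * rng.standard_normal((500, n_V))
        p = PatternEstimate(beta_hat=rng.standard_normal((3, n_V)),
                            estimator="ols", residuals=resid)
        (w,) = spatial_whiten([p], resid)
        def offdiag_norm(R):
            cov = np.corrcoef(R.T)
            return np.linalg.norm(cov - np.diag(np.diag(cov)))
        assert offdiag_norm(w.residuals) < offdiag_norm(resid)

    def test_voxel_permutation_equivariance(self, rng):
        beta = rng.standard_normal((3, 12))
        resid = rng.standard_normal((300, 12))
        perm = rng.permutation(12)
        p = PatternEstimate(beta_hat=beta, estimator="ols", residuals=resid)
        pp = PatternEstimate(beta_hat=beta[:, perm], estimator="ols",
                             residuals=resid[:, perm])
        (w,) = spatial_whiten([p], resid)
        (wp,) = spatial_whiten([pp], resid[:, perm])
        assert_allclose(wp.beta_hat, w.beta_hat[:, perm], atol=1e-8)


class TestEuclidean:
    def test_basic_distances(self):
        p = PatternEstimate(
            beta_hat=np.array([[0.0, 0.0], [3.0, 4.0], [0.0, 0.0]]),
            estimator="ols", residuals=None,
        )
        D = euclidean_rdm(p).C
        assert D[0, 1] == pytest.approx(5.0)
        assert D[0, 2] == pytest.approx(0.0)

    def test_triangle_inequality(self, rng):
        p = PatternEstimate(beta_hat=rng.standard_normal((6, 9)),
                            estimator="ols", residuals=None)
        D = euclidean_rdm(p).C
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-12


class TestBiasTheory:
    def test_orthonormal_design_white_noise_gives_identity(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((20, 4)))
        bias = theoretical_bias(_design(Q), "white", sigma2=1.0)
        assert_allclose(bias.B, np.eye(4), atol=1e-12)

    def test_correlated_columns_hand_inverted(self):
        X = np.array([[1.0, 1.0], [1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        bias = theoretical_bias(_design(X), "white")
        # X'X = [[2,1],[1,2]]; inverse = [[2,-1],[-1,2]]/3
        assert_allclose(bias.B, np.array([[2, -1], [-1, 2]]) / 3.0)
        assert_allclose(np.diag(bias.normalized_bias), 1.0)

    def test_noise_only_pattern_covariance_converges_to_B(self, rng):
        """Sample covariance of OLS pattern noise matches
        (X'X)^{-1} X' Sigma X (X'X)^{-1} under AR(1) noise."""
        X = rng.standard_normal((50, 4))
        design = _design(X)
        rho = 0.6
        Sigma = toeplitz(rho ** np.arange(50)) / (1 - rho**2)
        bias = theoretical_bias(design, Sigma)
        Lc = np.linalg.cholesky(Sigma)
        noise = Lc @ rng.standard_normal((50, 6000))
        est = glm_point_estimate(noise, design, estimator="ols")
        emp = est.beta_hat @ est.beta_hat.T / 6000
        err = np.linalg.norm(emp - bias.B) / np.linalg.norm(bias.B)
        assert err < 0.05

    def test_shape_mismatch_rejected(self, rng):
        design = _design(rng.standard_normal((10, 2)))
        with pytest.raises(ValueError, match="shape"):
            theoretical_bias(design, np.eye(5))


class TestEuclideanBias:
    def test_identity_bias(self):
        from bayesrsa.classic import BiasMatrix
        bias = BiasMatrix(B=np.eye(3), normalized_bias=np.eye(3))
        out = euclidean_bias(bias, n_V=10)
        assert out[0, 1] == pytest.approx(20.0)
        assert out[0, 0] == pytest.approx(0.0)

    def test_equal_entries_cancel(self):
        from bayesrsa.classic import BiasMatrix
        B = np.full((2, 2), 0.7)
        out = euclidean_bias(BiasMatrix(B=B, normalized_bias=B), n_V=5)
        assert_allclose(out, 0.0)

    def test_monte_carlo_expected_squared_distance(self, rng):
        X = rng.standard_normal((30, 3))
        design = _design(X)
        rho = 0.4
        Sigma = toeplitz(rho ** np.arange(30)) / (1 - rho**2)
        bias = theoretical_bias(design, Sigma)
        n_V = 10000
        Lc = np.linalg.cholesky(Sigma)
        noise = Lc @ rng.standard_normal((30, n_V))
        beta = glm_point_estimate(noise, design, estimator="ols").beta_hat
        expected = euclidean_bias(bias, n_V)
        for i in range(3):
            for j in range(i + 1, 3):
                d2 = np.sum((beta[i] - beta[j]) ** 2)
                assert d2 == pytest.approx(expected[i, j], rel=0.05)


class TestDelta6:
    def test_single_events_pick_raw_volumes(self):
        TR = 1.0
        n_T = 30
        Y = np.arange(n_T, dtype=float)[:, None] * np.ones((1, 2))
        events = pd.DataFrame(
            {"onset": [4.0, 12.0], "duration": 1.0, "trial_type": [0, 1]}
        )
        est = delta6_patterns(Y, events, TR)
        assert_allclose(est.beta_hat[0], Y[10])  # onset 4 + 6 s
        assert_allclose(est.beta_hat[1], Y[18])

    def test_tie_rounds_down(self):
        TR = 2.0
        Y = np.arange(20, dtype=float)[:, None]
        events = pd.DataFrame({"onset": [1.0], "duration": 1.0, "trial_type": [0]})
        # (1 + 6)/2 = 3.5 -> volume 3, not 4
        est = delta6_patterns(Y, events, TR)
        assert est.beta_hat[0, 0] == pytest.approx(Y[3, 0])

    def test_bias_samples_noise_autocovariance_at_event_lags(self):
        TR = 1.0
        n_T = 60
        events = pd.DataFrame(
            {"onset": [4.0, 9.0, 24.0], "duration": 1.0, "trial_type": [0, 1, 2]}
        )
        rho = 0.5
        Sigma = toeplitz(rho ** np.arange(n_T)) / (1 - rho**2)
        # one impulse per condition at volumes 10, 15, 30 -> orthogonal X6
        times = np.array([10, 15, 30])
        X6 = np.zeros((n_T, 3))
        X6[times, np.arange(3)] = 1.0
        B = np.linalg.inv(X6.T @ X6) @ X6.T @ Sigma @ X6 @ np.linalg.inv(X6.T @ X6)
        lags = np.abs(times[:, None] - times[None, :])
        assert_allclose(B, rho**lags / (1 - rho**2))

    def test_adjacent_events_mix_condition_patterns(self):
        from bayesrsa.simulate import build_design_matrix
        TR = 1.0
        n_T = 120
        onsets0 = np.arange(10.0, 100.0, 20.0)
        events = pd.DataFrame(
            {
                "onset": np.concatenate([onsets0, onsets0 + 2.0]),
                "duration": 1.0,
                "trial_type": [0] * 5 + [1] * 5,
            }
        )
        X = build_design_matrix(events, TR, n_T)
        X6 = np.zeros((n_T, 2))
        for j, ons in enumerate([onsets0, onsets0 + 2.0]):
            for o in ons:
                X6[int(o + 6), j] += 1
        M = np.linalg.inv(X6.T @ X6) @ X6.T @ X  # mixing of true patterns
        assert M[0, 1] > 0.1 and M[1, 0] > 0.1  # off-condition leakage

    def test_event_beyond_scan_dropped_with_warning(self):
        Y = np.zeros((10, 3))
        events = pd.DataFrame(
            {"onset": [1.0, 8.0], "duration": 1.0, "trial_type": [0, 0]}
        )
        with pytest.warns(UserWarning, match="dropped"):
            est = delta6_patterns(Y, events, TR=1.0)
        assert est.beta_hat.shape == (1, 3)


class TestWithinRunPipeline:
    def test_multi_run_average_and_whiten_smoke(self, rng):
        from bayesrsa.simulate import SimulationConfig, simulate_dataset
        cfg = SimulationConfig(
            n_C=4, n_T_per_run=80, n_runs=2, n_V=30, seed=21,
            true_U=np.eye(4), transition_matrix=np.full((4, 4), 0.25),
            target_snr=1.0,
        )
        ds = simulate_dataset(cfg)
        res = within_run_rsa(ds.data, ds.design, estimator="gls_ar1", whiten=True)
        assert res.C.shape == (4, 4)
        assert_allclose(np.diag(res.C), 1.0)
        assert res.whitened

    def test_glm_by_run_returns_run_patterns(self, rng):
        X = rng.standard_normal((40, 2))
        design = TaskDesign(X=X, run_index=np.repeat([0, 1], 20), TR=1.0)
        Y = rng.standard_normal((40, 8))
        per_run = glm_by_run(Y, design)
        assert [p.run_id for p in per_run] == [0, 1]
        assert per_run[0].beta_hat.shape == (2, 8)
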