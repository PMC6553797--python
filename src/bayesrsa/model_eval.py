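"""Cross-validated model selection and decoding.

A fitted model (full or null) assigns a predictive probability to
left-out test data: the task-driven mean ``X_test beta_hat`` (absent in
the null model) plus Gaussian noise whose covariance combines the
voxel's AR(1) posterior parameters with the test-phase intrinsic
fluctuations.  The unknown test-phase fluctuations are marginalized by
assuming their statistical properties (variance and lag-1
autocorrelation of each training component) carry over to the test
phase; test-phase drift is marginalized under a flat prior.  Comparing
the full model's log predictive probability against the null model's
across subjects with a one-sided t-test guards against over-fitting:
the full model's extra log-determinant term penalizes its additional
flexibility, so pure noise favours the null model.

Decoding inverts the same generative model: given the posterior-mean
patterns, the unknown test-phase design and fluctuation time courses
get independent standard-normal priors per time point, making the
posterior mean a single linear solve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, toeplitz
from scipy.stats import ttest_1samp

from .inference import FitConfig, FitResult, fit_brsa, fit_null
from .likelihood import DataMatrix, TaskDesign, _run_slices, legendre_drift_basis

__all__ = [
    "CrossValScore",
    "SelectionDecision",
    "predictive_loglik",
    "crossval_score",
    "select_model",
    "decode",
]


@dataclass
class CrossValScore:
    """Per-subject cross-validation scores (log predictive probabilities)."""

    full_log_pred: float
    null_log_pred: float

    @property
    def delta(self) -> float:
        return self.full_log_pred - self.null_log_pred


@dataclass
class SelectionDecision:
    """Outcome of the one-sided group test of full vs null model."""

    t_statistic: float
    p_value: float
    accepted: bool
    alpha: float


# --------------------------------------------------------------------------
# Predictive likelihood
# --------------------------------------------------------------------------


def _intrinsic_stats(fit: FitResult):
    """Variance and lag-1 autocorrelation of each training intrinsic
    component (the statistical properties assumed to carry over)."""
    X0 = fit.X0_hat.intrinsic
    slices = _run_slices(fit.run_index)
    stats = []
    for j in range(X0.shape[1]):
        col = X0[:, j]
        var = float(col.var())
        num = den = 0.0
        for sl in slices:
            c = col[sl] - col[sl].mean()
            num += float(c[1:] @ c[:-1])
            den += float(c @ c)
        r = num / den if den > 0 else 0.0
        stats.append((var, float(np.clip(r, -0.98, 0.98))))
    return stats


def _ar1_cov_blocks(rho: float, run_slices, n_T: int) -> np.ndarray:
    """Unit-innovation stationary AR(1) covariance, block per run."""
    out = np.zeros((n_T, n_T))
    for sl in run_slices:
        n = sl.stop - sl.start
        out[sl, sl] = toeplitz(rho ** np.arange(n)) / (1.0 - rho**2)
    return out


def _unit_ar1_corr_blocks(r: float, run_slices, n_T: int) -> np.ndarray:
    """Unit-variance AR(1) correlation matrix, block per run."""
    out = np.zeros((n_T, n_T))
    for sl in run_slices:
        n = sl.stop - sl.start
        out[sl, sl] = toeplitz(r ** np.arange(n))
    return out


def predictive_loglik(fit: FitResult, Y_test, design_test: TaskDesign | None = None,
                      drift_order: int = 4) -> float:
    """Log predictive probability of test data under a fitted model.

    For a full-model fit with a known test design the predictive mean
    is ``X_test beta_hat``; for a null fit (or ``design_test=None``)
    the mean is zero.  Per voxel the predictive covariance is the AR(1)
    posterior noise plus the carried-over intrinsic fluctuation
    covariance; test drift is marginalized under a flat prior.
    """
    if not isinstance(Y_test, DataMatrix):
        raise TypeError("Y_test must be a DataMatrix (data plus run structure)")
    Y = Y_test.Y
    n_T, n_V = Y.shape
    if n_V != fit.kept_voxels.size:
        raise ValueError(
            f"test data have {n_V} voxels but the fit was computed on "
            f"{fit.kept_voxels.size}"
        )
    slices = _run_slices(Y_test.run_index)
    if fit.beta_hat is not None and design_test is not None:
        mean = design_test.X @ fit.beta_hat
    else:
        mean = np.zeros_like(Y)
    drift = legendre_drift_basis(Y_test.run_index, drift_order)
    D, _ = np.linalg.qr(drift)
    q = D.shape[1]
    istats = _intrinsic_stats(fit)
    intr_corrs = [
        _unit_ar1_corr_blocks(r, slices, n_T) * var for (var, r) in istats
    ]
    b0_int = fit.beta0_hat[fit.X0_hat.n_drift :]
    total = 0.0
    const = -0.5 * (n_T - q) * np.log(2 * np.pi)
    for k in np.flatnonzero(fit.kept_voxels):
        rho = fit.rho_hat[k]
        sig2 = fit.sigma2_hat[k]
        V = sig2 * _ar1_cov_blocks(rho, slices, n_T)
        for j, corr in enumerate(intr_corrs):
            V += b0_int[j, k] ** 2 * corr
        cho = cho_factor(V)
        logdet_V = 2.0 * np.sum(np.log(np.diag(cho[0])))
        r = Y[:, k] - mean[:, k]
        Vinv_r = cho_solve(cho, r)
        Vinv_D = cho_solve(cho, D)
        G = D.T @ Vinv_D
        choG = cho_factor(G)
        logdet_G = 2.0 * np.sum(np.log(np.diag(choG[0])))
        quad = r @ Vinv_r - (D.T @ Vinv_r) @ cho_solve(choG, D.T @ Vinv_r)
        total += const - 0.5 * logdet_V - 0.5 * logdet_G - 0.5 * quad
    return float(total)


def crossval_score(Y_train, design_train: TaskDesign, Y_test,
                   design_test: TaskDesign, config: FitConfig | None = None,
                   fits: tuple | None = None) -> CrossValScore:
    """Fit full and null models on training data and score both on the
    left-out test data.  Pre-computed ``fits=(full, null)`` may be
    passed to re-score without refitting."""
    config = config or FitConfig()
    if fits is None:
        full = fit_brsa(Y_train, design_train, config)
        null = fit_null(Y_train, design_train.run_index, config,
                        drift_order=design_train.drift_order)
    else:
        full, null = fits
    return CrossValScore(
        full_log_pred=predictive_loglik(full, Y_test, design_test),
        null_log_pred=predictive_loglik(null, Y_test, None),
    )


def select_model(scores: list[CrossValScore], alpha: float = 0.05) -> SelectionDecision:
    """One-sided paired t-test across subjects of full-minus-null
    cross-validation scores (H1: full > null); the full model is
    accepted iff p < alpha."""
    if len(scores) < 2:
        raise ValueError("model selection needs scores from at least 2 subjects")
    deltas = np.array([s.delta for s in scores])
    if not np.all(np.isfinite(deltas)):
        raise ValueError("non-finite cross-validation deltas")
    if np.std(deltas) == 0:
        warnings.warn("zero-variance score differences; full model not accepted",
                      stacklevel=2)
        return SelectionDecision(t_statistic=np.nan, p_value=1.0,
                                 accepted=False, alpha=alpha)
    t, p = ttest_1samp(deltas, 0.0, alternative="greater")
    return SelectionDecision(t_statistic=float(t), p_value=float(p),
                             accepted=bool(p < alpha), alpha=alpha)


# --------------------------------------------------------------------------
# Decoding
# --------------------------------------------------------------------------


def decode(fit: FitResult, Y_test, drift_order: int = 4):
    """Posterior mean of the unknown test-phase design and intrinsic
    fluctuation time courses.

    Each entry of the test design ``X_test`` (one column per condition)
    and of the intrinsic courses gets an independent N(0, 1) prior;
    jointly Gaussian with the observation model, so the posterior mean
    is one linear solve.  Test data are detrended (per-run Legendre
    projection) first.  Returns ``(X_test_hat, X0_test_hat)`` with
    shapes (n_T_test, n_C) and (n_T_test, n_intrinsic).
    """
    if fit.beta_hat is None:
        raise ValueError("decoding requires a full-model fit")
    if not isinstance(Y_test, DataMatrix):
        raise TypeError("Y_test must be a DataMatrix")
    Y = Y_test.Y
    n_T, n_V = Y.shape
    if n_V != fit.kept_voxels.size:
        raise ValueError("voxel count mismatch between fit and test data")
    n_C = fit.beta_hat.shape[0]
    b_int = fit.beta0_hat[fit.X0_hat.n_drift :]
    n_int = b_int.shape[0]
    if not np.any(fit.beta_hat):
        warnings.warn("all-zero pattern estimates; decoded signals are zero",
                      stacklevel=2)
        return np.zeros((n_T, n_C)), np.zeros((n_T, n_int))
    slices = _run_slices(Y_test.run_index)
    drift = legendre_drift_basis(Y_test.run_index, drift_order)
    Qd, _ = np.linalg.qr(drift)
    Yd = Y - Qd @ (Qd.T @ Y)
    keep = fit.kept_voxels
    b = np.vstack([fit.beta_hat, b_int])[:, keep]  # (p, n_kept)
    p = n_C + n_int
    rho = fit.rho_hat[keep]
    winv = 1.0 / fit.sigma2_hat[keep]
    Yk = Yd[:, keep]
    # A_k y_k for every voxel (vectorized over voxels, runs handled per slice)
    Ay = np.empty_like(Yk)
    bnd = np.zeros(n_T, dtype=bool)
    for sl in slices:
        blk = Yk[sl]
        coeff = 1.0 + rho**2
        R = coeff[None, :] * blk
        R[0] = blk[0]
        R[-1] = blk[-1]
        R[1:] -= rho[None, :] * blk[:-1]
        R[:-1] -= rho[None, :] * blk[1:]
        Ay[sl] = R
        bnd[sl.start] = bnd[sl.stop - 1] = True
    Ay *= winv[None, :]
    # pairwise scalars for the tridiagonal precision blocks
    S_off = (b * (-rho * winv)) @ b.T
    S_int = (b * ((1.0 + rho**2) * winv)) @ b.T
    S_bnd = (b * winv) @ b.T
    # assemble the (p n_T) x (p n_T) posterior precision, regressor-major
    M = np.eye(p * n_T)
    for i in range(p):
        for j in range(p):
            blk = M[i * n_T : (i + 1) * n_T, j * n_T : (j + 1) * n_T]
            idx = np.arange(n_T)
            d = np.where(bnd, S_bnd[i, j], S_int[i, j])
            blk[idx, idx] += d
            for sl in slices:
                rr = np.arange(sl.start, sl.stop - 1)
                blk[rr, rr + 1] += S_off[i, j]
                blk[rr + 1, rr] += S_off[i, j]
    rhs = (Ay @ b.T).T.ravel()  # stack per regressor
    sol = np.linalg.solve(M, rhs).reshape(p, n_T)
    return sol[:n_C].T, sol[n_C:].T
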