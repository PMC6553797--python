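"""Fitting the Bayesian RSA model.

The shared condition covariance ``U = L L^T`` is estimated by maximizing
the marginal likelihood of the data over the free entries of the
Cholesky factor ``L`` (empirical Bayes), with the activity profiles,
nuisance modulations, noise variances and the (rho, s) grid all
marginalized by the likelihood engine.  Because the intrinsic
fluctuation time courses ``X0`` are themselves unknown, fitting
alternates between (i) optimizing ``L`` with ``X0`` fixed and (ii)
re-estimating the intrinsic components from the residuals after
removing the posterior-mean task signal, by principal component
analysis with the number of components chosen by an optimal
hard-threshold rule.  Group fitting (GBRSA) shares a single ``L``
across subjects while every subject keeps its own nuisance model and
voxel-level posteriors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from .likelihood import (
    DataMatrix,
    GridSpec,
    NuisanceModel,
    SharedCovariance,
    TaskDesign,
    _apply_ar1_unit,
    covariance_to_correlation,
    legendre_drift_basis,
)

logger = logging.getLogger("bayesrsa")

__all__ = [
    "FitConfig",
    "FitResult",
    "VoxelGridPosterior",
    "estimate_rank",
    "estimate_X0",
    "fit_brsa",
    "fit_null",
    "fit_gbrsa",
    "u_to_correlation",
]


# --------------------------------------------------------------------------
# Configuration and result containers
# --------------------------------------------------------------------------


@dataclass
class FitConfig:
    """Settings for a BRSA fit.

    ``grid`` is the (rho, s) prior grid; ``rank_method`` is either
    "auto" (optimal hard threshold on the residual singular values) or
    a fixed integer count of intrinsic components; ``rank_cap`` bounds
    the automatic choice (default min(n_T // 10, 20)).
    """

    grid: GridSpec = field(default_factory=GridSpec.default)
    max_outer_iters: int = 20
    convergence_tol: float = 1e-4
    loglik_tol: float = 1e-2
    optimizer_maxiter: int = 100
    optimizer_gtol: float = 1e-5
    rank_method: str | int = "auto"
    rank_cap: int | None = None
    drift_order: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.convergence_tol <= 0 or self.optimizer_gtol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class VoxelGridPosterior:
    """Per-voxel posterior over the (rho, s) grid and conditional profile
    posteriors.

    ``weights`` has shape (n_rho, n_snr, n_V) and sums to 1 over the
    grid for each voxel.
    """

    grid: GridSpec
    weights: np.ndarray
    rho_mean: np.ndarray
    snr_mean: np.ndarray
    _L: np.ndarray = field(repr=False, default=None)
    _cond_mean_factors: list = field(repr=False, default=None)

    def conditional_beta(self, il: int, im: int):
        """Conditional posterior mean of beta given grid cell (il, im) and
        the unit-sigma^2 conditional covariance s^2 L Lambda* L'."""
        V, evals, M = self._cond_mean_factors[il]
        s2 = self.grid.snr[im] ** 2
        denom = 1.0 + s2 * evals
        mean = self._L @ (V @ (s2 / denom[:, None] * M))
        cov_unit = self._L @ (V @ np.diag(s2 / denom) @ V.T) @ self._L.T
        return mean, cov_unit


@dataclass
class FitResult:
    """Output of a (null or full) BRSA fit for one subject.

    Voxel-level maps are aligned to the input voxel order; voxels that
    were dropped as constant carry NaN (and zero pattern estimates).
    """

    shared: SharedCovariance | None
    X0_hat: NuisanceModel
    sigma2_hat: np.ndarray
    rho_hat: np.ndarray
    snr_hat: np.ndarray | None
    beta_hat: np.ndarray | None  # (n_C, n_V)
    beta0_hat: np.ndarray  # (n_0, n_V)
    loglik_trace: list[float]
    converged: bool
    grid: GridSpec
    run_index: np.ndarray
    kept_voxels: np.ndarray  # boolean mask of analyzed voxels
    posterior: VoxelGridPosterior | None = field(repr=False, default=None)

    @property
    def is_null(self) -> bool:
        return self.shared is None


def u_to_correlation(U: np.ndarray) -> np.ndarray:
    """Similarity matrix from a covariance: C_ij = U_ij / sqrt(U_ii U_jj),
    with a tiny trace-scaled jitter if the diagonal touches zero."""
    return covariance_to_correlation(U)


# --------------------------------------------------------------------------
# Intrinsic-fluctuation estimation
# --------------------------------------------------------------------------


def estimate_rank(residuals: np.ndarray, cap: int | None = None) -> int:
    """Number of shared components in a residual matrix by the optimal
    hard threshold for singular values (unknown noise level).

    The threshold is omega(beta) * median singular value with
    omega(beta) ~= 0.56 b^3 - 0.95 b^2 + 1.82 b + 1.43 for aspect ratio
    b = min(m, n) / max(m, n).
    """
    R = np.asarray(residuals, dtype=float)
    if not np.any(R):
        return 0
    svals = np.linalg.svd(R, compute_uv=False)
    b = min(R.shape) / max(R.shape)
    omega = 0.56 * b**3 - 0.95 * b**2 + 1.82 * b + 1.43
    tau = omega * np.median(svals)
    rank = int(np.sum(svals > tau))
    if cap is not None:
        rank = min(rank, cap)
    return rank


def estimate_X0(residuals: np.ndarray, rank: int,
                drift_basis: np.ndarray) -> NuisanceModel:
    """Nuisance model: orthonormalized drift basis plus the top ``rank``
    left singular vectors of the drift-projected residuals."""
    R = np.asarray(residuals, dtype=float)
    D = np.asarray(drift_basis, dtype=float)
    if D.size:
        Q, _ = np.linalg.qr(D)
    else:
        Q = np.zeros((R.shape[0], 0))
    if rank > min(R.shape):
        raise ValueError(f"rank {rank} exceeds residual matrix dimensions {R.shape}")
    if rank > 0:
        Rp = R - Q @ (Q.T @ R)
        Rp = Rp - Rp.mean(axis=0, keepdims=True) if Q.shape[1] == 0 else Rp
        U_, s_, _ = np.linalg.svd(Rp, full_matrices=False)
        comps = U_[:, :rank]
        X0 = np.column_stack([Q, comps])
    else:
        X0 = Q
    return NuisanceModel(X0=X0, n_drift=Q.shape[1])


# --------------------------------------------------------------------------
# Precomputed per-rho sufficient statistics
# --------------------------------------------------------------------------


class _GridStats:
    """Everything the optimizer and the posterior pass need, computed once
    per (data, design, X0) for every rho on the grid."""

    def __init__(self, Y: np.ndarray, design: TaskDesign, X0m: np.ndarray,
                 grid: GridSpec):
        n_T, n_V = Y.shape
        n_0 = X0m.shape[1]
        self.d = n_T - n_0
        if self.d <= 2:
            raise ValueError("need n_T - n_0 > 2")
        self.n_V = n_V
        self.n_runs = design.n_runs
        self.n_C = design.n_C
        n_l = grid.n_rho
        self.F = np.empty((n_l, self.n_C, self.n_C))
        self.XtAsY = np.empty((n_l, self.n_C, n_V))
        self.yAsy = np.empty((n_l, n_V))
        self.yAy = np.empty((n_l, n_V))
        self.rho_const = np.empty(n_l)
        self.choG = []
        self.X0tAY = np.empty((n_l, n_0, n_V))
        self.X0tAX = np.empty((n_l, n_0, self.n_C))
        X = design.X
        slices = design.run_slices
        for il, rho in enumerate(grid.rho):
            AX = _apply_ar1_unit(rho, slices, X)
            AY = _apply_ar1_unit(rho, slices, Y)
            XtAX = X.T @ AX
            XtAY = X.T @ AY
            yAy = np.einsum("tv,tv->v", Y, AY)
            self.yAy[il] = yAy
            logdet_G = 0.0
            if n_0:
                AX0 = _apply_ar1_unit(rho, slices, X0m)
                G = X0m.T @ AX0
                cho = cho_factor(G)
                logdet_G = 2.0 * np.sum(np.log(np.diag(cho[0])))
                X0tAX = X0m.T @ AX
                X0tAY = X0m.T @ AY
                sol_X = cho_solve(cho, X0tAX)
                sol_Y = cho_solve(cho, X0tAY)
                self.F[il] = XtAX - X0tAX.T @ sol_X
                self.XtAsY[il] = XtAY - X0tAX.T @ sol_Y
                self.yAsy[il] = yAy - np.einsum("ov,ov->v", X0tAY, sol_Y)
                self.choG.append(cho)
                self.X0tAY[il] = X0tAY
                self.X0tAX[il] = X0tAX
            else:
                self.F[il] = XtAX
                self.XtAsY[il] = XtAY
                self.yAsy[il] = yAy
                self.choG.append(None)
            self.rho_const[il] = (
                self.n_runs / 2.0
            ) * np.log1p(-rho**2) - 0.5 * logdet_G
        self.const = -(self.d / 2.0) * np.log(2 * np.pi) + gammaln(self.d / 2.0 - 1.0)

    def negll_and_grad(self, L: np.ndarray, grid: GridSpec, logw: np.ndarray):
        """Negative summed marginal log-likelihood and its analytic gradient
        with respect to the entries of L.

        Per grid cell the gradient of the log-likelihood is
        ``-s^2 F L Lambda* + (d-2) s^2 / Q (h u' - s^2 F L u u')`` with
        ``u = Lambda* L' h``; cells are averaged under the per-voxel
        grid posterior (differentiating through the log-sum-exp).
        """
        s2 = grid.snr**2
        lls, factors, Q = self.cell_loglik(L, grid)
        if lls is None:
            return None, None
        evals, V, M = factors  # M = V' L' H, shape (l, c, v)
        logZ = logsumexp(lls + logw[:, :, None], axis=(0, 1))  # (v,)
        p = np.exp(lls + logw[:, :, None] - logZ[None, None, :])  # (l, m, v)
        denom = 1.0 + s2[None, :, None] * evals[:, None, :]  # (l, m, c)
        inv_denom = 1.0 / denom
        d = self.d
        c2 = p * ((d - 2.0) * s2[None, :, None] / Q)  # (l, m, v)
        grad = np.zeros_like(L)
        P_lm = p.sum(axis=2)  # (l, m)
        for il in range(grid.n_rho):
            Vl, Ml, Hl, Fl = V[il], M[il], self.XtAsY[il], self.F[il]
            a = (P_lm[il] * s2) @ inv_denom[il]  # (c,)
            S_in = np.einsum("mk,mc->ck", c2[il], inv_denom[il])
            G = Ml * S_in  # (c, v)
            R = Ml[None, :, :] * inv_denom[il][:, :, None]  # (m, c, v)
            S = np.einsum("mck,mdk->cd", R * (c2[il] * s2[:, None])[:, None, :], R)
            FL = Fl @ L
            grad += (
                -FL @ (Vl @ ((a[:, None] * Vl.T)))
                - FL @ (Vl @ S @ Vl.T)
                + Hl @ G.T @ Vl.T
            )
        return -float(logZ.sum()), -grad

    def cell_loglik(self, L: np.ndarray, grid: GridSpec):
        """Per-cell log-likelihood array (n_l, n_m, n_V) plus the
        eigen-factorizations needed for posterior means."""
        s2 = grid.snr**2
        K = np.matmul(np.matmul(L.T[None], self.F), L)
        evals, V = np.linalg.eigh(0.5 * (K + np.swapaxes(K, 1, 2)))
        evals = np.clip(evals, 0.0, None)
        M = np.matmul(np.swapaxes(V, 1, 2), np.matmul(L.T[None], self.XtAsY))
        denom = 1.0 + s2[None, :, None] * evals[:, None, :]  # (l, m, c)
        half_logdet = -0.5 * np.sum(np.log(denom), axis=-1)  # (l, m)
        quad = np.einsum("lmc,lcv->lmv", s2[None, :, None] / denom, M**2)
        Q = self.yAsy[:, None, :] - quad
        # voxels (nearly) inside span(X0 or X) leave a ~zero residual form;
        # floor it at a tiny fraction of the unprojected energy
        Q = np.maximum(Q, 1e-10 * self.yAy[:, None, :])
        if Q.min() <= 0:
            return None, None, None
        lls = (
            self.const
            + self.rho_const[:, None, None]
            + half_logdet[:, :, None]
            - (self.d / 2.0 - 1.0) * np.log(Q / 2.0)
        )
        return lls, (evals, V, M), Q


# --------------------------------------------------------------------------
# Cholesky parameterization
# --------------------------------------------------------------------------


def _softplus(x):
    return np.logaddexp(0.0, x)


def _softplus_inv(y):
    y = np.maximum(y, 1e-8)
    return np.where(y > 30, y, np.log(np.expm1(y)))


def _n_free(n_C: int) -> int:
    return n_C * (n_C + 1) // 2


def _unpack_L(theta: np.ndarray, n_C: int) -> np.ndarray:
    L = np.zeros((n_C, n_C))
    L[np.tril_indices(n_C)] = theta
    diag = _softplus(np.diag(L).copy())
    L[np.diag_indices(n_C)] = diag
    return L


def _pack_L(L: np.ndarray) -> np.ndarray:
    n_C = L.shape[0]
    M = L.copy()
    M[np.diag_indices(n_C)] = _softplus_inv(np.diag(L))
    return M[np.tril_indices(n_C)]


# --------------------------------------------------------------------------
# Single-subject fitting
# --------------------------------------------------------------------------


def _prepare_subject(Y, design: TaskDesign, config: FitConfig):
    """Validation, constant-voxel dropping, drift basis, initial X0 and
    crude initial scale."""
    Ymat = Y.Y if isinstance(Y, DataMatrix) else np.atleast_2d(np.asarray(Y, float))
    if Ymat.shape[0] != design.n_T:
        raise ValueError(
            f"data have {Ymat.shape[0]} time points, design has {design.n_T}"
        )
    keep = np.ptp(Ymat, axis=0) > 0
    if not np.all(keep):
        dropped = np.flatnonzero(~keep).tolist()
        logger.warning("dropping %d constant voxel(s): %s", len(dropped), dropped[:20])
    Ymat = Ymat[:, keep]
    if Ymat.shape[1] == 0:
        raise ValueError("no non-constant voxels left to analyze")
    if design.n_T < 3 * design.n_C:
        warnings.warn(
            f"only {design.n_T} time points for {design.n_C} conditions; "
            "at least 3x n_C is recommended",
            stacklevel=3,
        )
    if Ymat.shape[1] < design.n_C:
        warnings.warn(
            "fewer voxels than conditions; U is weakly identified", stacklevel=3
        )
    drift = design.drift_basis
    Xfull = np.column_stack([design.X, drift])
    coef, *_ = np.linalg.lstsq(Xfull, Ymat, rcond=None)
    resid = Ymat - Xfull @ coef
    beta_crude = coef[: design.n_C]
    if config.rank_method == "auto":
        cap = config.rank_cap
        if cap is None:
            cap = min(design.n_T // 10, 20)
        rank = estimate_rank(resid, cap=cap)
    else:
        rank = int(config.rank_method)
    X0 = estimate_X0(resid, rank, drift)
    # crude moment-matched initial scale for L = c I:
    # E[diag(beta beta')] ~ E[s^2] sigma^2 c^2 under the model
    grid = config.grid
    mean_s2 = float(np.sum(grid.weights * (grid.snr**2)[None, :]))
    sigma2_crude = float(np.mean(resid.var(axis=0)))
    pattern_var = float(np.mean(beta_crude**2))
    c2 = pattern_var / max(mean_s2 * sigma2_crude, 1e-12)
    c = float(np.sqrt(max(c2, 1e-4)))
    return Ymat, keep, drift, X0, rank, c, resid


def _optimize_L(theta0, stats_list, grid: GridSpec, config: FitConfig):
    """Quasi-Newton maximization of the summed marginal log-likelihood
    over the free entries of L (finite-difference gradients)."""
    with np.errstate(divide="ignore"):
        logw = np.where(grid.weights > 0, np.log(grid.weights), -np.inf)

    n_C = stats_list[0].n_C
    tril = np.tril_indices(n_C)
    diag_pos = np.flatnonzero(tril[0] == tril[1])

    def negll(theta):
        from scipy.special import expit

        L = _unpack_L(theta, n_C)
        total = 0.0
        grad_L = np.zeros_like(L)
        for st in stats_list:
            nll, g = st.negll_and_grad(L, grid, logw)
            if nll is None or not np.isfinite(nll):
                return 1e12, np.zeros(theta.size)
            total += nll
            grad_L += g
        g_theta = grad_L[tril]
        g_theta[diag_pos] *= expit(theta[diag_pos])  # softplus chain rule
        return total, g_theta

    res = minimize(
        negll,
        theta0,
        method="L-BFGS-B",
        jac=True,
        options={
            "maxiter": config.optimizer_maxiter,
            "gtol": config.optimizer_gtol,
            "maxfun": 20 * config.optimizer_maxiter,
        },
    )
    if not np.isfinite(res.fun):
        raise FloatingPointError("optimizer reached a non-finite objective")
    return res.x, -float(res.fun)


def _posterior_pass(st: _GridStats, L: np.ndarray, grid: GridSpec):
    """Grid posterior weights and posterior-mean maps for one subject."""
    lls, factors, Q = st.cell_loglik(L, grid)
    if lls is None:
        raise FloatingPointError("non-positive residual quadratic form")
    with np.errstate(divide="ignore"):
        logw = np.where(grid.weights > 0, np.log(grid.weights), -np.inf)
    logpost = lls + logw[:, :, None]
    logpost -= logsumexp(logpost, axis=(0, 1), keepdims=True)
    w_post = np.exp(logpost)  # (l, m, v)
    rho_mean = np.einsum("lmv,l->v", w_post, grid.rho)
    snr_mean = np.einsum("lmv,m->v", w_post, grid.snr)
    d = st.d
    if d > 4:
        sigma2_mean = np.einsum("lmv,lmv->v", w_post, Q) / (d - 4.0)
    else:  # posterior mean undefined; fall back to the scale Q/d
        sigma2_mean = np.einsum("lmv,lmv->v", w_post, Q) / d
    evals, V, M = factors
    s2 = grid.snr**2
    denom = 1.0 + s2[None, :, None] * evals[:, None, :]  # (l, m, c)
    n_C = st.n_C
    beta = np.zeros((n_C, st.n_V))
    beta0 = np.zeros((st.X0tAY.shape[1], st.n_V))
    cond_factors = []
    for il in range(grid.n_rho):
        # sum over s of w_post * s^2 / (1 + s^2 eig), coupled in (c, v)
        coefs = np.einsum("mv,mc->cv", w_post[il], s2[:, None] / denom[il])
        B_l = V[il] @ (coefs * M[il])  # pre-L accumulation at this rho
        beta_l = L @ B_l
        beta += beta_l
        if st.choG[il] is not None:
            w_l = w_post[il].sum(axis=0)  # (v,)
            rhs = st.X0tAY[il] * w_l[None, :] - st.X0tAX[il] @ beta_l
            beta0 += cho_solve(st.choG[il], rhs)
        cond_factors.append((V[il], evals[il], np.swapaxes(V, 1, 2)[il] @ (L.T @ st.XtAsY[il])))
    posterior = VoxelGridPosterior(
        grid=grid,
        weights=w_post,
        rho_mean=rho_mean,
        snr_mean=snr_mean,
        _L=L,
        _cond_mean_factors=cond_factors,
    )
    return posterior, sigma2_mean, beta, beta0


def _pad(values: np.ndarray, keep: np.ndarray, fill=np.nan) -> np.ndarray:
    if values.ndim == 1:
        out = np.full(keep.size, fill)
        out[keep] = values
    else:
        out = np.full((values.shape[0], keep.size), fill)
        out[:, keep] = values
    return out


def fit_brsa(Y, design: TaskDesign, config: FitConfig | None = None) -> FitResult:
    """Fit the full BRSA model to one subject.

    Alternates quasi-Newton maximization of the marginal likelihood
    over the Cholesky factor of U with PCA re-estimation of the
    intrinsic fluctuations from the residuals after removing the
    posterior-mean task signal.  Stops when the similarity matrix C
    changes by less than ``convergence_tol`` (max absolute entry).
    """
    config = config or FitConfig()
    Ymat, keep, drift, X0, rank, c, _ = _prepare_subject(Y, design, config)
    grid = config.grid
    n_C = design.n_C
    theta = _pack_L(c * np.eye(n_C))
    C_prev = None
    trace: list[float] = []
    converged = False
    posterior = sigma2 = beta = beta0 = None
    for it in range(config.max_outer_iters):
        st = _GridStats(Ymat, design, X0.X0, grid)
        theta, ll = _optimize_L(theta, [st], grid, config)
        trace.append(ll)
        L = _unpack_L(theta, n_C)
        C = covariance_to_correlation(L @ L.T)
        posterior, sigma2, beta, beta0 = _posterior_pass(st, L, grid)
        # converge on the similarity matrix, or on a stalled likelihood
        # (C is ill-conditioned when U shrinks toward zero on null data)
        if C_prev is not None and (
            np.max(np.abs(C - C_prev)) < config.convergence_tol
            or abs(trace[-1] - trace[-2]) < config.loglik_tol
        ):
            converged = True
            break
        C_prev = C
        if it < config.max_outer_iters - 1:
            resid = Ymat - design.X @ beta
            X0 = estimate_X0(resid, rank, drift)
    if not converged:
        warnings.warn("BRSA fit did not converge within max_outer_iters", stacklevel=2)
    L = _unpack_L(theta, n_C)
    return FitResult(
        shared=SharedCovariance(L=L),
        X0_hat=X0,
        sigma2_hat=_pad(sigma2, keep),
        rho_hat=_pad(posterior.rho_mean, keep),
        snr_hat=_pad(posterior.snr_mean, keep),
        beta_hat=_pad(beta, keep, fill=0.0),
        beta0_hat=_pad(beta0, keep, fill=0.0),
        loglik_trace=trace,
        converged=converged,
        grid=grid,
        run_index=design.run_index,
        kept_voxels=keep,
        posterior=posterior,
    )


def fit_null(Y, run_index, config: FitConfig | None = None,
             drift_order: int = 4) -> FitResult:
    """Fit the null model (no task-related component) to one subject.

    Identical assumptions to the full model except that no design
    matrix is assumed: only drift, intrinsic fluctuations and AR(1)
    noise, with rho marginalized on the grid's rho margin.
    """
    from .likelihood import null_grid_loglik

    config = config or FitConfig()
    Ymat = Y.Y if isinstance(Y, DataMatrix) else np.atleast_2d(np.asarray(Y, float))
    run_index = np.asarray(run_index)
    keep = np.ptp(Ymat, axis=0) > 0
    Ymat = Ymat[:, keep]
    drift = legendre_drift_basis(run_index, drift_order)
    Qd, _ = np.linalg.qr(drift)
    resid = Ymat - Qd @ (Qd.T @ Ymat)
    cap = config.rank_cap
    if cap is None:
        cap = min(Ymat.shape[0] // 10, 20)
    rank = (
        estimate_rank(resid, cap=cap)
        if config.rank_method == "auto"
        else int(config.rank_method)
    )
    X0 = estimate_X0(resid, rank, drift)
    rho_grid = config.grid.rho
    rho_w = config.grid.weights.sum(axis=1)
    rho_w = rho_w / rho_w.sum()
    lls = null_grid_loglik(Ymat, run_index, X0, rho_grid)  # (l, v)
    with np.errstate(divide="ignore"):
        logw = np.where(rho_w > 0, np.log(rho_w), -np.inf)
    logpost = lls + logw[:, None]
    trace = [float(logsumexp(logpost, axis=0).sum())]
    logpost -= logsumexp(logpost, axis=0, keepdims=True)
    w_post = np.exp(logpost)
    rho_mean = w_post.T @ rho_grid
    # per-rho residual quadratic forms and beta0 conditional means
    n_0 = X0.n_0
    n_T = Ymat.shape[0]
    d = n_T - n_0
    from .likelihood import _run_slices

    slices = _run_slices(run_index)
    sigma2 = np.zeros(Ymat.shape[1])
    beta0 = np.zeros((n_0, Ymat.shape[1]))
    for il, rho in enumerate(rho_grid):
        AY = _apply_ar1_unit(rho, slices, Ymat)
        yAy = np.einsum("tv,tv->v", Ymat, AY)
        if n_0:
            AX0 = _apply_ar1_unit(rho, slices, X0.X0)
            cho = cho_factor(X0.X0.T @ AX0)
            X0tAY = X0.X0.T @ AY
            sol = cho_solve(cho, X0tAY)
            yAsy = yAy - np.einsum("ov,ov->v", X0tAY, sol)
            beta0 += w_post[il][None, :] * sol
        else:
            yAsy = yAy
        sigma2 += w_post[il] * yAsy / (d - 4.0 if d > 4 else d)
    return FitResult(
        shared=None,
        X0_hat=X0,
        sigma2_hat=_pad(sigma2, keep),
        rho_hat=_pad(rho_mean, keep),
        snr_hat=None,
        beta_hat=None,
        beta0_hat=_pad(beta0, keep, fill=0.0),
        loglik_trace=trace,
        converged=True,
        grid=config.grid,
        run_index=run_index,
        kept_voxels=keep,
    )


# --------------------------------------------------------------------------
# Group fitting
# --------------------------------------------------------------------------


def fit_gbrsa(datasets, config: FitConfig | None = None):
    """Group BRSA: one shared U maximizing the joint marginal likelihood
    of all subjects' data.

    ``datasets`` is a sequence of ``(Y, design)`` pairs (designs may
    differ across subjects).  Returns ``(SharedCovariance,
    [FitResult, ...])``; only U is shared — nuisance models, grids and
    voxel posteriors remain per subject.
    """
    config = config or FitConfig()
    if len(datasets) < 2:
        raise ValueError("group fitting requires at least 2 subjects")
    subjects = []
    n_C = None
    for i, (Y, design) in enumerate(datasets):
        try:
            Ymat, keep, drift, X0, rank, c, _ = _prepare_subject(Y, design, config)
        except ValueError as err:
            raise ValueError(f"subject {i}: {err}") from err
        if n_C is None:
            n_C = design.n_C
        elif design.n_C != n_C:
            raise ValueError(f"subject {i} has {design.n_C} conditions, expected {n_C}")
        subjects.append(
            {"Y": Ymat, "keep": keep, "drift": drift, "X0": X0, "rank": rank,
             "c": c, "design": design}
        )
    grid = config.grid
    c0 = float(np.mean([s["c"] for s in subjects]))
    theta = _pack_L(c0 * np.eye(n_C))
    C_prev = None
    trace: list[float] = []
    converged = False
    per_subject: list[tuple] = []
    for it in range(config.max_outer_iters):
        stats = [_GridStats(s["Y"], s["design"], s["X0"].X0, grid) for s in subjects]
        theta, ll = _optimize_L(theta, stats, grid, config)
        trace.append(ll)
        L = _unpack_L(theta, n_C)
        C = covariance_to_correlation(L @ L.T)
        per_subject = [_posterior_pass(st, L, grid) for st in stats]
        if C_prev is not None and (
            np.max(np.abs(C - C_prev)) < config.convergence_tol
            or abs(trace[-1] - trace[-2]) < config.loglik_tol
        ):
            converged = True
            break
        C_prev = C
        if it < config.max_outer_iters - 1:
            for s, (post, sig2, beta, beta0) in zip(subjects, per_subject):
                resid = s["Y"] - s["design"].X @ beta
                s["X0"] = estimate_X0(resid, s["rank"], s["drift"])
    if not converged:
        warnings.warn("GBRSA fit did not converge within max_outer_iters", stacklevel=2)
    L = _unpack_L(theta, n_C)
    shared = SharedCovariance(L=L)
    results = []
    for s, (post, sig2, beta, beta0) in zip(subjects, per_subject):
        results.append(
            FitResult(
                shared=shared,
                X0_hat=s["X0"],
                sigma2_hat=_pad(sig2, s["keep"]),
                rho_hat=_pad(post.rho_mean, s["keep"]),
                snr_hat=_pad(post.snr_mean, s["keep"]),
                beta_hat=_pad(beta, s["keep"], fill=0.0),
                beta0_hat=_pad(beta0, s["keep"], fill=0.0),
                loglik_trace=trace,
                converged=converged,
                grid=grid,
                run_index=s["design"].run_index,
                kept_voxels=s["keep"],
                posterior=post,
            )
        )
    return shared, results
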