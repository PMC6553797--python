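"""Marginalized likelihood for Bayesian RSA.

The generative model for the time series of a single voxel ``k`` is

    Y_k = X beta_k + X0 beta0_k + eps_k

where ``X`` is the task design matrix, ``X0`` collects nuisance time
courses (slow drift plus shared intrinsic fluctuations), and ``eps_k``
is a stationary AR(1) noise process with voxel-specific coefficient
``rho_k`` and innovation variance ``sigma_k^2``.  The activity profile
``beta_k`` is drawn from N(0, (s_k sigma_k)^2 U) where ``U = L L^T`` is
the condition-by-condition covariance shared across voxels and ``s_k``
is the voxel's pseudo-SNR.

This module computes the log-likelihood of a voxel's data with
``beta_k``, ``beta0_k`` (flat prior) and ``sigma_k^2`` (improper flat
prior on sigma^2) integrated out analytically, and ``(rho_k, s_k)``
integrated numerically over a weighted grid.  With ``d = n_T - n_0``
the per-gridpoint log-likelihood is

    -(d/2) log(2 pi) + (n_runs/2) log(1 - rho^2)
    - (1/2) log|X0' A X0| + (1/2) log|Lambda*|
    + log Gamma(d/2 - 1) - (d/2 - 1) log(Q/2)

where ``A`` is the unit-variance AR(1) precision, ``A*`` its projection
off the column space of ``X0``, ``Lambda* = (I + s^2 L' X' A* X L)^{-1}``
and ``Q = Y' A* Y - s^2 (L' X' A* Y)' Lambda* (L' X' A* Y)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse
from numpy.polynomial import legendre
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.special import gammaln, logsumexp

logger = logging.getLogger("bayesrsa")

__all__ = [
    "TaskDesign",
    "DataMatrix",
    "NuisanceModel",
    "ArPrecision",
    "GridSpec",
    "SharedCovariance",
    "MarginalTerms",
    "legendre_drift_basis",
    "build_ar1_precision",
    "project_precision",
    "loglik_voxel_at_gridpoint",
    "loglik_voxel",
    "total_loglik",
    "null_loglik_voxel",
    "marginal_terms",
    "grid_loglik",
    "null_grid_loglik",
]


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


def _run_slices(run_index: np.ndarray) -> list[slice]:
    """Contiguous slices of equal run label (labels must be non-decreasing)."""
    run_index = np.asarray(run_index)
    if run_index.ndim != 1:
        raise ValueError("run_index must be 1-D")
    change = np.flatnonzero(np.diff(run_index) != 0) + 1
    bounds = np.concatenate(([0], change, [run_index.size]))
    labels = run_index[bounds[:-1]]
    if np.unique(labels).size != labels.size:
        raise ValueError("run_index must be non-decreasing (runs contiguous)")
    return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]


def legendre_drift_basis(run_index: np.ndarray, order: int = 4) -> np.ndarray:
    """Per-run Legendre polynomial drift regressors up to ``order``.

    Each run contributes ``order + 1`` columns (including the constant),
    evaluated on the run's volume index mapped to [-1, 1] and zero
    outside the run.
    """
    run_index = np.asarray(run_index)
    slices = _run_slices(run_index)
    n_T = run_index.size
    cols = []
    for sl in slices:
        n = sl.stop - sl.start
        t = np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1)
        for deg in range(order + 1):
            c = np.zeros(n_T)
            c[sl] = legendre.legval(t, np.eye(order + 1)[deg])
            cols.append(c)
    return np.column_stack(cols)


@dataclass
class TaskDesign:
    """Temporal model of the experiment: design matrix plus run structure.

    Parameters
    ----------
    X : (n_T, n_C) array
        Hypothesized response time course of each task condition
        (events convolved with the HRF).
    run_index : (n_T,) array
        Run label per time point; must be non-decreasing.
    TR : float
        Repetition time in seconds.
    drift_basis : (n_T, n_drift) array, optional
        Nuisance drift regressors.  Built on demand (per-run Legendre
        polynomials up to order 4) when not supplied.
    """

    X: np.ndarray
    run_index: np.ndarray
    TR: float = 2.0
    drift_basis: np.ndarray | None = None
    drift_order: int = 4

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] == 1 and self.X.shape[1] > 1:
            # a single column passed as a row vector
            self.X = self.X.T
        self.run_index = np.asarray(self.run_index)
        if self.run_index.size != self.X.shape[0]:
            raise ValueError(
                f"run_index length {self.run_index.size} does not match "
                f"n_T={self.X.shape[0]}"
            )
        self._slices = _run_slices(self.run_index)
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix X is rank deficient")
        if self.TR <= 0:
            raise ValueError("TR must be positive")
        if self.drift_basis is None:
            self.drift_basis = legendre_drift_basis(self.run_index, self.drift_order)
        else:
            self.drift_basis = np.asarray(self.drift_basis, dtype=float)

    @property
    def n_T(self) -> int:
        return self.X.shape[0]

    @property
    def n_C(self) -> int:
        return self.X.shape[1]

    @property
    def n_runs(self) -> int:
        return len(self._slices)

    @property
    def run_slices(self) -> list[slice]:
        return list(self._slices)

    @property
    def run_lengths(self) -> list[int]:
        return [sl.stop - sl.start for sl in self._slices]


@dataclass
class DataMatrix:
    """Observed time-by-voxel signal for one subject's region of interest."""

    Y: np.ndarray
    run_index: np.ndarray

    def __post_init__(self) -> None:
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        self.run_index = np.asarray(self.run_index)
        if not np.all(np.isfinite(self.Y)):
            bad = np.argwhere(~np.isfinite(self.Y))
            raise ValueError(f"data contain non-finite values, e.g. at {bad[:5].tolist()}")
        if self.run_index.size != self.Y.shape[0]:
            raise ValueError("run_index length does not match number of time points")

    @property
    def n_T(self) -> int:
        return self.Y.shape[0]

    @property
    def n_V(self) -> int:
        return self.Y.shape[1]


@dataclass
class NuisanceModel:
    """Nuisance time courses X0: drift regressors plus intrinsic fluctuations.

    The first ``n_drift`` columns are deterministic drift regressors;
    the remainder are data-derived shared fluctuation components.  The
    modulation of every column is marginalized under a flat prior.
    """

    X0: np.ndarray
    n_drift: int = 0

    def __post_init__(self) -> None:
        self.X0 = np.asarray(self.X0, dtype=float)
        if self.X0.ndim == 1:
            self.X0 = self.X0[:, None]
        if self.X0.shape[1]:
            if np.linalg.matrix_rank(self.X0) < self.X0.shape[1]:
                raise ValueError("X0 columns are linearly dependent")
            if self.X0.shape[1] >= self.X0.shape[0]:
                raise ValueError("X0 must have fewer columns than time points")

    @property
    def n_0(self) -> int:
        return self.X0.shape[1]

    @property
    def intrinsic(self) -> np.ndarray:
        """The data-derived (non-drift) columns."""
        return self.X0[:, self.n_drift:]


@dataclass
class ArPrecision:
    """Sparse AR(1) precision (inverse temporal covariance), one block per run.

    ``log_det_scaled`` is the log-determinant of the sigma^2-scaled
    precision, i.e. ``sum over runs of log(1 - rho^2)``; ``log_det`` is
    the log-determinant of the full precision matrix.
    """

    rho: float
    sigma2: float
    run_lengths: list[int]
    matrix: scipy.sparse.spmatrix
    log_det_scaled: float
    log_det: float


def build_ar1_precision(rho: float, sigma2: float, run_lengths) -> ArPrecision:
    """Block-diagonal tridiagonal precision of stationary per-run AR(1) noise.

    Each run block, scaled by sigma^2, has diagonal (1, 1+rho^2, ...,
    1+rho^2, 1) and off-diagonals -rho; its determinant is exactly
    1 - rho^2 regardless of run length.
    """
    if not abs(rho) < 1:
        raise ValueError(f"AR(1) coefficient must satisfy |rho| < 1, got {rho}")
    if sigma2 <= 0:
        raise ValueError("innovation variance sigma2 must be positive")
    run_lengths = [int(n) for n in run_lengths]
    if any(n < 2 for n in run_lengths):
        raise ValueError("each run must contain at least 2 time points")
    blocks = []
    for n in run_lengths:
        diag = np.full(n, 1.0 + rho**2)
        diag[0] = diag[-1] = 1.0
        off = np.full(n - 1, -rho)
        blocks.append(scipy.sparse.diags([off, diag, off], [-1, 0, 1]))
    mat = scipy.sparse.block_diag(blocks, format="csr") / sigma2
    n_T = sum(run_lengths)
    log_det_scaled = len(run_lengths) * np.log1p(-rho**2)
    return ArPrecision(
        rho=float(rho),
        sigma2=float(sigma2),
        run_lengths=run_lengths,
        matrix=mat,
        log_det_scaled=float(log_det_scaled),
        log_det=float(log_det_scaled - n_T * np.log(sigma2)),
    )


@dataclass
class GridSpec:
    """Discrete (rho, s) grid with prior weights for numerical marginalization.

    ``rho`` are the autoregressive-coefficient grid values, ``snr`` the
    pseudo-SNR grid values, and ``weights[l, m]`` the prior mass of cell
    (rho_l, s_m).  The default grid places rho at midpoints of
    equal-probability bins of a uniform prior on (-1, 1) and s at
    mass-matched quantiles of the chosen prior, so all weights are
    equal and the weighted sum is an unbiased quadrature of the prior.
    """

    rho: np.ndarray
    snr: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.atleast_1d(np.asarray(self.rho, dtype=float))
        self.snr = np.atleast_1d(np.asarray(self.snr, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.rho.size, self.snr.size):
            raise ValueError("weights must have shape (n_rho, n_snr)")
        if np.any(self.weights < 0):
            raise ValueError("grid weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("grid weights must sum to 1")
        if np.any(np.abs(self.rho) >= 1):
            raise ValueError("rho grid values must lie in (-1, 1)")
        if np.any(self.snr < 0):
            raise ValueError("snr grid values must be non-negative")

    @property
    def n_rho(self) -> int:
        return self.rho.size

    @property
    def n_snr(self) -> int:
        return self.snr.size

    @classmethod
    def default(
        cls,
        n_rho: int = 16,
        n_snr: int = 21,
        prior: str = "exponential",
        rate: float = 1.0,
        fixed_snr: float = 1.0,
        lognormal_mu: float = 0.0,
        lognormal_sigma: float = 1.0,
    ) -> "GridSpec":
        """Equal-mass grid for a uniform rho prior and the chosen s prior."""
        q_rho = (np.arange(n_rho) + 0.5) / n_rho
        rho = -1.0 + 2.0 * q_rho
        q_s = (np.arange(n_snr) + 0.5) / n_snr
        if prior == "exponential":
            snr = -np.log1p(-q_s) / rate
        elif prior == "uniform01":
            snr = q_s
        elif prior == "lognormal":
            from scipy.stats import norm

            snr = np.exp(lognormal_mu + lognormal_sigma * norm.ppf(q_s))
        elif prior == "fixed":
            snr = np.array([float(fixed_snr)])
            n_snr = 1
        else:
            raise ValueError(f"unknown pseudo-SNR prior {prior!r}")
        weights = np.full((n_rho, snr.size), 1.0 / (n_rho * snr.size))
        return cls(rho=rho, snr=snr, weights=weights)

    @classmethod
    def single(cls, rho: float, snr: float) -> "GridSpec":
        """A one-cell grid (degenerate prior at a single (rho, s) point)."""
        return cls(rho=[rho], snr=[snr], weights=np.ones((1, 1)))

    def rho_only(self) -> "GridSpec":
        """Collapse to the rho margin with s = 0 (null-model grid)."""
        w = self.weights.sum(axis=1, keepdims=True)
        return GridSpec(rho=self.rho, snr=[0.0], weights=w / w.sum())


@dataclass
class SharedCovariance:
    """Shared condition covariance U = L L^T and its correlation form C."""

    L: np.ndarray
    U: np.ndarray = field(init=False)
    C: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        self.U = self.L @ self.L.T
        self.C = covariance_to_correlation(self.U)


def covariance_to_correlation(U: np.ndarray, jitter: float = 1e-10) -> np.ndarray:
    """Rescale a PSD covariance to a correlation matrix with exact unit diagonal."""
    U = np.asarray(U, dtype=float)
    d = np.diag(U).copy()
    if np.any(d <= 0):
        eps = jitter * max(np.trace(U) / U.shape[0], 1.0)
        d = d + eps
        if np.any(d <= 0):
            raise ValueError("covariance has non-positive diagonal entries")
    scale = 1.0 / np.sqrt(d)
    C = U * np.outer(scale, scale)
    np.fill_diagonal(C, 1.0)
    return C


@dataclass
class MarginalTerms:
    """Dense intermediate quantities of the marginal likelihood (diagnostics)."""

    A_star: np.ndarray
    Lambda_star: np.ndarray
    mu_star: np.ndarray
    yAy: float
    quad_signal: float


# --------------------------------------------------------------------------
# AR(1) algebra (banded, no dense inversion)
# --------------------------------------------------------------------------


def _apply_ar1_unit(rho: float, run_slices: list[slice], M: np.ndarray) -> np.ndarray:
    """Product of the unit-variance AR(1) precision with the columns of M."""
    M = np.atleast_2d(M.T).T if M.ndim == 1 else M
    out = np.empty_like(M, dtype=float)
    for sl in run_slices:
        B = M[sl]
        coeff = np.full(B.shape[0], 1.0 + rho**2)
        coeff[0] = coeff[-1] = 1.0
        R = coeff[:, None] * B
        R[1:] -= rho * B[:-1]
        R[:-1] -= rho * B[1:]
        out[sl] = R
    return out


def project_precision(A, X0) -> np.ndarray:
    """Projected precision A* = A - A X0 (X0' A X0)^{-1} X0' A.

    Marginalizes the nuisance modulation beta0 under a flat prior: A*
    is symmetric and annihilates the column space of X0.  ``A`` may be
    an :class:`ArPrecision` or a dense/sparse matrix; ``X0`` a
    :class:`NuisanceModel` or array (possibly with zero columns).
    """
    Amat = A.matrix if isinstance(A, ArPrecision) else A
    Adense = Amat.toarray() if scipy.sparse.issparse(Amat) else np.asarray(Amat, float)
    X0m = X0.X0 if isinstance(X0, NuisanceModel) else np.asarray(X0, float)
    if X0m.ndim == 1:
        X0m = X0m[:, None]
    if X0m.shape[1] == 0:
        return Adense.copy()
    AX0 = Adense @ X0m
    G = X0m.T @ AX0
    try:
        cho = cho_factor(G)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "X0' A X0 is singular; nuisance columns "
            f"{list(range(X0m.shape[1]))} may be collinear"
        ) from err
    A_star = Adense - AX0 @ cho_solve(cho, AX0.T)
    return 0.5 * (A_star + A_star.T)


# --------------------------------------------------------------------------
# Grid log-likelihood engine
# --------------------------------------------------------------------------


def _as_X0_matrix(X0) -> np.ndarray:
    if X0 is None:
        return np.zeros((0, 0))
    if isinstance(X0, NuisanceModel):
        return X0.X0
    X0 = np.asarray(X0, dtype=float)
    return X0[:, None] if X0.ndim == 1 else X0


def _rho_stats(Y: np.ndarray, design: TaskDesign, X0m: np.ndarray, rho: float):
    """Sufficient statistics at one rho: projected Gram matrices and quad forms."""
    slices = design.run_slices
    X = design.X
    AX = _apply_ar1_unit(rho, slices, X)
    AY = _apply_ar1_unit(rho, slices, Y)
    XtAX = X.T @ AX
    XtAY = X.T @ AY
    yAy = np.einsum("tv,tv->v", Y, AY)
    if X0m.size and X0m.shape[1] > 0:
        AX0 = _apply_ar1_unit(rho, slices, X0m)
        G = X0m.T @ AX0
        try:
            cho = cho_factor(G)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"X0' A X0 singular at rho={rho:.3f}"
            ) from err
        logdet_G = 2.0 * np.sum(np.log(np.diag(cho[0])))
        X0tAX = X0m.T @ AX
        X0tAY = X0m.T @ AY
        sol_X = cho_solve(cho, X0tAX)
        sol_Y = cho_solve(cho, X0tAY)
        F = XtAX - X0tAX.T @ sol_X
        XtAsY = XtAY - X0tAX.T @ sol_Y
        yAsy = yAy - np.einsum("ov,ov->v", X0tAY, sol_Y)
    else:
        logdet_G = 0.0
        F = XtAX
        XtAsY = XtAY
        yAsy = yAy
    return F, XtAsY, yAsy, logdet_G


def grid_loglik(Y, design: TaskDesign, X0, L, grid: GridSpec) -> np.ndarray:
    """Per-gridpoint log-likelihood, shape (n_rho, n_snr, n_V).

    All analytic marginalizations (beta, beta0, sigma^2) applied; the
    (rho, s) grid left un-summed so callers can form either the
    marginal likelihood or grid posteriors.
    """
    Ymat = Y.Y if isinstance(Y, DataMatrix) else np.asarray(Y, dtype=float)
    if Ymat.ndim == 1:
        Ymat = Ymat[:, None]
    X0m = _as_X0_matrix(X0)
    L = np.asarray(L, dtype=float)
    n_T, n_V = Ymat.shape
    n_0 = X0m.shape[1] if X0m.size else 0
    d = n_T - n_0
    if d <= 2:
        raise ValueError(f"need n_T - n_0 > 2 for a proper sigma^2 marginal, got {d}")
    n_runs = design.n_runs
    const = -(d / 2.0) * np.log(2.0 * np.pi) + gammaln(d / 2.0 - 1.0)
    s2 = grid.snr**2
    out = np.empty((grid.n_rho, grid.n_snr, n_V))
    for il, rho in enumerate(grid.rho):
        F, XtAsY, yAsy, logdet_G = _rho_stats(Ymat, design, X0m, rho)
        K = L.T @ F @ L
        evals, evecs = eigh(0.5 * (K + K.T))
        evals = np.clip(evals, 0.0, None)
        M2 = (evecs.T @ (L.T @ XtAsY)) ** 2  # (n_C, n_V)
        denom = 1.0 + s2[:, None] * evals[None, :]  # (n_m, n_C)
        half_logdet_lam = -0.5 * np.sum(np.log(denom), axis=1)
        quad = (s2[:, None] / denom) @ M2  # (n_m, n_V)
        Q = yAsy[None, :] - quad
        if np.any(Q <= 0):
            raise FloatingPointError(
                "non-positive residual quadratic form; inputs are "
                f"ill-conditioned at rho={rho:.3f}"
            )
        out[il] = (
            const
            + (n_runs / 2.0) * np.log1p(-rho**2)
            - 0.5 * logdet_G
            + half_logdet_lam[:, None]
            - (d / 2.0 - 1.0) * np.log(Q / 2.0)
        )
    return out


def null_grid_loglik(Y, run_index, X0, rho_grid: np.ndarray) -> np.ndarray:
    """Null-model per-gridpoint log-likelihood, shape (n_rho, n_V).

    Same marginalizations as the full model but with no task design:
    equivalently the full model at s = 0.
    """
    Ymat = Y.Y if isinstance(Y, DataMatrix) else np.asarray(Y, dtype=float)
    if Ymat.ndim == 1:
        Ymat = Ymat[:, None]
    X0m = _as_X0_matrix(X0)
    run_index = np.asarray(run_index)
    slices = _run_slices(run_index)
    n_T, n_V = Ymat.shape
    n_0 = X0m.shape[1] if X0m.size else 0
    d = n_T - n_0
    if d <= 2:
        raise ValueError(f"need n_T - n_0 > 2 for a proper sigma^2 marginal, got {d}")
    n_runs = len(slices)
    const = -(d / 2.0) * np.log(2.0 * np.pi) + gammaln(d / 2.0 - 1.0)
    out = np.empty((len(rho_grid), n_V))
    for il, rho in enumerate(rho_grid):
        AY = _apply_ar1_unit(rho, slices, Ymat)
        yAy = np.einsum("tv,tv->v", Ymat, AY)
        if n_0:
            AX0 = _apply_ar1_unit(rho, slices, X0m)
            G = X0m.T @ AX0
            cho = cho_factor(G)
            logdet_G = 2.0 * np.sum(np.log(np.diag(cho[0])))
            X0tAY = X0m.T @ AY
            yAsy = yAy - np.einsum("ov,ov->v", X0tAY, cho_solve(cho, X0tAY))
        else:
            logdet_G = 0.0
            yAsy = yAy
        if np.any(yAsy <= 0):
            raise FloatingPointError("non-positive residual quadratic form")
        out[il] = (
            const
            + (n_runs / 2.0) * np.log1p(-rho**2)
            - 0.5 * logdet_G
            - (d / 2.0 - 1.0) * np.log(yAsy / 2.0)
        )
    return out


# --------------------------------------------------------------------------
# Public per-voxel operations
# --------------------------------------------------------------------------


def loglik_voxel_at_gridpoint(Y_k, design: TaskDesign, X0, L, rho: float, s: float) -> float:
    """Log-likelihood of one voxel's series at a single (rho, s) gridpoint,
    with beta, beta0 and sigma^2 analytically marginalized."""
    if s < 0:
        raise ValueError("pseudo-SNR s must be non-negative")
    vals = grid_loglik(np.asarray(Y_k, float), design, X0, L, GridSpec.single(rho, s))
    return float(vals[0, 0, 0])


def loglik_voxel(Y_k, design: TaskDesign, X0, L, grid: GridSpec) -> float:
    """Grid-marginalized log-likelihood of one voxel (stable log-sum-exp)."""
    vals = grid_loglik(np.asarray(Y_k, float), design, X0, L, grid)[:, :, 0]
    with np.errstate(divide="ignore"):
        logw = np.where(grid.weights > 0, np.log(grid.weights), -np.inf)
    total = logsumexp(vals + logw)
    if not np.isfinite(total):
        raise FloatingPointError("marginal likelihood vanished at every grid point")
    return float(total)


def total_loglik(Y, design: TaskDesign, X0, L, grid: GridSpec) -> float:
    """Sum over voxels of the grid-marginalized log-likelihood (Eq. of the model:
    voxels are conditionally independent given X0)."""
    Ymat = Y.Y if isinstance(Y, DataMatrix) else np.asarray(Y, dtype=float)
    if Ymat.ndim == 1:
        Ymat = Ymat[:, None]
    vals = grid_loglik(Ymat, design, X0, L, grid)
    with np.errstate(divide="ignore"):
        logw = np.where(grid.weights > 0, np.log(grid.weights), -np.inf)
    per_voxel = logsumexp(vals + logw[:, :, None], axis=(0, 1))
    bad = np.flatnonzero(~np.isfinite(per_voxel))
    if bad.size:
        raise FloatingPointError(
            f"marginal likelihood vanished for voxel(s) {bad[:5].tolist()}"
        )
    return float(per_voxel.sum())


def null_loglik_voxel(Y_k, run_index, X0, rho_grid, rho_weights) -> float:
    """Null-model marginal log-likelihood of one voxel (rho marginalized
    numerically, sigma^2 analytically, no task design)."""
    rho_grid = np.atleast_1d(np.asarray(rho_grid, float))
    rho_weights = np.atleast_1d(np.asarray(rho_weights, float))
    vals = null_grid_loglik(np.asarray(Y_k, float), run_index, X0, rho_grid)[:, 0]
    with np.errstate(divide="ignore"):
        logw = np.where(rho_weights > 0, np.log(rho_weights), -np.inf)
    total = logsumexp(vals + logw)
    if not np.isfinite(total):
        raise FloatingPointError("null marginal likelihood vanished at every grid point")
    return float(total)


def marginal_terms(Y_k, design: TaskDesign, X0, L, rho: float, s: float) -> MarginalTerms:
    """Dense diagnostic computation of A*, Lambda*, mu* and quadratic forms."""
    Y_k = np.asarray(Y_k, dtype=float).ravel()
    X0m = _as_X0_matrix(X0)
    L = np.asarray(L, dtype=float)
    A = build_ar1_precision(rho, 1.0, design.run_lengths)
    A_star = project_precision(A, X0m if X0m.size else np.zeros((design.n_T, 0)))
    F = design.X.T @ A_star @ design.X
    Lam_inv = np.eye(L.shape[1]) + s**2 * (L.T @ F @ L)
    Lambda_star = np.linalg.inv(Lam_inv)
    xi = L.T @ design.X.T @ (A_star @ Y_k)
    mu_star = s * Lambda_star @ xi
    yAy = float(Y_k @ A_star @ Y_k)
    quad_signal = float(s**2 * xi @ Lambda_star @ xi)
    return MarginalTerms(
        A_star=A_star,
        Lambda_star=Lambda_star,
        mu_star=mu_star,
        yAy=yAy,
        quad_signal=quad_signal,
    )
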