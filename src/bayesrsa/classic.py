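"""Point-estimate RSA baselines and the analytic bias theory.

Classic RSA first estimates activity patterns by linear regression,
``beta_hat = (X'X)^{-1} X' Y``, then measures similarity between the
rows of ``beta_hat``.  Because the regression maps the noise ``eps``
into structured noise ``(X'X)^{-1} X' eps``, the covariance of the
estimated patterns is the true covariance plus a bias matrix

    B = (X'X)^{-1} X' Sigma_eps X (X'X)^{-1}

which depends on the task timing (through X) and the temporal noise
covariance.  This module implements the estimators (OLS, per-voxel
AR(1) GLS, raw-pattern averaging via a delayed delta design), the
within-run and cross-run similarity measures, spatial whitening with
Ledoit-Wolf shrinkage, and the bias matrix itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.covariance import LedoitWolf

from .likelihood import TaskDesign, _apply_ar1_unit, covariance_to_correlation

__all__ = [
    "PatternEstimate",
    "SimilarityResult",
    "BiasMatrix",
    "glm_point_estimate",
    "glm_by_run",
    "pearson_similarity",
    "cross_run_similarity",
    "spatial_whiten",
    "euclidean_rdm",
    "theoretical_bias",
    "euclidean_bias",
    "delta6_patterns",
    "within_run_rsa",
]


@dataclass
class PatternEstimate:
    """Point-estimated activity patterns (condition by voxel) for one run
    or for all runs jointly."""

    beta_hat: np.ndarray
    estimator: str
    residuals: np.ndarray
    run_id: int | None = None


@dataclass
class SimilarityResult:
    """Condition-by-condition similarity (or distance) matrix with
    provenance."""

    C: np.ndarray
    metric: str  # "pearson" | "euclidean"
    scheme: str  # "within_run" | "cross_run"
    whitened: bool = False


@dataclass
class BiasMatrix:
    """The additive bias (X'X)^{-1} X' Sigma_eps X (X'X)^{-1} in the
    covariance of point-estimated patterns, and its unit-diagonal form."""

    B: np.ndarray
    normalized_bias: np.ndarray


# --------------------------------------------------------------------------
# Pattern estimation
# --------------------------------------------------------------------------


def _check_full_rank(M: np.ndarray, what: str) -> None:
    if np.linalg.matrix_rank(M) < M.shape[1]:
        # name the offending columns via the QR diagonal
        _, R = np.linalg.qr(M)
        diag = np.abs(np.diag(R))
        bad = np.flatnonzero(diag < 1e-10 * max(diag.max(), 1.0)).tolist()
        raise ValueError(f"{what} is rank deficient; collinear column(s) {bad}")


def _ar1_coef_from_residuals(resid: np.ndarray, run_slices) -> np.ndarray:
    """Per-voxel lag-1 regression coefficient, pooled across runs."""
    num = np.zeros(resid.shape[1])
    den = np.zeros(resid.shape[1])
    for sl in run_slices:
        r = resid[sl]
        num += np.einsum("tv,tv->v", r[1:], r[:-1])
        den += np.einsum("tv,tv->v", r[:-1], r[:-1])
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > 0, num / den, 0.0)
    return np.clip(rho, -0.99, 0.99)


def glm_point_estimate(Y, design: TaskDesign, estimator: str = "ols",
                       include_drift: bool = True) -> PatternEstimate:
    """Estimate activity patterns by regression on the design matrix.

    ``ols``: ordinary least squares.  ``gls_ar1``: AR(1) parameters are
    first estimated per voxel from OLS residuals by lag-1 regression,
    then patterns are re-estimated by generalized least squares under
    the per-voxel AR(1) noise covariance.  Drift regressors are
    appended to the design and their coefficients discarded.
    """
    Ymat = Y.Y if hasattr(Y, "Y") else np.asarray(Y, dtype=float)
    X = design.X
    Xfull = np.column_stack([X, design.drift_basis]) if include_drift else X
    _check_full_rank(Xfull, "design matrix (with drift)")
    n_C = design.n_C
    coef, *_ = np.linalg.lstsq(Xfull, Ymat, rcond=None)
    resid = Ymat - Xfull @ coef
    if estimator == "ols":
        return PatternEstimate(beta_hat=coef[:n_C], estimator="ols", residuals=resid)
    if estimator != "gls_ar1":
        raise ValueError(f"unknown estimator {estimator!r}")
    rho = _ar1_coef_from_residuals(resid, design.run_slices)
    beta = np.empty((Xfull.shape[1], Ymat.shape[1]))
    # group voxels with identical rho to reuse factorization (common in tests)
    for r in np.unique(rho):
        idx = np.flatnonzero(rho == r)
        AX = _apply_ar1_unit(r, design.run_slices, Xfull)
        G = Xfull.T @ AX
        beta[:, idx] = np.linalg.solve(G, AX.T @ Ymat[:, idx])
    resid_gls = Ymat - Xfull @ beta
    return PatternEstimate(beta_hat=beta[:n_C], estimator="gls_ar1",
                           residuals=resid_gls)


def glm_by_run(Y, design: TaskDesign, estimator: str = "ols") -> list[PatternEstimate]:
    """Fit patterns separately within each run (classic within-run RSA
    inputs).  Every condition must occur in every run."""
    Ymat = Y.Y if hasattr(Y, "Y") else np.asarray(Y, dtype=float)
    out = []
    for rid, sl in enumerate(design.run_slices):
        sub = TaskDesign(
            X=design.X[sl],
            run_index=design.run_index[sl],
            TR=design.TR,
            drift_basis=design.drift_basis[sl][:, np.abs(design.drift_basis[sl]).sum(axis=0) > 0],
        )
        est = glm_point_estimate(Ymat[sl], sub, estimator=estimator)
        est.run_id = rid
        out.append(est)
    return out


def delta6_patterns(Y, events, TR: float, n_T: int | None = None,
                    delay: float = 6.0) -> PatternEstimate:
    """Raw-pattern averaging as a GLM: unit impulses ``delay`` seconds
    after each event onset (nearest volume, ties rounding down), then OLS.

    This is the analysis whose bias samples the noise autocovariance at
    inter-event lags and whose signal term mixes the patterns of
    temporally adjacent conditions.
    """
    Ymat = Y.Y if hasattr(Y, "Y") else np.asarray(Y, dtype=float)
    if n_T is None:
        n_T = Ymat.shape[0]
    conditions = sorted(events["trial_type"].unique())
    X6 = np.zeros((n_T, len(conditions)))
    for j, cond in enumerate(conditions):
        sub = events[events["trial_type"] == cond]
        for onset in sub["onset"]:
            x = (onset + delay) / TR
            idx = int(np.floor(x + 0.5))
            if x % 1 == 0.5:
                idx -= 1
            if idx >= n_T:
                warnings.warn(
                    f"event at {onset:.1f}s: sampling point beyond scan end; dropped",
                    stacklevel=2,
                )
                continue
            X6[idx, j] += 1.0
    _check_full_rank(X6, "delta design X6")
    coef, *_ = np.linalg.lstsq(X6, Ymat, rcond=None)
    return PatternEstimate(beta_hat=coef, estimator="delta6",
                           residuals=Ymat - X6 @ coef)


# --------------------------------------------------------------------------
# Similarity measures
# --------------------------------------------------------------------------


def _standardize_rows(beta: np.ndarray) -> np.ndarray:
    n_V = beta.shape[1]
    centered = beta - beta.mean(axis=1, keepdims=True)
    sd = np.sqrt((centered**2).sum(axis=1) / n_V)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise ValueError(f"zero-variance pattern row(s) {bad}; similarity undefined")
    return centered / sd[:, None]


def pearson_similarity(patterns: PatternEstimate) -> SimilarityResult:
    """Within-run Pearson similarity between pattern rows (population-style
    normalization across voxels)."""
    beta = patterns.beta_hat
    if beta.shape[1] < 3:
        raise ValueError("need at least 3 voxels for pattern correlation")
    z = _standardize_rows(beta)
    C = z @ z.T / beta.shape[1]
    np.fill_diagonal(C, 1.0)
    return SimilarityResult(C=C, metric="pearson", scheme="within_run")


def cross_run_similarity(patterns: list[PatternEstimate]) -> SimilarityResult:
    """Average correlation between patterns estimated from different runs.

    All ordered run pairs (m, n), m != n, are averaged, so the output is
    symmetric; the diagonal is the cross-run reliability of each
    condition and is not constrained to 1 (it can even be negative for
    anti-correlated noise realizations).
    """
    if len(patterns) < 2:
        raise ValueError(
            "cross-run similarity can only be applied when there are more than one run"
        )
    zs = [_standardize_rows(p.beta_hat) for p in patterns]
    n_V = patterns[0].beta_hat.shape[1]
    n_runs = len(zs)
    C = np.zeros_like(zs[0] @ zs[0].T)
    for m in range(n_runs):
        for n in range(n_runs):
            if m != n:
                C += zs[m] @ zs[n].T / n_V
    C /= n_runs * (n_runs - 1)
    return SimilarityResult(C=0.5 * (C + C.T), metric="pearson", scheme="cross_run")


def spatial_whiten(patterns: list[PatternEstimate],
                   residuals: np.ndarray) -> list[PatternEstimate]:
    """Whiten patterns spatially using the residual noise covariance.

    One spatial covariance is estimated from the concatenated residuals
    of all runs with Ledoit-Wolf optimal shrinkage toward a scaled
    identity, and each run's patterns are right-multiplied by its
    inverse square root.
    """
    residuals = np.asarray(residuals, dtype=float)
    lw = LedoitWolf(assume_centered=False).fit(residuals)
    cov = lw.covariance_
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 1e-10, None)
    W = evecs @ np.diag(evals**-0.5) @ evecs.T
    out = []
    for p in patterns:
        out.append(
            PatternEstimate(
                beta_hat=p.beta_hat @ W,
                estimator=p.estimator,
                residuals=p.residuals @ W,
                run_id=p.run_id,
            )
        )
    return out


def euclidean_rdm(patterns: PatternEstimate) -> SimilarityResult:
    """Pairwise Euclidean distances between pattern rows."""
    D = squareform(pdist(patterns.beta_hat, metric="euclidean"))
    return SimilarityResult(C=D, metric="euclidean", scheme="within_run")


def within_run_rsa(Y, design: TaskDesign, estimator: str = "gls_ar1",
                   whiten: bool = False) -> SimilarityResult:
    """Convenience pipeline: per-run pattern estimates (optionally spatially
    whitened), averaged over runs, then Pearson similarity."""
    per_run = glm_by_run(Y, design, estimator=estimator)
    if whiten:
        resid = np.vstack([p.residuals for p in per_run])
        per_run = spatial_whiten(per_run, resid)
    mean_beta = np.mean([p.beta_hat for p in per_run], axis=0)
    merged = PatternEstimate(beta_hat=mean_beta, estimator=estimator,
                             residuals=np.vstack([p.residuals for p in per_run]))
    result = pearson_similarity(merged)
    result.whitened = whiten
    return result


# --------------------------------------------------------------------------
# Bias theory
# --------------------------------------------------------------------------


def theoretical_bias(design: TaskDesign, noise_cov="white",
                     sigma2: float = 1.0) -> BiasMatrix:
    """Bias matrix B = (X'X)^{-1} X' Sigma_eps X (X'X)^{-1}.

    ``noise_cov="white"`` uses Sigma_eps = sigma2 * I, for which B
    reduces to sigma2 (X'X)^{-1}.
    """
    X = design.X
    _check_full_rank(X, "design matrix")
    G = np.linalg.inv(X.T @ X)
    if isinstance(noise_cov, str):
        if noise_cov != "white":
            raise ValueError(f"unknown noise covariance {noise_cov!r}")
        B = sigma2 * G
    else:
        Sigma = np.asarray(noise_cov, dtype=float)
        if Sigma.shape != (design.n_T, design.n_T):
            raise ValueError(
                f"noise covariance has shape {Sigma.shape}, expected "
                f"({design.n_T}, {design.n_T})"
            )
        B = G @ X.T @ Sigma @ X @ G
    B = 0.5 * (B + B.T)
    return BiasMatrix(B=B, normalized_bias=covariance_to_correlation(B))


def euclidean_bias(bias: BiasMatrix, n_V: int) -> np.ndarray:
    """Additive bias n_V (B_ii + B_jj - 2 B_ij) in the expected squared
    Euclidean distance between noisy pattern estimates."""
    d = np.diag(bias.B)
    return n_V * (d[:, None] + d[None, :] - 2.0 * bias.B)
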