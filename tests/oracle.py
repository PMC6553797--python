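"""Brute-force reference computations used to validate the likelihood engine.

Everything here is deliberately naive: dense covariance matrices, explicit
Gaussian marginals over beta and beta0, and 1-D quadrature over sigma^2.
No banded algebra, no log-space grid tricks.
"""

import numpy as np
from scipy import integrate
from scipy.linalg import block_diag, toeplitz


def ar1_covariance_unit(rho, run_lengths):
    """Dense stationary AR(1) covariance with unit innovation variance:
    per-run blocks rho^|i-j| / (1 - rho^2)."""
    blocks = [
        toeplitz(rho ** np.arange(n)) / (1.0 - rho**2) for n in run_lengths
    ]
    return block_diag(*blocks)


def _log_density_given_sigma2(y, X, X0, U, rho, s, run_lengths, sigma2):
    """log p(y | sigma2, rho, s) with beta ~ N(0, (s sigma)^2 U) and beta0
    marginalized under a flat prior, everything dense."""
    n = y.size
    Sigma = ar1_covariance_unit(rho, run_lengths)
    V = sigma2 * (Sigma + s**2 * X @ U @ X.T)
    sign, logdet_V = np.linalg.slogdet(V)
    assert sign > 0
    M = np.linalg.inv(V)
    if X0 is not None and X0.size:
        X0 = X0 if X0.ndim == 2 else X0[:, None]
        G = X0.T @ M @ X0
        sign_G, logdet_G = np.linalg.slogdet(G)
        assert sign_G > 0
        M_star = M - M @ X0 @ np.linalg.inv(G) @ X0.T @ M
        n0 = X0.shape[1]
    else:
        logdet_G = 0.0
        M_star = M
        n0 = 0
    return (
        -0.5 * (n - n0) * np.log(2 * np.pi)
        - 0.5 * logdet_V
        - 0.5 * logdet_G
        - 0.5 * y @ M_star @ y
    )


def oracle_loglik_sigma_marginal(y, X, X0, U, rho, s, run_lengths):
    """log of integral over sigma^2 (flat improper prior) of the dense
    Gaussian marginal: analytic over beta and beta0, quadrature over sigma^2."""
    y = np.asarray(y, float).ravel()

    def logf(log_s2):
        return _log_density_given_sigma2(
            y, X, X0, U, rho, s, run_lengths, np.exp(log_s2)
        )

    # locate the mode on a coarse log-scale grid, then integrate around it
    grid = np.linspace(-12.0, 12.0, 241)
    vals = np.array([logf(u) for u in grid])
    shift = vals.max()

    def integrand(u):
        # flat prior on sigma^2: d sigma^2 = e^u du on the log scale
        return np.exp(logf(u) - shift + u)

    total, _ = integrate.quad(
        integrand, -14.0, 14.0, limit=400, epsabs=0.0, epsrel=1e-10
    )
    return shift + np.log(total)


def oracle_grid_marginal(y, X, X0, U_from_L, grid_rho, grid_snr, weights, run_lengths):
    """Naive weighted sum over the (rho, s) grid of exponentiated oracle
    likelihoods (no max-shift; relies on small instances)."""
    total = 0.0
    for il, rho in enumerate(grid_rho):
        for im, s in enumerate(grid_snr):
            ll = oracle_loglik_sigma_marginal(
                y, X, X0, U_from_L, rho, s, run_lengths
            )
            total += weights[il, im] * np.exp(ll)
    return np.log(total)
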