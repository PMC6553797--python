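# Methods

## The problem

Representational similarity analysis (RSA) asks how similar the
multivoxel activity patterns evoked by different task conditions are.
The classic recipe estimates each condition's pattern by linear
regression of the fMRI time series on a design matrix and then
correlates the estimated patterns.  Because regression maps the noise
`eps` into structured noise `(X'X)^{-1} X' eps`, the covariance of the
estimated patterns is

    Cov(beta_hat) = U + (X'X)^{-1} X' Sigma_eps X (X'X)^{-1}

where `U` is the true condition covariance and the second term — the
bias matrix `B` — depends on the task timing (through the design
correlations) and on the temporal covariance of the noise.  Whenever
consecutive events of different conditions fall within the width of the
hemodynamic response, or the noise is autocorrelated, `B` has structured
off-diagonal content and the measured similarity reflects the *task*
structure rather than the *representational* structure.  The bias is
worst at low SNR and for designs that cannot be counterbalanced
(sequential decision tasks, learning experiments).

## The model

Bayesian RSA (BRSA) avoids the point estimates entirely.  For voxel `k`,

    Y_k = X beta_k + X0 beta0_k + eps_k
    beta_k   ~ N(0, (s_k sigma_k)^2 U),   U = L L'
    eps_t,k  = rho_k eps_{t-1,k} + N(0, sigma_k^2)

`X0` collects nuisance time courses: per-run Legendre drift polynomials
(order 4) plus a small number of data-derived shared "intrinsic
fluctuation" components that carry the spatially correlated part of the
noise.  `s_k` is the voxel's pseudo-SNR — only the product with the
free magnitude of `U` is identified, so `s_k` is kept on a fixed prior
scale while `U` absorbs the overall magnitude.

The likelihood used for fitting marginalizes, per voxel:

* `beta_k` and `beta0_k` analytically (Gaussian and flat-improper
  priors respectively),
* `sigma_k^2` analytically under a flat improper prior on the variance
  — with `d = n_T - n_0` this yields the `Gamma(d/2 - 1)` /
  `(Q/2)^{1 - d/2}` closed form implemented in
  `bayesrsa.likelihood` (the residual quadratic form `Q` uses the
  projected precision `A* = A - A X0 (X0' A X0)^{-1} X0' A`),
* `(rho_k, s_k)` numerically on a weighted grid: 16 rho values at
  midpoints of equal-probability bins of a uniform prior on (-1, 1) and
  21 pseudo-SNR values at mass-matched quantiles of the s-prior
  (exponential with rate 1 by default; uniform(0,1), log-normal and
  fixed-point priors are available).  Equal-mass placement makes the
  weighted sum an unbiased quadrature of the prior.

The total log-likelihood is the sum over voxels (conditional
independence given `X0`), maximized over the `n_C (n_C + 1) / 2` free
entries of `L` (diagonal kept non-negative through a softplus
re-parameterization) with L-BFGS and an analytic gradient.  Similarity
is `C_ij = U_ij / sqrt(U_ii U_jj)`; the Cholesky parameterization makes
`U` and `C` positive semi-definite by construction.

Numerical notes: the AR(1) precision is applied as a banded operator
(never densely inverted); its sigma^2-scaled per-run determinant is
exactly `1 - rho^2`; grid sums use max-shifted log-sum-exp; per-rho
eigendecompositions of `L' X' A* X L` let all 336 grid cells share two
small matrix products.  A voxel whose series is (numerically) inside
the span of the nuisance model leaves a ~zero residual quadratic form;
the fitting engine floors `Q` at `1e-10` of the voxel's unprojected
energy rather than failing, while the public likelihood functions raise
on non-positive `Q` as a genuine ill-conditioning signal.

## Fitting procedure

`X0` is unknown, so fitting alternates:

1. initialize from an OLS fit with drift; estimate the number of shared
   residual components by the optimal-hard-threshold rule for singular
   values (`omega(beta) ~ 0.56 b^3 - 0.95 b^2 + 1.82 b + 1.43` times
   the median singular value), capped at `min(n_T / 10, 20)` so task
   signal is not absorbed; take that many left singular vectors of the
   drift-projected residuals;
2. maximize the marginal likelihood over `L` (warm-started);
3. recompute voxel grid posteriors and posterior-mean patterns
   `beta_hat = sum_cells w_cell s^2 L Lambda* L' X' A* Y_k`, then
   re-estimate the intrinsic components from `Y - X beta_hat`;
4. stop when the similarity matrix changes by less than `1e-4` (max
   absolute entry), when the log-likelihood improves by less than
   `1e-2`, or after 20 outer iterations.

The component *count* is chosen once at initialization and held fixed
across alternations: re-selecting it every iteration changes the
marginalization dimension `n_0`, which shifts the likelihood by
`n_0`-dependent constants and would make successive objective values
incomparable.  The log-likelihood stalling rule exists because on
null data `U` shrinks toward zero and the *correlation* matrix — a
ratio of vanishing quantities — never settles even though the fit has.
Residuals for the PCA step remove the posterior-mean task signal; the
alternative (marginal residuals) differs only at low SNR and was not
adopted.

Group fitting (GBRSA) shares only `L`: the objective is the sum of the
subjects' total log-likelihoods, and every subject keeps its own
nuisance model, grid posteriors and noise parameters.

Posterior voxel maps: `rho_hat`, `s_hat` and `sigma2_hat` are
grid-posterior means (`sigma^2 | cell` is inverse-gamma with mean
`Q / (d - 4)`); the pseudo-SNR map `s_hat` indicates where the learned
structure is supported.  Voxels constant in time are dropped up front
and reported as NaN in the maps.

## Model selection and decoding

For a left-out run, the log predictive probability of the test data is
computed per voxel from a Gaussian whose mean is `X_test beta_hat`
(zero for the null model, which is the same model with no task term)
and whose covariance is the posterior AR(1) noise plus the test-phase
intrinsic fluctuations.  The latter are unknown, so each training
component is carried over as a stationary AR(1) process matching its
training variance and lag-1 autocorrelation, scaled by the voxel's
fitted loading; test drift is marginalized under a flat prior.  Plugging
in grid-posterior means (rather than re-marginalizing the grid on test
data) keeps the test computation a single Gaussian evaluation and is an
acknowledged approximation.  Full-minus-null score differences across
subjects enter a one-sided t-test (alpha = 0.05); the full model's
extra log-determinant term penalizes its flexibility, so on pure noise
the differences are negative on average and false acceptance is rare.

Decoding treats the test-phase design and intrinsic courses as unknowns
with independent N(0, 1) priors per time point, jointly Gaussian with
the observation model: the posterior mean is one linear solve against a
block-tridiagonal precision assembled from the per-voxel AR(1)
precisions weighted by the fitted patterns.  Test data are detrended
first; the resulting slight misfit of the noise model is ignored for
the point estimate.

## Classic baselines and bias theory

`bayesrsa.classic` implements the estimators this method is compared
against: OLS and per-voxel AR(1)-GLS pattern estimation (drift
regressors appended), within-run Pearson similarity with
population-style normalization, cross-run similarity averaged over all
ordered run pairs (unbiased numerator, deflated magnitude,
unconstrained diagonal), spatial whitening via Ledoit-Wolf shrinkage of
the residual spatial covariance (inverse square root through an
eigendecomposition with a 1e-10 eigenvalue floor), Euclidean distance
matrices, the bias matrix `B` itself, its Euclidean-distance form
`n_V (B_ii + B_jj - 2 B_ij)` (the printed superscripts in some
renderings of this term are inconsistent with the variance-of-difference
identity; the implemented form is verified by a Monte-Carlo oracle),
and "raw-pattern averaging" formalized as a delta-function design 6 s
after each event (nearest volume, ties rounding down).

## The synthetic-data generator

The generator produces data with exactly the structure the model
assumes — making parameter-recovery tests exact — and emulates a
continuous sequential-decision experiment:

* 16 task states by default, transitions following a 3-category Markov
  graph with p = 0.5 branching (an approximate synthetic stand-in for a
  structured task graph, generalized to any `n_C >= 6`); uniform
  transitions for small `n_C`;
* events last 2.5 s (a reaction-time-scale duration) with uniform
  2.5-4.5 s inter-onset intervals at TR = 2.4 s — a quasi-continuous
  design whose HRF overlap produces the correlated design columns that
  drive the bias;
* boxcars convolved with the canonical double-gamma HRF (peak ~5 s,
  1/6-weighted undershoot at ~15 s, peak normalized to 1);
* per-voxel stationary AR(1) noise restarting at each run boundary,
  `rho ~ U(0, 0.8)`, `sigma ~ U(0.7, 1.3)`;
* 10 shared intrinsic components: 1/f-spectrum courses obtained by
  phase randomization (amplitude spectra preserved exactly), with
  Gaussian per-voxel loadings scaled by the voxel's noise sigma;
* activity profiles `beta_k ~ N(0, (scale * sigma_k)^2 U_true)` in a
  25% subset of "active" voxels (run lengths 182, 200 voxels by
  default); `target_snr` rescales the signal so the mean realized SNR —
  `std(X beta_k) / std(noise_k)` — over active voxels matches a stated
  study condition;
* model-violation switches (Laplace profiles, AR(2) noise) for
  robustness tests.

What the generator does *not* emulate: real fMRI noise is not AR(1)
plus an exactly low-rank shared term — it has long-memory spectra,
spatially smooth non-separable correlation, motion and physiological
artifacts.  Passing recovery tests on this generator therefore shows
the estimator is correct *under its own assumptions* and that the bias
mechanism is reproduced; it understates how much worse point-estimate
RSA fares on real noise, and overstates the benefit of AR(1)-GLS
estimation (which is exactly matched here).  Desk-scale problem sizes
(200 voxels, 1-2 runs of 90-300 time points, 20-replicate ensembles,
groups of 4 subjects for model selection) were chosen so the full suite
exercises every claim end-to-end in minutes; they are smaller than the
original ROI analyses (~4800 voxels, 24 subjects) and correspondingly
noisier per replicate.

## Known limitations

* A weak residual bias toward the design structure remains at very low
  SNR (the part of the intrinsic fluctuations not orthogonal to `X`
  cannot be separated); cross-validation is the guard, not a fix.
* Strong, high-rank intrinsic fluctuations (e.g. 15 components at 1.5x
  noise scale) can destabilize the fit itself — the alternation then
  trades task signal against nuisance components.  The default rank cap
  mitigates but does not remove this.
* The pseudo-SNR scale is identified only jointly with `|U|`; maps are
  comparable within a fit, not across fits.
* One HRF for all voxels; AR(1) noise only; no spatial smoothness
  priors; no leave-one-subject-out cross-validation.
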