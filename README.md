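# bayesrsa

Bayesian representational similarity analysis (BRSA) for fMRI time
series: direct estimation of the condition-by-condition covariance and
similarity of neural activity patterns from noisy data, by
marginalizing the unknown patterns instead of point-estimating them.

## Who this is for

Cognitive neuroscientists running RSA on task fMRI — especially with
designs that cannot be fully counterbalanced (sequential decision
tasks, learning experiments) or in regions with low SNR.  In those
regimes classic RSA is systematically biased: regressing the time
series `Y = X beta + eps` and correlating the estimated patterns adds
the structured-noise term

    B = (X'X)^{-1} X' Sigma_eps X (X'X)^{-1}

to the pattern covariance, so the measured "similarity" partly reflects
the task's timing structure and the noise autocorrelation, not the
neural code.

## The model

BRSA treats the shared covariance `U = L L'` as a hyper-parameter of a
generative model of the raw data.  For voxel `k`:

    Y_k = X beta_k + X0 beta0_k + eps_k,
    beta_k ~ N(0, (s_k sigma_k)^2 U),
    eps_k  ~ AR(1) with coefficient rho_k, innovation variance sigma_k^2,

where `X0` holds drift regressors and data-derived shared intrinsic
fluctuations.  The likelihood marginalizes `beta`, `beta0` and
`sigma^2` analytically and `(rho, s)` numerically on a prior grid;
maximizing it over the Cholesky factor `L` yields a positive
semi-definite similarity matrix `C_ij = U_ij / sqrt(U_ii U_jj)`.  The
package also provides group fitting (one `U` across subjects), a
pseudo-SNR map, cross-validated full-vs-null model selection, decoding
of task time courses from unlabeled data, the classic RSA baselines
(OLS / AR(1)-GLS patterns, within-run and cross-run similarity,
Ledoit-Wolf spatial whitening, Euclidean distances), the analytic bias
theory above, and a synthetic-data generator that reproduces the
model's assumptions exactly.  See `docs/methods.md` for the formulas
and all numerical choices.

## Worked example

```python
import numpy as np
from bayesrsa import SimulationConfig, simulate_dataset, fit_brsa, within_run_rsa

cfg = SimulationConfig(n_C=8, n_T_per_run=300, n_runs=1, n_V=200,
                       target_snr=0.5, true_U="four_block", seed=42)
ds = simulate_dataset(cfg)              # Markov task, AR(1)+intrinsic noise
fit = fit_brsa(ds.data, ds.design)      # marginal-likelihood fit of U
rsa = within_run_rsa(ds.data, ds.design, estimator="ols")

io = np.triu_indices(8, 1)
print(np.round(fit.shared.C[:4, :4], 2))
print(f"recovery r (BRSA):       {np.corrcoef(fit.shared.C[io], ds.C_true[io])[0,1]:.3f}")
print(f"recovery r (within-run): {np.corrcoef(rsa.C[io], ds.C_true[io])[0,1]:.3f}")
```

Output:

```
[[1.   0.85 0.31 0.18]
 [0.85 1.   0.32 0.24]
 [0.31 0.32 1.   0.83]
 [0.18 0.24 0.83 1.  ]]
recovery r (BRSA):       0.962
recovery r (within-run): 0.938
```

The simulated truth has four blocks of correlated conditions
(within-block similarity 0.8, zero across blocks); only a quarter of
the 200 voxels carry signal at a mean SNR of 0.5.  BRSA recovers the
block structure (off-diagonal correlation with the truth 0.96) and its
pseudo-SNR map separates the signal-carrying voxels (mean fitted
pseudo-SNR 2.98 in active vs 0.29 in inactive voxels).  The same
pipeline runs from the shell:

```bash
bayesrsa simulate --out sim --n-conditions 8 --n-voxels 200 --snr 0.5 --seed 42
bayesrsa fit --data sim/data.tsv --design sim/design.tsv --tr 2.4 --out fit
bayesrsa rsa --data sim/data.tsv --design sim/design.tsv --tr 2.4 \
             --estimator ols --out rsa
```

`crossval` (full-vs-null model selection on left-out runs) and `decode`
(posterior-mean task time courses from unlabeled data) complete the
CLI; every run writes a JSON record with its seed and config hash.

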