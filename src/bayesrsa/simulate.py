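"""Synthetic fMRI data with the exact statistical structure the model assumes.

The generator emulates the simulation regime used to study similarity-
structure recovery: a Markov-chain task sequence convolved with the
canonical double-gamma HRF, activity profiles drawn from a known
condition covariance in a subset of "active" voxels, voxelwise
stationary AR(1) noise with heterogeneous (rho, sigma), and a small set
of shared low-rank intrinsic fluctuations with 1/f-like, phase-
randomized spectra.  Optional switches (non-Gaussian profiles, AR(2)
noise) deliberately violate the model for robustness tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn

from .likelihood import DataMatrix, TaskDesign, covariance_to_correlation

logger = logging.getLogger("bayesrsa")

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "markov_task_sequence",
    "double_gamma_hrf",
    "build_design_matrix",
    "phase_randomize",
    "one_over_f_course",
    "simulate_noise",
    "simulate_dataset",
    "four_block_covariance",
    "sixteen_state_transition",
]


def four_block_covariance(n_C: int, within: float = 0.8) -> np.ndarray:
    """Unit-diagonal covariance with 4 equal blocks of mutually correlated
    conditions (correlation ``within`` inside a block, 0 across blocks)."""
    if n_C < 4:
        raise ValueError("need at least 4 conditions for a four-block structure")
    U = np.eye(n_C)
    sizes = [n_C // 4 + (1 if i < n_C % 4 else 0) for i in range(4)]
    start = 0
    for size in sizes:
        U[start : start + size, start : start + size] = within
        start += size
    np.fill_diagonal(U, 1.0)
    return U


def structured_transition(n_C: int) -> np.ndarray:
    """Markov chain over ``n_C`` states grouped into 3 categories, each
    state branching with p = 0.5 to two states of the next category
    (cyclically).  Produces a temporally structured, non-counterbalanced
    task sequence in which certain conditions systematically precede
    others — the regime where point-estimate RSA is most biased.
    """
    if n_C < 6:
        raise ValueError("structured transitions need at least 6 states")
    base = n_C // 3
    sizes = [base + (1 if i < n_C % 3 else 0) for i in range(3)]
    starts = np.concatenate(([0], np.cumsum(sizes)))
    P = np.zeros((n_C, n_C))
    for cat in range(3):
        nxt = (cat + 1) % 3
        for i in range(sizes[cat]):
            s = starts[cat] + i
            P[s, starts[nxt] + i % sizes[nxt]] += 0.5
            P[s, starts[nxt] + (i + 1) % sizes[nxt]] += 0.5
    return P


def sixteen_state_transition() -> np.ndarray:
    """A 16-state Markov chain grouped into 3 categories (sizes 6, 6, 4).

    Each state branches with p = 0.5 to two states of the next category,
    cycling category 1 -> 2 -> 3 -> 1.  This is an approximate,
    synthetic stand-in for a structured sequential task graph; it is
    not a reconstruction of any particular experiment.
    """
    P = np.zeros((16, 16))
    for i in range(6):  # category 1: states 0-5
        P[i, 6 + i % 6] += 0.5
        P[i, 6 + (i + 1) % 6] += 0.5
    for i in range(6):  # category 2: states 6-11
        P[6 + i, 12 + i % 4] += 0.5
        P[6 + i, 12 + (i + 1) % 4] += 0.5
    for i in range(4):  # category 3: states 12-15
        P[12 + i, i % 6] += 0.5
        P[12 + i, (i + 1) % 6] += 0.5
    return P


@dataclass
class SimulationConfig:
    """Study conditions for one simulated subject.

    Defaults mirror the desk-scale simulation regime: 16 task states in
    a Markov sequence at TR = 2.4 s, runs of 182 volumes, 200 voxels of
    which half carry signal, activity profiles scaled by ``snr_scale``
    times each voxel's noise standard deviation, and 3 shared intrinsic
    fluctuation components.  ``target_snr``, when set, rescales the
    signal globally so the mean realized SNR over active voxels equals
    the requested value.
    """

    n_C: int = 16
    n_T_per_run: int = 182
    n_runs: int = 1
    n_V: int = 200
    active_fraction: float = 0.25
    true_U: np.ndarray | str = "four_block"
    snr_scale: float = 4.0
    target_snr: float | None = None
    rho_range: tuple[float, float] = (0.0, 0.8)
    sigma_range: tuple[float, float] = (0.7, 1.3)
    n_intrinsic: int = 10
    intrinsic_scale: float = 1.0
    transition_matrix: np.ndarray | None = None
    TR: float = 2.4
    iti_range: tuple[float, float] = (2.5, 4.5)
    event_duration: float = 2.5
    beta_dist: str = "gaussian"  # or "laplace" (model violation)
    noise_model: str = "ar1"  # or "ar2" (model violation)
    ar2_coefs: tuple[float, float] = (0.5, 0.25)
    seed: int = 0

    def resolve_U(self) -> np.ndarray:
        if isinstance(self.true_U, str):
            if self.true_U == "four_block":
                return four_block_covariance(self.n_C)
            if self.true_U == "identity":
                return np.eye(self.n_C)
            raise ValueError(f"unknown covariance preset {self.true_U!r}")
        U = np.asarray(self.true_U, dtype=float)
        if U.shape != (self.n_C, self.n_C):
            raise ValueError("true_U has wrong shape")
        evals = np.linalg.eigvalsh(U)
        if evals.min() < -1e-10 * max(evals.max(), 1.0):
            raise ValueError("true_U must be positive semi-definite")
        return U

    def resolve_transitions(self) -> np.ndarray:
        if self.transition_matrix is None:
            if self.n_C == 16:
                return sixteen_state_transition()
            if self.n_C >= 6:
                return structured_transition(self.n_C)
            # few conditions: uniform transitions excluding self-repeats
            P = np.full((self.n_C, self.n_C), 1.0 / max(self.n_C - 1, 1))
            np.fill_diagonal(P, 0.0)
            if self.n_C == 1:
                P = np.ones((1, 1))
            return P
        return np.asarray(self.transition_matrix, dtype=float)


@dataclass
class SimulatedDataset:
    """A simulated subject with full ground truth attached."""

    data: DataMatrix
    design: TaskDesign
    events: pd.DataFrame
    beta_true: np.ndarray  # (n_C, n_V), zero in inactive voxels
    active_mask: np.ndarray  # (n_V,) bool
    U_true: np.ndarray
    C_true: np.ndarray
    X0_true: np.ndarray  # (n_T, n_intrinsic)
    beta0_true: np.ndarray  # (n_intrinsic, n_V)
    rho_true: np.ndarray
    sigma_true: np.ndarray
    realized_snr: np.ndarray  # (n_V,), std(X beta_k) / std(noise_k)
    config: SimulationConfig = field(repr=False, default=None)


# --------------------------------------------------------------------------
# Task sequence and design matrix
# --------------------------------------------------------------------------


def markov_task_sequence(transition_matrix, n_events: int, rng, init_state=None) -> np.ndarray:
    """Seeded condition sequence from a first-order Markov chain."""
    P = np.asarray(transition_matrix, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("transition matrix rows must be non-negative and sum to 1")
    if np.any(np.diag(P) == 1.0):
        warnings.warn("transition matrix has absorbing state(s)", stacklevel=2)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_states = P.shape[0]
    if n_events == 0:
        return np.empty(0, dtype=int)
    seq = np.empty(n_events, dtype=int)
    seq[0] = rng.integers(n_states) if init_state is None else int(init_state)
    cdf = np.cumsum(P, axis=1)
    draws = rng.random(n_events)
    for t in range(1, n_events):
        seq[t] = np.searchsorted(cdf[seq[t - 1]], draws[t])
    return seq


def double_gamma_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma hemodynamic response.

    Response gamma with shape 6 and unit time scale (peak ~5 s) minus a
    1/6-weighted undershoot gamma with shape 16 (trough ~15 s); peak
    amplitude normalized to 1.
    """
    t = np.asarray(t, dtype=float)
    h = np.where(
        t > 0,
        t ** 5 * np.exp(-t) / gamma_fn(6.0)
        - (1.0 / 6.0) * t ** 15 * np.exp(-t) / gamma_fn(16.0),
        0.0,
    )
    peak = (5.0**5) * np.exp(-5.0) / gamma_fn(6.0) - (1 / 6.0) * 5.0**15 * np.exp(
        -5.0
    ) / gamma_fn(16.0)
    return h / peak


def build_design_matrix(
    events: pd.DataFrame,
    TR: float,
    n_T: int,
    hrf: str = "double_gamma",
    oversample: int = 10,
    conditions=None,
) -> np.ndarray:
    """Convolve per-condition boxcars with the HRF, sampled at TR.

    ``events`` needs columns onset, duration, trial_type (BIDS events
    dialect).  Columns are ordered by sorted condition label unless an
    explicit ``conditions`` order is given.  Events that start beyond
    the scan are dropped with a warning; events overlapping the scan
    end are truncated.
    """
    if hrf != "double_gamma":
        raise ValueError(f"unknown HRF {hrf!r}")
    required = {"onset", "duration", "trial_type"}
    if not required.issubset(events.columns):
        raise ValueError(f"events table must have columns {sorted(required)}")
    if conditions is None:
        conditions = sorted(events["trial_type"].unique())
    scan_len = n_T * TR
    dt = TR / oversample
    n_fine = n_T * oversample
    t_hrf = np.arange(0, 32.0, dt)
    kernel = double_gamma_hrf(t_hrf)
    X = np.zeros((n_T, len(conditions)))
    fine_idx = np.arange(0, n_fine, oversample)  # sample at volume onsets
    for j, cond in enumerate(conditions):
        box = np.zeros(n_fine)
        sub = events[events["trial_type"] == cond]
        for onset, dur in zip(sub["onset"], sub["duration"]):
            if onset >= scan_len:
                warnings.warn(
                    f"event at {onset:.1f}s beyond scan end ({scan_len:.1f}s); dropped",
                    stacklevel=2,
                )
                continue
            if onset + dur > scan_len:
                warnings.warn(
                    f"event at {onset:.1f}s truncated at scan end", stacklevel=2
                )
            a = int(np.round(onset / dt))
            b = min(int(np.round((onset + dur) / dt)), n_fine)
            box[a : max(b, a + 1)] = 1.0
        conv = np.convolve(box, kernel)[:n_fine] * dt
        X[:, j] = conv[fine_idx]
    return X


# --------------------------------------------------------------------------
# Noise
# --------------------------------------------------------------------------


def phase_randomize(x: np.ndarray, rng) -> np.ndarray:
    """Randomize Fourier phases of a real series, preserving the amplitude
    spectrum exactly (DC and Nyquist bins keep zero phase)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = np.asarray(x, dtype=float)
    n = x.size
    spec = np.fft.rfft(x)
    phases = rng.uniform(0, 2 * np.pi, spec.size)
    phases[0] = 0.0
    if n % 2 == 0:
        phases[-1] = 0.0
    return np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=n)


def one_over_f_course(n_T: int, rng, exponent: float = 1.0) -> np.ndarray:
    """Smooth time course with a 1/f^exponent amplitude spectrum and random
    phases, standardized to zero mean and unit standard deviation."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    freqs = np.fft.rfftfreq(n_T, d=1.0)
    amps = np.zeros_like(freqs)
    amps[1:] = freqs[1:] ** (-exponent)
    template = np.fft.irfft(amps, n=n_T)
    course = phase_randomize(template, rng)
    course -= course.mean()
    sd = course.std()
    return course / sd if sd > 0 else course


def _ar_series(rho, sigma, run_lengths, rng, ar2=None):
    """Stationary AR noise, one column per voxel; restarts at each run."""
    n_V = rho.size
    cols = []
    for n in run_lengths:
        eps = np.empty((n, n_V))
        innov = rng.standard_normal((n, n_V)) * sigma
        if ar2 is None:
            eps[0] = innov[0] / np.sqrt(1.0 - rho**2)
            for t in range(1, n):
                eps[t] = rho * eps[t - 1] + innov[t]
        else:
            a1, a2 = ar2
            eps[0] = innov[0]
            eps[1] = a1 * eps[0] + innov[1]
            for t in range(2, n):
                eps[t] = a1 * eps[t - 1] + a2 * eps[t - 2] + innov[t]
        cols.append(eps)
    return np.vstack(cols)


def simulate_noise(config: SimulationConfig, rng=None):
    """Voxelwise AR noise plus shared intrinsic fluctuations.

    Returns ``(noise, X0_true, params)`` where ``noise`` is the full
    (n_T, n_V) task-unrelated signal, ``X0_true`` the (n_T, n_intrinsic)
    shared fluctuation courses, and ``params`` a dict with rho, sigma
    and beta0 draws.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng) \
        if not isinstance(rng, np.random.Generator) else rng
    n_T = config.n_T_per_run * config.n_runs
    run_lengths = [config.n_T_per_run] * config.n_runs
    rho = rng.uniform(*config.rho_range, size=config.n_V)
    sigma = rng.uniform(*config.sigma_range, size=config.n_V)
    ar2 = config.ar2_coefs if config.noise_model == "ar2" else None
    if config.noise_model not in ("ar1", "ar2"):
        raise ValueError(f"unknown noise model {config.noise_model!r}")
    noise = _ar_series(rho, sigma, run_lengths, rng, ar2=ar2)
    if config.n_intrinsic > 0:
        X0_true = np.column_stack(
            [one_over_f_course(n_T, rng) for _ in range(config.n_intrinsic)]
        )
        beta0 = rng.standard_normal((config.n_intrinsic, config.n_V)) * (
            config.intrinsic_scale * sigma
        )
        noise = noise + X0_true @ beta0
    else:
        X0_true = np.zeros((n_T, 0))
        beta0 = np.zeros((0, config.n_V))
    return noise, X0_true, {"rho": rho, "sigma": sigma, "beta0": beta0}


# --------------------------------------------------------------------------
# Full dataset
# --------------------------------------------------------------------------


def _make_events(config: SimulationConfig, rng) -> pd.DataFrame:
    """Markov event sequence per run with uniform inter-onset intervals.

    Resampled (bounded retries) until every condition occurs in every
    run, so per-run designs have full column rank.
    """
    P = config.resolve_transitions()
    frames = []
    scan_len = config.n_T_per_run * config.TR
    for run in range(config.n_runs):
        onsets = []
        t = float(rng.uniform(*config.iti_range))
        while t + config.event_duration < scan_len - 1e-9:
            onsets.append(t)
            t += float(rng.uniform(*config.iti_range))
        for attempt in range(50):
            seq = markov_task_sequence(P, len(onsets), rng)
            if np.unique(seq).size == config.n_C:
                break
        else:
            raise RuntimeError(
                "could not produce a sequence visiting every condition; "
                "run too short for n_C"
            )
        frames.append(
            pd.DataFrame(
                {
                    "onset": onsets,
                    "duration": config.event_duration,
                    "trial_type": seq,
                    "run": run,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate one subject: design, signal, noise and ground truth.

    Activity profiles of active voxels are drawn from
    N(0, (scale * sigma_k)^2 U_true) with ``scale = snr_scale``;
    inactive voxels carry no task signal.  The realized per-voxel SNR
    is std(X beta_k) / std(noise_k).
    """
    rng = np.random.default_rng(config.seed)
    U = config.resolve_U()
    events = _make_events(config, rng)
    # design built per run then stacked (conditions shared across runs)
    conditions = list(range(config.n_C))
    X_runs = []
    for run in range(config.n_runs):
        sub = events[events["run"] == run]
        X_runs.append(
            build_design_matrix(
                sub, config.TR, config.n_T_per_run, conditions=conditions
            )
        )
    X = np.vstack(X_runs)
    run_index = np.repeat(np.arange(config.n_runs), config.n_T_per_run)
    design = TaskDesign(X=X, run_index=run_index, TR=config.TR)

    noise, X0_true, params = simulate_noise(config, rng)
    n_active = int(round(config.active_fraction * config.n_V))
    active = np.zeros(config.n_V, dtype=bool)
    active[rng.choice(config.n_V, size=n_active, replace=False)] = True

    Lu = np.linalg.cholesky(U + 1e-12 * np.eye(config.n_C))
    if config.beta_dist == "gaussian":
        z = rng.standard_normal((config.n_C, config.n_V))
    elif config.beta_dist == "laplace":
        z = rng.laplace(scale=1.0 / np.sqrt(2.0), size=(config.n_C, config.n_V))
    else:
        raise ValueError(f"unknown beta distribution {config.beta_dist!r}")
    beta = Lu @ z * (config.snr_scale * params["sigma"])[None, :]
    beta[:, ~active] = 0.0

    noise_sd = noise.std(axis=0)
    if config.target_snr is not None and n_active > 0:
        signal_sd = (X @ beta).std(axis=0)
        current = np.mean(signal_sd[active] / noise_sd[active])
        if current > 0:
            beta *= config.target_snr / current
    signal = X @ beta
    with np.errstate(invalid="ignore", divide="ignore"):
        realized_snr = np.where(noise_sd > 0, signal.std(axis=0) / noise_sd, 0.0)

    Y = signal + noise
    return SimulatedDataset(
        data=DataMatrix(Y=Y, run_index=run_index),
        design=design,
        events=events,
        beta_true=beta,
        active_mask=active,
        U_true=U,
        C_true=covariance_to_correlation(U),
        X0_true=X0_true,
        beta0_true=params["beta0"],
        rho_true=params["rho"],
        sigma_true=params["sigma"],
        realized_snr=realized_snr,
        config=config,
    )
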