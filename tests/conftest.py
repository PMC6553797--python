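import sys
from pathlib import Path

import numpy as np
import pytest

# make the oracle helpers importable as `oracle` regardless of invocation dir
sys.path.insert(0, str(Path(__file__).parent))

from bayesrsa.likelihood import TaskDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


def random_tiny_instance(rng, n_T=None, n_C=None, n_0=None, n_runs=None):
    """A small random (y, design, X0, L) problem for oracle comparisons."""
    n_T = n_T or int(rng.integers(6, 11))
    n_C = n_C or int(rng.integers(1, 3))
    n_0 = n_0 if n_0 is not None else int(rng.integers(0, 2))
    n_runs = n_runs or (1 if n_T < 8 else int(rng.integers(1, 3)))
    # split n_T into runs of length >= 3
    if n_runs == 2:
        cut = int(rng.integers(3, n_T - 2))
        lengths = [cut, n_T - cut]
    else:
        lengths = [n_T]
    run_index = np.repeat(np.arange(n_runs), lengths)
    X = rng.standard_normal((n_T, n_C))
    design = TaskDesign(X=X, run_index=run_index, TR=1.0,
                        drift_basis=np.zeros((n_T, 0)))
    X0 = rng.standard_normal((n_T, n_0)) if n_0 else None
    A = rng.standard_normal((n_C, n_C))
    L = np.linalg.cholesky(A @ A.T + 0.5 * np.eye(n_C))
    y = rng.standard_normal(n_T)
    return y, design, X0, L, lengths
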