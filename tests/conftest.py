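"""Shared fixtures and generative helpers for the test suite."""

import numpy as np
import pytest

from adaptrate import ModelParams, TrialSeries


def prescribed_ar_series(A: float, Q: float, n: int, seed: int,
                         x_i: float = 0.0) -> TrialSeries:
    """Series from the linear error-correction process with a *known*
    adaptation rate: ``x_u[k+1] = x_u[k] + A (x_m[k] - x_i)`` with
    ``x_m = x_u + eta``, ``eta ~ N(0, Q)``.

    By construction the silver slope equals A exactly on every
    realization, and the population values are ``analytic = A`` and
    ``conventional = A - Q/(V + Q)`` with stationary error variance
    ``V = A^2 Q / (1 - (1 + A)^2)``.
    """
    rng = np.random.default_rng(seed)
    eta = rng.normal(0.0, np.sqrt(Q), n)
    x_u = np.empty(n)
    x_u[0] = x_i
    x_m = np.empty(n)
    for k in range(n - 1):
        x_m[k] = x_u[k] + eta[k]
        x_u[k + 1] = x_u[k] + A * (x_m[k] - x_i)
    x_m[n - 1] = x_u[n - 1] + eta[n - 1]
    return TrialSeries(x_m=x_m, x_i=x_i, x_u=x_u, eta_q=eta)


def conventional_closed_form(A: float, Q: float) -> float:
    """Population conventional AR for the prescribed-A process."""
    V = A ** 2 * Q / (1.0 - (1.0 + A) ** 2)
    return A - Q / (V + Q)


@pytest.fixture
def default_params() -> ModelParams:
    return ModelParams()  # Q=1, R=1, xi=0.1, B=1, B_hat=1, P_p=5, x_i=100


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
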