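"""Generative model of a Bayesian motor learner.

The learner is a two-layer hierarchical Kalman filter acting in a
scalar endpoint task (reach / toss / cursor movement to a target):

* **Planning** — the learner inverts its estimate ``B_hat`` of the true
  controller gain ``B`` to form a motor command ``u = x_i / B_hat`` aimed at
  the target ``x_i``.
* **Movement** — the command produces a noise-free endpoint ``x_u = B u``,
  corrupted by control noise ``eta_q ~ N(0, Q)`` into the measurable
  endpoint ``x_m`` (optionally plus a separately recorded stream of
  known, externally added control noise).
* **Sensing** — feedback noise ``eta_r ~ N(0, R)`` corrupts ``x_m`` into
  the sensed endpoint ``x_s``.
* **Perceiving (layer 1)** — a Kalman filter fuses the premotor
  prediction (the target, with variance from control noise plus
  propagated parameter uncertainty) with ``x_s`` into the perceived
  endpoint ``x_p``.
* **Learning (layer 2)** — a second Kalman filter treats ``x_p`` as a
  noisy measurement of the noise-free endpoint ``B u`` and updates
  ``B_hat``; its uncertainty ``P_p`` grows by the increment ``xi`` every
  trial, which keeps the learner adapting indefinitely.

All randomness flows through one :class:`numpy.random.Generator` seeded
per run, with a fixed draw order per trial, so a (params, seed) pair
reproduces a run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateGainError,
    TooShortSeriesError,
    UndefinedFusionError,
    UndefinedUpdateError,
)

__all__ = [
    "ModelParams",
    "TrialRecord",
    "SimulationResult",
    "plan_command",
    "execute_and_sense",
    "perceive",
    "update_parameter",
    "simulate_run",
    "simulate_batch",
    "GAIN_GUARD",
]

#: Below this |B_hat| the planned command is considered unbounded.
GAIN_GUARD = 1e-6

#: Canonical column order for trial-trace CSV output.
TRACE_COLUMNS = (
    "trial", "u", "x_u", "eta_q", "x_m", "eta_r", "x_s", "x_p", "B_hat", "P_p",
)


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the learner and of the world it acts in.

    Parameters
    ----------
    Q : float
        Control-noise variance (endpoint units squared).
    R : float
        Sensory (feedback) noise variance (endpoint units squared).
    xi : float
        Per-trial increment of the learner's parameter-estimate variance
        (gain-variance units). Implemented as additive process variance
        in the layer-2 predict step, not as a sampled perturbation of B.
    B : float
        True controller gain (dimensionless).
    B_hat_init : float
        Learner's initial estimate of the gain.
    P_p_init : float
        Initial parameter-estimate variance.
    x_i : float
        Intended target (endpoint units).
    """

    Q: float = 1.0
    R: float = 1.0
    xi: float = 0.1
    B: float = 1.0
    B_hat_init: float = 1.0
    P_p_init: float = 5.0
    x_i: float = 100.0

    def __post_init__(self) -> None:
        for name in ("Q", "R", "xi", "P_p_init"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        for name in ("B", "B_hat_init"):
            if getattr(self, name) == 0:
                raise ValueError(f"{name} must be nonzero")
        if not math.isfinite(self.x_i):
            raise ValueError("x_i must be finite")

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class TrialRecord:
    """Full latent + observable state of one trial (1-based index ``k``)."""

    k: int
    u: float
    x_u: float
    eta_q: float
    x_m: float
    eta_r: float
    x_s: float
    x_p: float
    B_hat: float
    P_p: float
    eta_add: float = 0.0


def plan_command(B_hat: float, x_i: float) -> float:
    """Plan the motor command ``u = x_i / B_hat`` by inverting the learner's
    internal model of the controller gain."""
    if abs(B_hat) < GAIN_GUARD:
        raise DegenerateGainError(
            f"|B_hat| = {abs(B_hat):.3g} below guard {GAIN_GUARD:g}; "
            "command would be unbounded"
        )
    return x_i / B_hat


def execute_and_sense(
    u: float, params: ModelParams, rng: np.random.Generator
) -> tuple[float, float, float, float, float]:
    """Execute command ``u`` and sense the outcome.

    Draw order is fixed (``eta_q`` first, then ``eta_r``) so that a seeded
    generator reproduces a movement exactly.

    Returns
    -------
    (x_u, eta_q, x_m, eta_r, x_s)
    """
    x_u = params.B * u
    eta_q = rng.normal(0.0, math.sqrt(params.Q))
    x_m = x_u + eta_q
    eta_r = rng.normal(0.0, math.sqrt(params.R))
    x_s = x_m + eta_r
    return x_u, eta_q, x_m, eta_r, x_s


def perceive(
    x_i: float, x_s: float, prior_var: float, R: float
) -> tuple[float, float]:
    """Layer-1 Kalman fusion of the premotor prediction and the sensed
    endpoint into the perceived endpoint ``x_p``.

    ``prior_var`` is the variance of the learner's pre-feedback prediction
    of where the movement will land; ``R`` the feedback-noise variance.
    """
    if prior_var < 0 or R < 0:
        raise ValueError("variances must be non-negative")
    denom = prior_var + R
    if denom == 0.0:
        if x_s != x_i:
            raise UndefinedFusionError(
                "prior_var = R = 0 but the sensed endpoint disagrees with "
                "the prediction"
            )
        return x_i, 0.0
    K1 = prior_var / denom
    x_p = x_i + K1 * (x_s - x_i)
    posterior_var = prior_var * R / denom
    return x_p, posterior_var


def update_parameter(
    B_hat: float, P_pred: float, u: float, x_p: float, obs_var: float
) -> tuple[float, float]:
    """Layer-2 Kalman update of the gain estimate.

    The percept ``x_p`` is treated as a measurement of the noise-free
    endpoint ``B_hat * u`` with measurement variance ``obs_var``.
    """
    if P_pred < 0 or obs_var < 0:
        raise ValueError("variances must be non-negative")
    nu = x_p - B_hat * u
    S = u * u * P_pred + obs_var
    if S == 0.0:
        if nu == 0.0:
            # fully certain and fully consistent: nothing to learn
            return B_hat, P_pred
        raise UndefinedUpdateError(
            "zero innovation variance (u^2 P + obs_var = 0) with nonzero "
            "innovation"
        )
    K2 = P_pred * u / S
    return B_hat + K2 * nu, (1.0 - K2 * u) * P_pred


@dataclass
class SimulationResult:
    """One simulated run, stored column-wise for speed.

    Attributes mirror the per-trial quantities of :class:`TrialRecord`;
    ``trials`` materializes the record list on demand.
    """

    params: ModelParams
    seed: int
    n_trials: int
    u: np.ndarray
    x_u: np.ndarray
    eta_q: np.ndarray
    x_m: np.ndarray
    eta_r: np.ndarray
    x_s: np.ndarray
    x_p: np.ndarray
    B_hat: np.ndarray
    P_p: np.ndarray
    eta_add: Optional[np.ndarray] = None
    added_noise_sd: float = 0.0
    obs_var_mode: str = "control+percept"
    _trials: Optional[list] = field(default=None, repr=False, compare=False)

    @property
    def trials(self) -> list[TrialRecord]:
        if self._trials is None:
            add = self.eta_add if self.eta_add is not None else np.zeros(self.n_trials)
            self._trials = [
                TrialRecord(
                    k + 1, self.u[k], self.x_u[k], self.eta_q[k], self.x_m[k],
                    self.eta_r[k], self.x_s[k], self.x_p[k], self.B_hat[k],
                    self.P_p[k], add[k],
                )
                for k in range(self.n_trials)
            ]
        return self._trials

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "trial": np.arange(1, self.n_trials + 1),
            "u": self.u, "x_u": self.x_u, "eta_q": self.eta_q,
            "x_m": self.x_m, "eta_r": self.eta_r, "x_s": self.x_s,
            "x_p": self.x_p, "B_hat": self.B_hat, "P_p": self.P_p,
        })
        if self.eta_add is not None:
            df["eta_add"] = self.eta_add
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.12g")

    def config_dict(self) -> dict:
        """Everything needed to replay this run bit-identically."""
        d = dataclasses.asdict(self.params)
        d.update(
            seed=int(self.seed),
            n_trials=int(self.n_trials),
            added_noise_sd=float(self.added_noise_sd),
            obs_var_mode=self.obs_var_mode,
        )
        return d


def simulate_run(
    params: ModelParams,
    n_trials: int,
    seed: int,
    *,
    added_noise_sd: float = 0.0,
    obs_var_mode: str = "control+percept",
    rng: Optional[np.random.Generator] = None,
) -> SimulationResult:
    """Simulate ``n_trials`` movements of the hierarchical Kalman learner.

    Per trial: inflate parameter uncertainty (``P_pred = P_p + xi``), plan,
    move and sense, perceive, update the gain estimate, record. The same
    ``P_pred`` feeds both layers within a trial.

    Parameters
    ----------
    added_noise_sd : float
        SD of externally added, per-trial *known* control noise (the
        experimental manipulation of the cursor task). It shifts the
        measurable endpoint exactly like intrinsic control noise and is
        recorded separately per trial; the learner's effective
        control-noise variance becomes ``Q + added_noise_sd**2``.
    obs_var_mode : {"control+percept", "percept"}
        Variance assigned to the percept as a layer-2 measurement of the
        noise-free endpoint. The default adds the control-noise variance
        to the perceptual posterior variance (the percept tracks the
        *noisy* endpoint, so as a measurement of ``B u`` it carries the
        control noise); ``"percept"`` uses the perceptual posterior
        variance alone.
    rng : numpy.random.Generator, optional
        Supply to continue an existing stream; otherwise one is created
        from ``seed``.
    """
    if n_trials < 2:
        raise TooShortSeriesError("n_trials must be >= 2")
    if obs_var_mode not in ("control+percept", "percept"):
        raise ValueError(f"unknown obs_var_mode {obs_var_mode!r}")
    if added_noise_sd < 0:
        raise ValueError("added_noise_sd must be >= 0")

    if rng is None:
        rng = np.random.default_rng(seed)

    with_add = added_noise_sd > 0
    # Pre-draw the whole noise stream; numpy draws a standard-normal array
    # in the same sequence as repeated scalar draws, so the per-trial order
    # (eta_q, [eta_add,] eta_r) is preserved.
    z = rng.standard_normal((n_trials, 3 if with_add else 2))
    sq = math.sqrt(params.Q)
    sr = math.sqrt(params.R)
    Q_eff = params.Q + added_noise_sd ** 2

    cols = {name: np.empty(n_trials) for name in
            ("u", "x_u", "eta_q", "x_m", "eta_r", "x_s", "x_p", "B_hat", "P_p")}
    eta_add = np.zeros(n_trials) if with_add else None

    B = params.B
    x_i = params.x_i
    xi = params.xi
    R = params.R
    B_hat = params.B_hat_init
    P_p = params.P_p_init

    try:
        for k in range(n_trials):
            P_pred = P_p + xi
            u = plan_command(B_hat, x_i)
            x_u = B * u
            eta_q = sq * z[k, 0]
            if with_add:
                add = added_noise_sd * z[k, 1]
                eta_add[k] = add
                eta_r = sr * z[k, 2]
            else:
                add = 0.0
                eta_r = sr * z[k, 1]
            x_m = x_u + eta_q + add
            x_s = x_m + eta_r
            # Premotor endpoint prediction: blurred by control noise and by
            # parameter uncertainty propagated through the command.
            prior_var = Q_eff + u * u * P_pred
            x_p, posterior_var = perceive(x_i, x_s, prior_var, R)
            obs_var = posterior_var if obs_var_mode == "percept" else Q_eff + posterior_var
            B_hat, P_p = update_parameter(B_hat, P_pred, u, x_p, obs_var)
            c = cols
            c["u"][k] = u
            c["x_u"][k] = x_u
            c["eta_q"][k] = eta_q
            c["x_m"][k] = x_m
            c["eta_r"][k] = eta_r
            c["x_s"][k] = x_s
            c["x_p"][k] = x_p
            c["B_hat"][k] = B_hat
            c["P_p"][k] = P_p
    except Exception as exc:
        exc.args = (f"trial {k + 1}: {exc}",)
        raise

    return SimulationResult(
        params=params, seed=seed, n_trials=n_trials, eta_add=eta_add,
        added_noise_sd=added_noise_sd, obs_var_mode=obs_var_mode, **cols,
    )


def simulate_batch(
    params: ModelParams, n_trials: int, n_sims: int, base_seed: int, **kwargs
) -> list[SimulationResult]:
    """Independent runs with seeds ``base_seed + 0 .. base_seed + n_sims - 1``
    (each run individually replayable)."""
    return [
        simulate_run(params, n_trials, base_seed + i, **kwargs)
        for i in range(n_sims)
    ]


def read_trace_csv(path) -> pd.DataFrame:
    """Read a trial-trace CSV written by :meth:`SimulationResult.to_csv`."""
    df = pd.read_csv(path)
    missing = [c for c in ("trial", "x_m") if c not in df.columns]
    if missing:
        from .exceptions import SchemaError
        raise SchemaError(f"trace CSV missing columns {missing}")
    return df
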