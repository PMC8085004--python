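"""Trial-by-trial adaptation-rate estimators.

The adaptation rate (AR) is the slope relating the trial-to-trial change
in movement output to the previous trial's error; a negative value means
the learner corrects its errors. Four estimators share the same slope
primitive and differ only in which endpoint domain supplies the change
(numerator) and the error (predictor):

========================  =====================  ==========================
estimator                 change (response)      error (predictor)
========================  =====================  ==========================
gold                      x_u[k+1] - x_u[k]      x_p[k] - x_i
silver                    x_u[k+1] - x_u[k]      x_m[k] - x_i
conventional              x_m[k+1] - x_m[k]      x_m[k] - x_i
analytic                  (covariance form, see :func:`ar_analytic`)
========================  =====================  ==========================

``x_u`` (noise-free endpoint) and ``x_p`` (perceived endpoint) are latent;
the gold and silver ARs are computable only from simulation traces or
experiments where the added control noise is known per trial
(``x_u = x_m - eta_q``). The analytic estimator removes the control-noise
bias of the conventional estimator using only measured endpoints plus the
control-noise variance Q:

    AR_analytic = (cov(x_m[k+1], x_m[k]) - var(x_m[k]) + Q) / var(x_m[k])

Conventions (applied consistently everywhere):

* cov and var are the unbiased (``ddof=1``) sample statistics over the
  n-1 lagged pairs, i.e. denominator ``(n-1) - 1 = n - 2``. The same
  denominator must be used for both because Q enters on an absolute scale.
* the denominator variance is computed over the predictor trials
  ``x_m[1..n-1]`` only;
* means are always subtracted (slope of a regression with intercept), so
  the target cancels out of centered quantities — estimates are invariant
  to a joint shift of all endpoints and the target;
* estimates are signed; absolute values are a reporting option only;
* a series must be contiguous and at least 3 trials long.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateVarianceError,
    MissingLatentError,
    NonContiguousSeriesError,
    SchemaError,
    TooShortSeriesError,
)

__all__ = [
    "TrialSeries",
    "ARSet",
    "slope_regression",
    "slope_analytic",
    "ar_conventional",
    "ar_silver",
    "ar_gold",
    "ar_analytic",
    "estimate_all",
]

MIN_TRIALS = 3  # at least 2 lagged pairs, so a slope with intercept exists


def _as1d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValueError("series must be one-dimensional")
    return a


@dataclass
class TrialSeries:
    """A contiguous sequence of trials toward a fixed target.

    Parameters
    ----------
    x_m : array-like
        Measured endpoints, in trial order.
    x_i : float
        Target (same units as the endpoints).
    x_u, x_p : array-like, optional
        Latent noise-free and perceived endpoints (from simulation).
    eta_q : array-like, optional
        Known per-trial added control noise; when given and ``x_u`` is
        absent, ``x_u = x_m - eta_q``.
    contiguous : bool
        Must be True for estimation; callers holding gapped data segment
        it first.
    """

    x_m: np.ndarray
    x_i: float
    x_u: Optional[np.ndarray] = None
    x_p: Optional[np.ndarray] = None
    eta_q: Optional[np.ndarray] = None
    contiguous: bool = True

    def __post_init__(self) -> None:
        self.x_m = _as1d(self.x_m)
        n = len(self.x_m)
        for name in ("x_u", "x_p", "eta_q"):
            v = getattr(self, name)
            if v is not None:
                v = _as1d(v)
                if len(v) != n:
                    raise ValueError(f"{name} length {len(v)} != x_m length {n}")
                setattr(self, name, v)
        self.x_i = float(self.x_i)

    def __len__(self) -> int:
        return len(self.x_m)

    @property
    def x_u_resolved(self) -> Optional[np.ndarray]:
        """x_u, reconstructed from the known control noise if needed."""
        if self.x_u is not None:
            return self.x_u
        if self.eta_q is not None:
            return self.x_m - self.eta_q
        return None

    @classmethod
    def from_simulation(cls, result, last: Optional[int] = None,
                        use_added_noise_only: bool = False) -> "TrialSeries":
        """Build a series from a :class:`~adaptrate.simulate.SimulationResult`.

        Parameters
        ----------
        last : int, optional
            Keep only the final ``last`` trials (e.g. the post-burn-in
            steady state).
        use_added_noise_only : bool
            Expose only the externally added noise stream as the known
            control noise (the empirical situation, where intrinsic
            control noise is unmeasurable) and drop the latents.
        """
        sl = slice(None) if last is None else slice(-last, None)
        if use_added_noise_only:
            add = result.eta_add if result.eta_add is not None else np.zeros(result.n_trials)
            return cls(x_m=result.x_m[sl], x_i=result.params.x_i, eta_q=add[sl])
        total_eta = result.x_m - result.x_u  # intrinsic + added control noise
        return cls(
            x_m=result.x_m[sl], x_i=result.params.x_i,
            x_u=result.x_u[sl], x_p=result.x_p[sl], eta_q=total_eta[sl],
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, x_i: Optional[float] = None,
                       endpoint_col: str = "x_m") -> "TrialSeries":
        """Build a series from a trace/empirical table.

        Recognizes the simulator trace schema (``x_m``, optional ``x_u``,
        ``x_p``, ``eta_q``/``eta_add``) and the empirical schema
        (``endpoint``, ``target``, ``added_noise``).
        """
        if endpoint_col not in df.columns and "endpoint" in df.columns:
            endpoint_col = "endpoint"
        if endpoint_col not in df.columns:
            raise SchemaError(
                f"no endpoint column ({endpoint_col!r} or 'endpoint') in "
                f"{list(df.columns)}"
            )
        x_m = df[endpoint_col].to_numpy(dtype=float)
        if x_i is None:
            for c in ("target", "x_i"):
                if c in df.columns:
                    tv = df[c].to_numpy(dtype=float)
                    if len(np.unique(tv)) > 1:
                        raise SchemaError("target column is not constant")
                    x_i = float(tv[0])
                    break
        if x_i is None:
            raise SchemaError("target not given and no target/x_i column")
        opt = {}
        for name, cands in (("x_u", ("x_u",)), ("x_p", ("x_p",)),
                            ("eta_q", ("eta_add", "added_noise", "eta_q"))):
            for c in cands:
                if c in df.columns:
                    opt[name] = df[c].to_numpy(dtype=float)
                    break
        return cls(x_m=x_m, x_i=x_i, **opt)

    @classmethod
    def from_csv(cls, path, x_i: Optional[float] = None) -> "TrialSeries":
        return cls.from_dataframe(pd.read_csv(path), x_i=x_i)


@dataclass
class ARSet:
    """The adaptation-rate estimates available for one trial sequence.

    Fields are ``None`` when the required inputs (latents, known noise,
    or Q) were not available.
    """

    conventional: Optional[float] = None
    analytic: Optional[float] = None
    silver: Optional[float] = None
    gold: Optional[float] = None
    n_trials_used: int = 0
    errors: dict = field(default_factory=dict)

    _ORDER = ("gold", "silver", "conventional", "analytic")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self._ORDER}
        d["n_trials_used"] = self.n_trials_used
        return d

    def to_series(self) -> pd.Series:
        return pd.Series(self.to_dict())

    def abs(self) -> "ARSet":
        """Magnitude view (reporting convention: plots show |AR|)."""
        return ARSet(
            **{k: (None if getattr(self, k) is None else abs(getattr(self, k)))
               for k in self._ORDER},
            n_trials_used=self.n_trials_used, errors=dict(self.errors),
        )


def _check_slope_inputs(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = _as1d(x)
    y = _as1d(y)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 2:
        raise TooShortSeriesError("need at least 2 points for a slope")
    if np.ptp(x) == 0.0:
        raise DegenerateVarianceError("predictor has zero variance")
    return x, y


def slope_regression(x, y) -> float:
    """Least-squares slope of ``y = a + b x`` via centered sums,
    ``sum((x - xbar)(y - ybar)) / sum((x - xbar)^2)``."""
    x, y = _check_slope_inputs(x, y)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = xc @ xc
    if sxx == 0.0:  # ptp > 0 can still underflow to zero variance
        raise DegenerateVarianceError("predictor has zero variance")
    return float(xc @ yc / sxx)


def slope_analytic(x, y) -> float:
    """The same slope in its probabilistic form ``cov(x, y) / var(x)``
    (identical normalization for cov and var, so algebraically equal to
    :func:`slope_regression`)."""
    x, y = _check_slope_inputs(x, y)
    vx = np.var(x, ddof=1)
    if vx == 0.0:
        raise DegenerateVarianceError("predictor has zero variance")
    return float(np.cov(x, y, ddof=1)[0, 1] / vx)


def _check_series(series: TrialSeries) -> None:
    if not series.contiguous:
        raise NonContiguousSeriesError(
            "series has gaps; segment it before estimating"
        )
    if len(series) < MIN_TRIALS:
        raise TooShortSeriesError(
            f"need >= {MIN_TRIALS} trials, got {len(series)}"
        )


def ar_conventional(series: TrialSeries) -> float:
    """Conventional regression AR: slope of ``x_m[k+1] - x_m[k]`` on
    ``x_m[k] - x_i``. Biased by control noise (toward -1 for pure noise)."""
    _check_series(series)
    xm = series.x_m
    return slope_regression(xm[:-1] - series.x_i, np.diff(xm))


def ar_silver(series: TrialSeries) -> float:
    """Silver AR: slope of ``x_u[k+1] - x_u[k]`` on ``x_m[k] - x_i``,
    with ``x_u = x_m - eta_q`` when only the per-trial noise is known."""
    _check_series(series)
    x_u = series.x_u_resolved
    if x_u is None:
        raise MissingLatentError("silver AR needs x_u or per-trial eta_q")
    return slope_regression(series.x_m[:-1] - series.x_i, np.diff(x_u))


def ar_gold(series: TrialSeries) -> float:
    """Gold-standard AR: slope of ``x_u[k+1] - x_u[k]`` on
    ``x_p[k] - x_i``. Unmeasurable outside simulation (both domains are
    latent); the reference the other estimators are judged against."""
    _check_series(series)
    x_u = series.x_u_resolved
    if x_u is None or series.x_p is None:
        raise MissingLatentError("gold AR needs x_u (or eta_q) and x_p")
    return slope_regression(series.x_p[:-1] - series.x_i, np.diff(x_u))


def ar_analytic(series: TrialSeries, Q: float) -> float:
    """Covariance-based AR with the control-noise bias removed:

        (cov(x_m[k+1], x_m[k]) - var(x_m[k]) + Q) / var(x_m[k])

    cov and var use ddof=1 over the n-1 lagged pairs; var is over the
    predictor trials ``x_m[1..n-1]``. With Q = 0 this reduces exactly to
    the conventional estimator.
    """
    _check_series(series)
    if Q < 0:
        raise ValueError("Q must be >= 0")
    a = series.x_m[:-1]
    b = series.x_m[1:]
    va = np.var(a, ddof=1)
    if va == 0.0:
        raise DegenerateVarianceError("predictor trials have zero variance")
    cab = np.cov(a, b, ddof=1)[0, 1]
    return float((cab - va + Q) / va)


def estimate_all(
    series: TrialSeries, Q: Optional[float] = None, report_abs: bool = False
) -> ARSet:
    """Compute every estimator whose inputs are available.

    Missing latents (or a missing Q for the analytic estimator) leave the
    corresponding field ``None``; per-estimator errors (e.g. degenerate
    variance) are recorded in ``ARSet.errors`` instead of propagating, so
    batch pipelines get partial results.
    """
    _check_series(series)
    out = ARSet(n_trials_used=len(series))

    def attempt(name, fn, *args):
        try:
            setattr(out, name, fn(*args))
        except MissingLatentError:
            pass
        except (DegenerateVarianceError, TooShortSeriesError) as exc:
            out.errors[name] = str(exc)

    attempt("conventional", ar_conventional, series)
    attempt("silver", ar_silver, series)
    attempt("gold", ar_gold, series)
    if Q is not None:
        attempt("analytic", ar_analytic, series, Q)
    return out.abs() if report_abs else out
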