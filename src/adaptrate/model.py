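"""statsmodels-style front end: ``AdaptationModel(...).fit() -> AdaptationResults``.

The model object holds a :class:`~adaptrate.estimators.TrialSeries` plus
the control-noise variance; ``fit`` evaluates every adaptation-rate
estimator the data support and packages them with uncertainties and a
``summary()`` table.

Standard errors: the gold, silver and conventional ARs are ordinary
regression slopes, so their classical OLS slope standard errors are
reported. The analytic AR is a ratio of lagged moment estimates with no
closed-form small-sample SE; a circular block bootstrap over the lagged
pairs (block length ~ n^(1/3), preserving serial dependence) is used for
it, and can optionally replace the OLS SEs for the others as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .estimators import ARSet, TrialSeries, ar_analytic, estimate_all
from .exceptions import TooShortSeriesError

__all__ = ["AdaptationModel", "AdaptationResults"]


def _ols_slope_se(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 3:
        return float("nan")
    xc = x - x.mean()
    sxx = xc @ xc
    if sxx == 0:
        return float("nan")
    b = (xc @ (y - y.mean())) / sxx
    resid = (y - y.mean()) - b * xc
    s2 = (resid @ resid) / (n - 2)
    return float(np.sqrt(s2 / sxx))


class AdaptationModel:
    """Trial-by-trial adaptation-rate model for one movement sequence.

    Parameters
    ----------
    series : TrialSeries
        Contiguous endpoint sequence toward a fixed target, optionally
        carrying latents / known per-trial control noise.
    q_control : float, optional
        Control-noise variance Q (endpoint units squared) for the
        analytic estimator. For an experiment with externally added
        noise this is the *added* variance; for free behavior it must be
        measured separately (e.g. endpoint variance without feedback).
    """

    def __init__(self, series: TrialSeries, q_control: Optional[float] = None):
        self.series = series
        self.q_control = q_control

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, target: Optional[float] = None,
                       q_control: Optional[float] = None) -> "AdaptationModel":
        """Build from a trace/empirical table (see
        :meth:`TrialSeries.from_dataframe` for recognized schemas)."""
        return cls(TrialSeries.from_dataframe(df, x_i=target), q_control)

    @classmethod
    def from_simulation(cls, result, last: Optional[int] = None) -> "AdaptationModel":
        series = TrialSeries.from_simulation(result, last=last)
        q = result.params.Q + result.added_noise_sd ** 2
        return cls(series, q_control=q)

    def fit(self, absolute: bool = False, n_boot: int = 0,
            seed: Optional[int] = None) -> "AdaptationResults":
        """Estimate all available adaptation rates.

        Parameters
        ----------
        absolute : bool
            Report magnitudes |AR| (plotting convention). Signed
            estimates remain available on the result.
        n_boot : int
            Circular-block-bootstrap replicates for standard errors of
            the analytic AR (and, when > 0, of all estimators). 0
            disables the bootstrap; the analytic SE is then NaN.
        seed : int, optional
            Bootstrap RNG seed.
        """
        arset = estimate_all(self.series, Q=self.q_control)
        ses = self._ols_ses(arset)
        if n_boot > 0:
            ses.update(self._bootstrap_ses(n_boot, seed))
        return AdaptationResults(self, arset, ses, absolute=absolute)

    # -- uncertainties -------------------------------------------------
    def _ols_ses(self, arset: ARSet) -> dict:
        s = self.series
        ses: dict[str, float] = {}
        xm = s.x_m
        if arset.conventional is not None:
            ses["conventional"] = _ols_slope_se(xm[:-1] - s.x_i, np.diff(xm))
        x_u = s.x_u_resolved
        if arset.silver is not None and x_u is not None:
            ses["silver"] = _ols_slope_se(xm[:-1] - s.x_i, np.diff(x_u))
        if arset.gold is not None and x_u is not None and s.x_p is not None:
            ses["gold"] = _ols_slope_se(s.x_p[:-1] - s.x_i, np.diff(x_u))
        return ses

    def _bootstrap_ses(self, n_boot: int, seed: Optional[int]) -> dict:
        rng = np.random.default_rng(seed)
        s = self.series
        n = len(s) - 1  # lagged pairs
        if n < 4:
            return {}
        block = max(2, int(round(n ** (1.0 / 3.0))))
        names = [k for k in ARSet._ORDER]
        reps: dict[str, list[float]] = {k: [] for k in names}
        starts_max = n
        n_blocks = int(np.ceil(n / block))
        for _ in range(n_boot):
            starts = rng.integers(0, starts_max, size=n_blocks)
            idx = (starts[:, None] + np.arange(block)[None, :]).ravel() % n
            idx = idx[:n]
            boot = TrialSeries(
                x_m=np.append(s.x_m[idx], s.x_m[idx[-1] + 1]),
                x_i=s.x_i,
                x_u=None if s.x_u is None else np.append(s.x_u[idx], s.x_u[idx[-1] + 1]),
                x_p=None if s.x_p is None else np.append(s.x_p[idx], s.x_p[idx[-1] + 1]),
                eta_q=None if s.eta_q is None else np.append(s.eta_q[idx], s.eta_q[idx[-1] + 1]),
            )
            bset = estimate_all(boot, Q=self.q_control)
            for k in names:
                v = getattr(bset, k)
                if v is not None:
                    reps[k].append(v)
        return {k: float(np.std(v, ddof=1)) for k, v in reps.items() if len(v) > 1}


@dataclass
class AdaptationResults:
    """Fitted adaptation rates with uncertainties.

    Attributes
    ----------
    arset : ARSet
        The signed estimates (``None`` where not computable).
    bse : dict
        Standard error per estimator (may be missing for the analytic
        estimator unless a bootstrap was requested).
    """

    model: AdaptationModel
    arset: ARSet
    bse: dict
    absolute: bool = False

    @property
    def n_trials_used(self) -> int:
        return self.arset.n_trials_used

    @property
    def params(self) -> pd.Series:
        """Estimates as reported (absolute if requested at fit time)."""
        view = self.arset.abs() if self.absolute else self.arset
        return pd.Series({k: getattr(view, k) for k in ARSet._ORDER},
                         name="adaptation_rate")

    def __getattr__(self, name):
        if name in ARSet._ORDER:
            return getattr(self.arset, name)
        raise AttributeError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        view = self.arset.abs() if self.absolute else self.arset
        for k in ARSet._ORDER:
            v = getattr(view, k)
            if v is None:
                continue
            rows.append({"estimator": k, "estimate": v,
                         "se": self.bse.get(k, float("nan"))})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        s = self.model.series
        q = self.model.q_control
        lines = [
            "Trial-by-trial Adaptation Rate Estimates",
            "=" * 58,
            f"Trials used:         {self.n_trials_used}",
            f"Target (x_i):        {s.x_i:g}",
            f"Control noise Q:     {'n/a' if q is None else format(q, 'g')}",
            f"Reporting:           {'|AR| (absolute)' if self.absolute else 'signed'}",
            "-" * 58,
            f"{'estimator':<14}{'estimate':>12}{'std err':>12}",
            "-" * 58,
        ]
        for _, row in self.to_frame().iterrows():
            se = row["se"]
            se_s = f"{se:>12.4f}" if np.isfinite(se) else f"{'--':>12}"
            lines.append(f"{row['estimator']:<14}{row['estimate']:>12.4f}{se_s}")
        lines.append("-" * 58)
        absent = [k for k in ARSet._ORDER if getattr(self.arset, k) is None]
        if absent:
            lines.append("not computable from these inputs: " + ", ".join(absent))
        if self.arset.errors:
            for k, msg in self.arset.errors.items():
                lines.append(f"{k}: failed ({msg})")
        return "\n".join(lines)
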