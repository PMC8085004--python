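"""Simulation studies: parameter sweeps and the analysis-window study.

``run_sweep`` varies one of the generative noise parameters (Q, R or xi)
over a log-spaced grid, simulates many learner runs per grid value, and
compares the estimators — per-run — against the gold-standard AR (mean,
SD and mean squared error). ``run_window_study`` fixes the parameters
and varies how many steady-state trials the estimators see, summarizing
run-to-run variability per window size.

Reference scale (full study): 100 grid values from 1e-2 to 1e2, 1000
simulations per value, 1500 trials each with the last 1000 analyzed;
window study: 10,000 runs of 2000 trials, 99 windows from 20 to 1000
trials starting at trial 1000. Both functions accept scaled-down
configurations; all results carry the seeds needed to replay them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .estimators import ARSet, TrialSeries, estimate_all
from .exceptions import WindowOverflowError
from .simulate import ModelParams, simulate_run

__all__ = ["SweepConfig", "SweepResult", "run_sweep",
           "WindowStudyResult", "run_window_study", "default_windows"]

ESTIMATORS = list(ARSet._ORDER)  # gold, silver, conventional, analytic


def log_grid(n: int = 100, lo: float = 1e-2, hi: float = 1e2) -> np.ndarray:
    """``n`` equally spaced values on a log10 scale, endpoints included."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of a one-parameter sweep.

    ``varied`` is one of ``"Q"``, ``"R"``, ``"xi"``; the other
    parameters are held at ``fixed``.
    """

    varied: str = "Q"
    grid: np.ndarray = field(default_factory=log_grid)
    fixed: ModelParams = field(default_factory=ModelParams)
    n_sims: int = 1000
    n_trials: int = 1500
    analyze_last: int = 1000
    seed: int = 0
    obs_var_mode: str = "control+percept"

    def __post_init__(self) -> None:
        if self.varied not in ("Q", "R", "xi"):
            raise ValueError(f"varied must be Q, R or xi, got {self.varied!r}")
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 1 or len(g) < 1 or np.any(np.diff(g) <= 0):
            raise ValueError("grid must be strictly increasing")
        object.__setattr__(self, "grid", g)
        if self.analyze_last > self.n_trials:
            raise ValueError("analyze_last must be <= n_trials")

    def to_dict(self) -> dict:
        import dataclasses
        return {
            "varied": self.varied,
            "grid": [float(v) for v in self.grid],
            "fixed": dataclasses.asdict(self.fixed),
            "n_sims": self.n_sims,
            "n_trials": self.n_trials,
            "analyze_last": self.analyze_last,
            "seed": self.seed,
            "obs_var_mode": self.obs_var_mode,
        }


@dataclass
class SweepResult:
    """Sweep summary plus (optionally) the raw per-run estimates.

    ``table`` has one row per grid value with, for each estimator,
    the mean/SD of the signed estimates, the mean of |AR| (the plotting
    convention), and the MSE against the per-run gold AR.
    """

    config: SweepConfig
    table: pd.DataFrame
    raw: Optional[np.ndarray] = None  # (n_grid, n_sims, 4), NaN where absent

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")


def _estimate_run(params: ModelParams, n_trials: int, analyze_last: int,
                  seed: int, obs_var_mode: str) -> ARSet:
    res = simulate_run(params, n_trials, seed, obs_var_mode=obs_var_mode)
    series = TrialSeries.from_simulation(res, last=analyze_last)
    return estimate_all(series, Q=params.Q)


def run_sweep(config: SweepConfig, progress: bool = False,
              keep_raw: bool = True) -> SweepResult:
    """Run the sweep. Seeds are ``config.seed + run_index`` with a
    distinct run-index range per grid value, recorded in the table."""
    rows = []
    raw = np.full((len(config.grid), config.n_sims, 4), np.nan)
    it = enumerate(config.grid)
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm  # type: ignore[import-not-found]
        it = tqdm(list(it), desc=f"sweep {config.varied}")
    for gi, value in it:
        params = replace(config.fixed, **{config.varied: float(value)})
        seed0 = config.seed + gi * config.n_sims
        n_errors = 0
        for si in range(config.n_sims):
            try:
                arset = _estimate_run(params, config.n_trials,
                                      config.analyze_last, seed0 + si,
                                      config.obs_var_mode)
            except Exception as exc:
                raise type(exc)(
                    f"{config.varied}={value:g}, run {si}: {exc}"
                ) from exc
            if arset.errors:
                n_errors += 1
            for ei, name in enumerate(ESTIMATORS):
                v = getattr(arset, name)
                if v is not None:
                    raw[gi, si, ei] = v
        row = {"value": float(value), "seed0": seed0, "n_errors": n_errors}
        gold = raw[gi, :, 0]
        for ei, name in enumerate(ESTIMATORS):
            est = raw[gi, :, ei]
            ok = np.isfinite(est)
            row[f"mean_{name}"] = np.nanmean(est) if ok.any() else np.nan
            row[f"sd_{name}"] = np.nanstd(est, ddof=1) if ok.sum() > 1 else np.nan
            row[f"mean_abs_{name}"] = np.nanmean(np.abs(est)) if ok.any() else np.nan
            if name != "gold":
                both = ok & np.isfinite(gold)
                row[f"mse_{name}"] = (
                    float(np.mean((est[both] - gold[both]) ** 2))
                    if both.any() else np.nan
                )
        rows.append(row)
    return SweepResult(config=config, table=pd.DataFrame(rows),
                       raw=raw if keep_raw else None)


def default_windows() -> np.ndarray:
    """99 window sizes equally spaced from 20 to 1000 trials (step 10)."""
    return np.arange(20, 1001, 10)


@dataclass
class WindowStudyResult:
    params: ModelParams
    n_sims: int
    n_trials: int
    start_trial: int
    seed: int
    table: pd.DataFrame  # one row per window size: sd_/mean_ per estimator
    raw: Optional[np.ndarray] = None  # (n_sims, n_windows, 4)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")


def run_window_study(
    params: ModelParams,
    n_sims: int = 10_000,
    n_trials: int = 2000,
    windows: Optional[Sequence[int]] = None,
    start_trial: int = 1000,
    seed: int = 0,
    obs_var_mode: str = "control+percept",
    keep_raw: bool = False,
) -> WindowStudyResult:
    """Variability of each estimator versus the number of trials analyzed.

    Each run is simulated once; every window ``[start_trial,
    start_trial + size)`` (1-based start) is then analyzed on that same
    run, so windows share trials and the comparison across sizes uses
    common random numbers.
    """
    windows = np.asarray(default_windows() if windows is None else windows,
                         dtype=int)
    if start_trial < 1:
        raise ValueError("start_trial is 1-based and must be >= 1")
    if start_trial - 1 + int(windows.max()) > n_trials:
        raise WindowOverflowError(
            f"window of {windows.max()} trials starting at trial "
            f"{start_trial} exceeds {n_trials} trials"
        )
    raw = np.full((n_sims, len(windows), 4), np.nan)
    i0 = start_trial - 1
    for si in range(n_sims):
        res = simulate_run(params, n_trials, seed + si,
                           obs_var_mode=obs_var_mode)
        full = TrialSeries.from_simulation(res)
        for wi, w in enumerate(windows):
            sub = TrialSeries(
                x_m=full.x_m[i0:i0 + w], x_i=full.x_i,
                x_u=full.x_u[i0:i0 + w], x_p=full.x_p[i0:i0 + w],
            )
            arset = estimate_all(sub, Q=params.Q)
            for ei, name in enumerate(ESTIMATORS):
                v = getattr(arset, name)
                if v is not None:
                    raw[si, wi, ei] = v
    rows = []
    for wi, w in enumerate(windows):
        row = {"window": int(w)}
        for ei, name in enumerate(ESTIMATORS):
            est = raw[:, wi, ei]
            row[f"mean_{name}"] = np.nanmean(est)
            row[f"sd_{name}"] = np.nanstd(est, ddof=1)
        rows.append(row)
    return WindowStudyResult(
        params=params, n_sims=n_sims, n_trials=n_trials,
        start_trial=start_trial, seed=seed, table=pd.DataFrame(rows),
        raw=raw if keep_raw else None,
    )
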