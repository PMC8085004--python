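"""Empirical cursor-task pipeline.

Takes per-block trial records from a target-reaching task (endpoint,
target, per-trial externally added control noise, validity flags) and
produces per-block adaptation-rate estimates plus repeated-measures
statistics across noise conditions:

1. :func:`clean_trials` — drop backwards/short movements (accidental
   clicks); off-screen movements have unmeasurable error and break the
   contiguous record into segments.
2. :func:`longest_contiguous` — keep the longest unbroken segment.
3. :func:`select_steady_state` — trim the initial learning transient.
4. :func:`analyze_block` — conventional / silver / analytic estimators,
   the silver AR using the *added* noise only (baseline control noise is
   unmeasurable) and the analytic AR using the added-noise variance.
5. :func:`rm_anova` — one-way repeated-measures ANOVA per estimator
   across the NO/LOW/HIGH conditions (Mauchly sphericity test,
   Greenhouse–Geisser correction when violated, Bonferroni-corrected
   paired comparisons).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .estimators import ARSet, TrialSeries, estimate_all
from .exceptions import IncompleteMatrixError, SchemaError, TooShortSegmentError

__all__ = [
    "CONDITIONS", "ExperimentBlock", "BlockResult", "RmAnovaResult",
    "clean_trials", "longest_contiguous", "select_steady_state",
    "analyze_block", "analyze_experiment", "rm_anova",
]

CONDITIONS = ("NO", "LOW", "HIGH")

#: Minimum analyzable steady-state trials per block.
MIN_STEADY_TRIALS = 20

TRIAL_COLUMNS = ("trial", "endpoint", "target", "added_noise",
                 "backwards", "short", "offscreen")


@dataclass
class ExperimentBlock:
    """One participant-condition block of trials.

    ``trials`` columns: trial, endpoint (cm), target (cm), added_noise
    (cm), backwards/short/offscreen (bool flags). After cleaning, a
    ``segment`` column labels contiguous stretches.
    """

    subject: str
    condition: str
    trials: pd.DataFrame
    Q_added: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ("trial", "endpoint", "target")
                   if c not in self.trials.columns]
        if missing:
            raise SchemaError(f"block missing columns {missing}")
        for flag in ("backwards", "short", "offscreen"):
            if flag not in self.trials.columns:
                self.trials[flag] = False
            self.trials[flag] = self.trials[flag].astype(bool)
        if self.Q_added < 0:
            raise ValueError("Q_added must be >= 0")

    @property
    def target(self) -> float:
        return float(self.trials["target"].iloc[0])

    def to_csv(self, path) -> None:
        self.trials.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path, subject: str, condition: str,
                 Q_added: float = 0.0,
                 column_map: Optional[dict] = None) -> "ExperimentBlock":
        """Load a block CSV; ``column_map`` adapts foreign schemas
        (``{"their_name": "our_name"}``)."""
        df = pd.read_csv(path)
        if column_map:
            df = df.rename(columns=column_map)
        return cls(subject=subject, condition=condition, trials=df,
                   Q_added=Q_added)


def clean_trials(block: ExperimentBlock) -> ExperimentBlock:
    """Remove backwards/short movements and segment at off-screen trials.

    Backwards and short movements are presumed accidental clicks and are
    dropped without breaking contiguity. Off-screen movements have no
    measurable error: the trial is dropped from the analyzable record
    and the record is split there (``segment`` increments).
    """
    df = block.trials
    seg = df["offscreen"].cumsum().astype(int)
    keep = ~(df["backwards"] | df["short"] | df["offscreen"])
    out = df.loc[keep].copy()
    out["segment"] = seg[keep]
    return ExperimentBlock(subject=block.subject, condition=block.condition,
                           trials=out, Q_added=block.Q_added,
                           meta=dict(block.meta))


def longest_contiguous(block: ExperimentBlock,
                       min_len: int = MIN_STEADY_TRIALS) -> pd.DataFrame:
    """Longest stretch of contiguous trials (ties broken by earliest
    start). Requires a cleaned block (``segment`` column present)."""
    df = block.trials
    if "segment" not in df.columns:
        df = clean_trials(block).trials
    if len(df) == 0:
        raise TooShortSegmentError("no valid trials")
    sizes = df.groupby("segment", sort=True).size()
    best = sizes.index[int(np.argmax(sizes.values))]  # argmax -> earliest tie
    seg = df[df["segment"] == best]
    if len(seg) < min_len:
        raise TooShortSegmentError(
            f"longest contiguous segment has {len(seg)} trials (< {min_len})"
        )
    return seg.reset_index(drop=True)


def select_steady_state(
    segment: pd.DataFrame,
    window: int = 20,
    tolerance: float = 0.2,
    burn_in: Optional[int] = None,
    min_steady: int = MIN_STEADY_TRIALS,
) -> pd.DataFrame:
    """Return the steady-state suffix of a contiguous segment.

    Default detector: the earliest trial ``k`` from which the mean
    absolute error over a ``window``-trial sliding window is within
    ``tolerance`` (relative) of the mean absolute error over the final
    half of the segment — i.e. initial parameter learning has
    stabilized to the segment's own asymptote. A fixed ``burn_in``
    (number of trials to discard) overrides the detector; the detector
    is deliberately swappable since steady-state identification is a
    convention, not part of the estimators.
    """
    n = len(segment)
    if burn_in is not None:
        out = segment.iloc[burn_in:]
        if len(out) < min_steady:
            raise TooShortSegmentError(
                f"{len(out)} steady-state trials (< {min_steady})"
            )
        return out.reset_index(drop=True)
    if n < max(min_steady, window):
        raise TooShortSegmentError(f"segment of {n} trials is too short")
    err = np.abs(segment["endpoint"].to_numpy(dtype=float)
                 - segment["target"].to_numpy(dtype=float))
    ref = float(err[n - n // 2:].mean()) if n // 2 >= 1 else float(err.mean())
    start = None
    means = np.convolve(err, np.ones(window) / window, mode="valid")
    for k in range(len(means)):
        if abs(means[k] - ref) <= tolerance * ref:
            start = k
            break
    if start is None:
        raise TooShortSegmentError("no steady-state stretch found")
    out = segment.iloc[start:]
    if len(out) < min_steady:
        raise TooShortSegmentError(
            f"{len(out)} steady-state trials (< {min_steady})"
        )
    return out.reset_index(drop=True)


@dataclass
class BlockResult:
    """Adaptation rates for one analyzed block."""

    subject: str
    condition: str
    n_steady: int
    arset: ARSet

    def to_row(self) -> dict:
        d = {"subject": self.subject, "condition": self.condition,
             "n_steady": self.n_steady}
        d.update({k: getattr(self.arset, k)
                  for k in ("conventional", "silver", "analytic")})
        return d


def analyze_block(
    segment: pd.DataFrame,
    Q_added: float,
    subject: str = "",
    condition: str = "",
) -> BlockResult:
    """Estimate adaptation rates on a steady-state segment.

    The silver AR reconstructs the noise-free endpoint from the *added*
    noise only (``x_u = endpoint - added_noise``), and the analytic AR
    uses ``Q = Q_added``, both deliberately ignoring the participant's
    baseline control noise.
    """
    target = float(segment["target"].iloc[0])
    eta = (segment["added_noise"].to_numpy(dtype=float)
           if "added_noise" in segment.columns else None)
    series = TrialSeries(
        x_m=segment["endpoint"].to_numpy(dtype=float), x_i=target, eta_q=eta,
    )
    arset = estimate_all(series, Q=Q_added)
    return BlockResult(subject=subject, condition=condition,
                       n_steady=len(segment), arset=arset)


def analyze_experiment(
    blocks: Sequence[ExperimentBlock],
    burn_in: Optional[int] = None,
    min_steady: int = MIN_STEADY_TRIALS,
) -> tuple[pd.DataFrame, list[str]]:
    """Full pipeline over all blocks with listwise subject exclusion.

    A subject whose *any* block fails (segment or steady-state shorter
    than ``min_steady``) is excluded across all conditions. Returns the
    per-block results table and the excluded subject list.
    """
    results: list[BlockResult] = []
    failed: set[str] = set()
    for block in blocks:
        try:
            cleaned = clean_trials(block)
            seg = longest_contiguous(cleaned, min_len=min_steady)
            steady = select_steady_state(seg, burn_in=burn_in,
                                         min_steady=min_steady)
        except TooShortSegmentError:
            failed.add(block.subject)
            continue
        results.append(analyze_block(steady, block.Q_added,
                                     subject=block.subject,
                                     condition=block.condition))
    rows = [r.to_row() for r in results if r.subject not in failed]
    return pd.DataFrame(rows), sorted(failed)


@dataclass
class RmAnovaResult:
    """One-way repeated-measures ANOVA with sphericity handling."""

    mauchly_w: float
    mauchly_chi2: float
    mauchly_df: int
    mauchly_p: float
    sphericity_violated: bool
    F: float
    df1: float
    df2: float
    p: float
    eps: float
    pairwise: pd.DataFrame  # condition_a, condition_b, t, df, p_unc, p_bonf

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("mauchly_w", "mauchly_chi2", "mauchly_df", "mauchly_p",
              "sphericity_violated", "F", "df1", "df2", "p", "eps")}
        d["pairwise"] = self.pairwise.to_dict(orient="records")
        return d

    def to_json(self, path=None) -> Optional[str]:
        s = json.dumps(self.to_dict(), indent=2, default=float)
        if path is None:
            return s
        with open(path, "w") as fh:
            fh.write(s)
        return None

    def summary(self) -> str:
        corr = " (Greenhouse-Geisser corrected)" if self.sphericity_violated else ""
        lines = [
            f"Mauchly's test: W={self.mauchly_w:.4f}, "
            f"chi2({self.mauchly_df})={self.mauchly_chi2:.3f}, p={self.mauchly_p:.4f}"
            f" -> sphericity {'violated' if self.sphericity_violated else 'assumed'}",
            f"RM ANOVA{corr}: F({self.df1:.3f},{self.df2:.3f})={self.F:.3f}, "
            f"p={self.p:.4g}",
            "Bonferroni-corrected pairwise comparisons:",
        ]
        for _, r in self.pairwise.iterrows():
            lines.append(
                f"  {r['condition_a']} vs {r['condition_b']}: "
                f"t({int(r['df'])})={r['t']:.3f}, p={r['p_bonf']:.4g}"
            )
        return "\n".join(lines)


def _as_wide(values, conditions: Sequence[str]) -> pd.DataFrame:
    if isinstance(values, pd.DataFrame):
        wide = values
        if set(conditions).issubset(wide.columns):
            wide = wide[list(conditions)]
    else:
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(conditions):
            raise IncompleteMatrixError(
                f"expected a subjects x {len(conditions)} matrix"
            )
        wide = pd.DataFrame(arr, columns=list(conditions))
    if wide.isna().any().any():
        raise IncompleteMatrixError("matrix has missing cells")
    if len(wide) < 3:
        raise IncompleteMatrixError("need at least 3 subjects")
    return wide


def rm_anova(values, conditions: Sequence[str] = CONDITIONS,
             alpha_sphericity: float = 0.05) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on a complete subjects-by-conditions
    matrix.

    Runs Mauchly's sphericity test; when it rejects at
    ``alpha_sphericity`` the Greenhouse–Geisser correction is applied to
    the ANOVA degrees of freedom and p-value. Pairwise Bonferroni-
    corrected paired t-tests are always reported.
    """
    import pingouin as pg
    from scipy import stats

    wide = _as_wide(values, conditions)
    long = wide.reset_index(names="subject").melt(
        id_vars="subject", var_name="condition", value_name="value")

    k = wide.shape[1]
    mauchly_df = k * (k - 1) // 2 - 1
    # Degenerate case: no within-subject variability at all.
    diffs = wide.to_numpy() - wide.to_numpy().mean(axis=1, keepdims=True)
    if np.allclose(diffs, 0.0):
        pairs = _pairwise(wide, conditions)
        return RmAnovaResult(1.0, 0.0, mauchly_df, 1.0, False,
                             0.0, float(k - 1), float((k - 1) * (len(wide) - 1)),
                             1.0, 1.0, pairs)

    sph = pg.sphericity(long, dv="value", within="condition", subject="subject")
    aov = pg.rm_anova(long, dv="value", within="condition", subject="subject",
                      correction=True, detailed=False)
    row = aov.iloc[0]
    F = float(row["F"])
    df1 = float(row["ddof1"])
    df2 = float(row["ddof2"])
    eps = float(row["eps"]) if "eps" in aov.columns and math.isfinite(row.get("eps", np.nan)) else 1.0
    violated = bool(sph.pval < alpha_sphericity)
    if violated:
        p = float(row["p_GG_corr"]) if "p_GG_corr" in aov.columns else \
            float(stats.f.sf(F, df1 * eps, df2 * eps))
        df1, df2 = df1 * eps, df2 * eps
    else:
        p = float(row["p_unc"])
    return RmAnovaResult(
        mauchly_w=float(sph.W), mauchly_chi2=float(sph.chi2),
        mauchly_df=int(sph.dof), mauchly_p=float(sph.pval),
        sphericity_violated=violated, F=F, df1=df1, df2=df2, p=p, eps=eps,
        pairwise=_pairwise(wide, conditions),
    )


def _pairwise(wide: pd.DataFrame, conditions: Sequence[str]) -> pd.DataFrame:
    from scipy import stats

    rows = []
    pairs = list(itertools.combinations(list(wide.columns), 2))
    m = len(pairs)
    for a, b in pairs:
        d = wide[a] - wide[b]
        if np.allclose(d, 0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(wide[a], wide[b])
        rows.append({
            "condition_a": a, "condition_b": b, "t": float(t),
            "df": len(wide) - 1, "p_unc": float(p),
            "p_bonf": float(min(1.0, p * m)),
        })
    return pd.DataFrame(rows)
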