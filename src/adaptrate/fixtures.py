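"""Synthetic cursor-task experiment generator.

Emulates the empirical study the analysis pipeline is built for:
participants move a cursor 22.4 cm to a target and receive endpoint-only
feedback; each completes three 100-trial blocks under different levels
of externally added Gaussian control noise (SD 0 / 2.24 / 4.48 cm — the
NO / LOW / HIGH conditions, 0%, 10% and 20% of the movement distance)
in one of the six possible condition orders. Endpoints come from the
hierarchical Kalman-filter learner (in cm), which experiences the added
noise exactly like intrinsic control noise and knows its total
noise level; the added noise is recorded per trial, as in the real
task. A configurable fraction of invalid movements (backwards, short,
off-screen) is injected with flags set, so the cleaning and
segmentation stages have realistic work to do.

Everything is driven by one seed and fully recorded in a manifest, so a
generated experiment can be replayed bit-identically.
"""

from __future__ import annotations

import itertools
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .empirical import CONDITIONS, ExperimentBlock
from .simulate import ModelParams, simulate_run

__all__ = ["DEFAULT_LEARNER", "DEFAULT_NOISE_SDS",
           "generate_fixture_experiment", "write_experiment_dir",
           "load_experiment_dir"]

#: Task geometry and learner defaults, in centimeters. Baseline control
#: noise SD 1 cm (~4.5% of the 22.4 cm movement), precise visual endpoint
#: feedback (R = 0.1 cm^2), small per-trial uncertainty increment, and a
#: mildly miscalibrated initial gain so each block has a learning
#: transient for the steady-state detector to trim.
DEFAULT_LEARNER = ModelParams(Q=1.0, R=0.1, xi=0.01, B=1.0,
                              B_hat_init=0.9, P_p_init=5.0, x_i=22.4)

#: Added control-noise SD (cm) per condition: 0%, 10%, 20% of distance.
DEFAULT_NOISE_SDS = {"NO": 0.0, "LOW": 2.24, "HIGH": 4.48}

#: Per-trial probability of each invalid-movement kind. Backwards/short
#: are accidental clicks (removed without breaking contiguity);
#: off-screen movements are rarer but each one splits the analyzable
#: record. Rates are set so a 100-trial block typically retains a ~90-
#: trial steady-state segment, matching the task being emulated.
DEFAULT_INVALID_RATES = {"backwards": 0.01, "short": 0.01, "offscreen": 0.003}

_ORDERS = list(itertools.permutations(CONDITIONS))


def _inject_invalid(df: pd.DataFrame, rates: dict, target: float,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Insert flagged invalid movement rows at random positions.

    Backwards/short movements (accidental clicks) get near-zero or
    sub-25%-of-target endpoints; off-screen movements have no
    measurable endpoint (NaN). Valid trials keep their order.
    """
    extra = []
    n = len(df)
    for kind, rate in rates.items():
        for _ in range(rng.binomial(n, rate)):
            pos = int(rng.integers(0, n + 1))
            if kind == "backwards":
                endpoint = -float(rng.uniform(0.2, 2.0))
            elif kind == "short":
                endpoint = float(rng.uniform(0.0, 0.25 * target))
            else:  # offscreen: error unmeasurable
                endpoint = np.nan
            extra.append({"pos": pos, "endpoint": endpoint,
                          "target": target, "added_noise": 0.0,
                          "backwards": kind == "backwards",
                          "short": kind == "short",
                          "offscreen": kind == "offscreen"})
    if not extra:
        out = df.copy()
    else:
        base = df.copy()
        base["pos"] = np.arange(n, dtype=float)
        ex = pd.DataFrame(extra)
        ex["pos"] = ex["pos"] - 0.5  # insert before the valid trial at pos
        out = pd.concat([base, ex], ignore_index=True).sort_values(
            "pos", kind="stable").drop(columns="pos").reset_index(drop=True)
    out.insert(0, "trial", np.arange(1, len(out) + 1))
    return out


def generate_fixture_experiment(
    n_subjects: int = 26,
    seed: int = 0,
    learner: ModelParams = DEFAULT_LEARNER,
    noise_sds: Optional[dict] = None,
    n_trials_per_block: int = 100,
    invalid_rates: Optional[dict] = None,
) -> tuple[list[ExperimentBlock], dict]:
    """Generate a full synthetic experiment.

    Returns ``(blocks, manifest)``: ``3 * n_subjects`` blocks of
    ``n_trials_per_block`` valid trials each (plus injected invalid
    trials), and a manifest recording the seed, each subject's condition
    order and every block's simulation seed.
    """
    noise_sds = dict(DEFAULT_NOISE_SDS if noise_sds is None else noise_sds)
    invalid_rates = dict(DEFAULT_INVALID_RATES
                         if invalid_rates is None else invalid_rates)
    rng = np.random.default_rng(seed)
    blocks: list[ExperimentBlock] = []
    manifest: dict = {
        "seed": int(seed),
        "n_subjects": int(n_subjects),
        "n_trials_per_block": int(n_trials_per_block),
        "noise_sds": {k: float(v) for k, v in noise_sds.items()},
        "invalid_rates": {k: float(v) for k, v in invalid_rates.items()},
        "learner": {k: float(v) for k, v in vars(learner).items()},
        "subjects": {},
    }
    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        order = list(_ORDERS[int(rng.integers(len(_ORDERS)))])
        manifest["subjects"][subject] = {"order": order, "block_seeds": {}}
        for condition in order:
            sd = float(noise_sds[condition])
            block_seed = int(rng.integers(0, 2**31 - 1))
            manifest["subjects"][subject]["block_seeds"][condition] = block_seed
            sim = simulate_run(learner, n_trials_per_block, block_seed,
                               added_noise_sd=sd)
            add = sim.eta_add if sim.eta_add is not None else np.zeros(sim.n_trials)
            df = pd.DataFrame({
                "endpoint": sim.x_m,
                "target": learner.x_i,
                "added_noise": add,
                "backwards": False, "short": False, "offscreen": False,
            })
            df = _inject_invalid(df, invalid_rates, learner.x_i, rng)
            blocks.append(ExperimentBlock(
                subject=subject, condition=condition, trials=df,
                Q_added=sd ** 2,
                meta={"block_seed": block_seed, "added_noise_sd": sd},
            ))
    return blocks, manifest


def write_experiment_dir(blocks: Sequence[ExperimentBlock], manifest: dict,
                         path) -> Path:
    """One CSV per subject-block plus a YAML manifest."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    for b in blocks:
        b.to_csv(root / f"{b.subject}_{b.condition}.csv")
    with open(root / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return root


def load_experiment_dir(path, column_map: Optional[dict] = None
                        ) -> tuple[list[ExperimentBlock], dict]:
    """Load an experiment directory written by :func:`write_experiment_dir`
    (or foreign data adapted via ``column_map``)."""
    root = Path(path)
    with open(root / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    noise_sds = manifest["noise_sds"]
    blocks = []
    for subject, info in manifest["subjects"].items():
        for condition in info["order"]:
            sd = float(noise_sds[condition])
            blocks.append(ExperimentBlock.from_csv(
                root / f"{subject}_{condition}.csv", subject=subject,
                condition=condition, Q_added=sd ** 2, column_map=column_map,
            ))
    return blocks, manifest
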