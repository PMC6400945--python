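"""End-to-end in-silico replications of the two experiments.

Experiment 1 measures symmetry-detection thresholds (80%-correct points from
logistic fits to pooled 1-up-3-down staircase data) across speed,
dynamic-flicker and static conditions.  No human observers are available, so
the default configuration drives the staircases with per-condition
``LogisticObserver`` oracles whose true 80% thresholds follow quadratic
speed-tuning curves (thresholds fall as the signal-to-noise speed ratio
departs from 1, are nearly flat across lifetime ratios, and sit higher for
the static baseline); the run then recovers those thresholds from simulated
trials.

Experiment 2 measures percent correct for 50%-symmetry segregated and
non-segregated stimuli with a ``ChannelObserver`` — the stochastic process
the probability-summation analysis assumes — and applies the
segregated-to-non-segregated prediction to the simulated segregated data.
Complementary segregated sub-conditions (symmetry at S1/noise at S2 and vice
versa) are averaged before prediction.

All randomness flows from a single seed; outputs are tidy DataFrames.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import psychofit
from .observer import (ChannelObserver, LogisticObserver, nonsegregated_trial,
                       segregated_trial)
from .ps_model import PSModelParams, predict_nonsegregated
from .staircase import PAIR_QUANTUM, run_interleaved
from .stimgen import compute_lifetime

__all__ = [
    "STANDARD_SPEEDS",
    "Exp1Config",
    "Exp2Config",
    "speed_tuning_threshold",
    "flicker_tuning_threshold",
    "run_experiment1",
    "run_experiment2",
    "predict_from_table",
    "config_hash",
]

#: the three element speeds, deg/s
STANDARD_SPEEDS = (3.33, 6.67, 10.0)

# quadratic threshold-vs-axis curves used as the synthetic ground truth for
# Experiment 1 (threshold in % symmetry against log2 signal-to-noise ratio;
# the flicker axis is reversed so shorter relative lifetimes align with
# faster relative speeds)
SPEED_QUAD = (-5.321, -0.133, 43.819)
FLICKER_QUAD = (-1.808, 0.906, 47.455)
STATIC_THRESHOLD = 55.0


def speed_tuning_threshold(ratio: float, coef: tuple[float, float, float] = SPEED_QUAD) -> float:
    """True 80% threshold (% symmetry) at a signal-to-noise speed ratio."""
    x = np.log2(ratio)
    a, b, c = coef
    return float(a * x**2 + b * x + c)


def flicker_tuning_threshold(lifetime_ratio: float,
                             coef: tuple[float, float, float] = FLICKER_QUAD) -> float:
    """True 80% threshold at a signal-to-noise lifetime ratio (reversed axis)."""
    x = -np.log2(lifetime_ratio)
    a, b, c = coef
    return float(a * x**2 + b * x + c)


@dataclass
class Exp1Config:
    """Configuration of the threshold experiment.

    Conditions default to every ordered pair of the three standard speeds
    (9 speed conditions), every ordered pair of the three matched lifetimes
    (9 dynamic-flicker conditions) and one static baseline.
    """

    speeds: tuple[float, ...] = STANDARD_SPEEDS
    n_runs: int = 10
    n_trials_per_track: int = 75
    observer_beta: float = 6.0
    observer_lapse: float = 0.0
    n_bootstrap: int = 1000
    step: float = PAIR_QUANTUM

    def conditions(self) -> list[dict]:
        conds = []
        for s_sig in self.speeds:
            for s_noi in self.speeds:
                conds.append({"condition": "speed", "signal": s_sig, "noise": s_noi,
                              "ratio": s_sig / s_noi})
        lifetimes = {s: compute_lifetime(s).ms for s in self.speeds}
        for s_sig in self.speeds:
            for s_noi in self.speeds:
                conds.append({"condition": "flicker",
                              "signal": lifetimes[s_sig], "noise": lifetimes[s_noi],
                              "ratio": lifetimes[s_sig] / lifetimes[s_noi]})
        conds.append({"condition": "static", "signal": np.nan, "noise": np.nan,
                      "ratio": np.nan})
        return conds

    def true_threshold(self, cond: dict) -> float:
        if cond["condition"] == "speed":
            return speed_tuning_threshold(cond["ratio"])
        if cond["condition"] == "flicker":
            return flicker_tuning_threshold(cond["ratio"])
        return STATIC_THRESHOLD


def _observer_for(cond: dict, config: Exp1Config) -> LogisticObserver:
    """Logistic oracle whose true 80% point matches the condition's tuning curve."""
    thr = config.true_threshold(cond)
    beta = config.observer_beta
    span = 1.0 - 0.5 - config.observer_lapse
    frac = (0.80 - 0.5) / span
    alpha = thr - beta * np.log(frac / (1.0 - frac))
    return LogisticObserver(alpha=alpha, beta=beta, lapse=config.observer_lapse)


def run_experiment1(config: Exp1Config | None = None,
                    seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Simulate the full threshold experiment and fit per-condition thresholds.

    For each condition, ``n_runs`` interleaved staircase runs (two 75-trial
    tracks each) are simulated, trials pooled across runs and tracks, a
    logistic fit made and the 80% threshold with its bootstrap SE recorded.
    Returns one row per condition with columns ``condition, signal, noise,
    ratio, true_threshold80, threshold80, se_threshold, n_trials``.
    """
    config = config or Exp1Config()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for cond in config.conditions():
        observer = _observer_for(cond, config)
        logs = [run_interleaved(observer, rng, n_trials_per_track=config.n_trials_per_track,
                                step=config.step) for _ in range(config.n_runs)]
        trials = pd.concat(logs, ignore_index=True)
        fit = psychofit.fit_logistic(trials)
        se, _ = psychofit.bootstrap_se(trials, n_resamples=config.n_bootstrap, rng=rng)
        rows.append({**cond, "true_threshold80": config.true_threshold(cond),
                     "threshold80": fit.threshold80, "se_threshold": se,
                     "n_trials": fit.n_trials})
    return pd.DataFrame(rows)


@dataclass
class Exp2Config:
    """Configuration of the segregated vs non-segregated experiment."""

    speeds: tuple[float, ...] = STANDARD_SPEEDS
    n_trials: int = 500          # per sub-condition
    n_symmetric_dots: int = 16   # 50% of 32 dots
    n_dots: int = 32
    gain: float = 3.0
    ps_params: PSModelParams = field(default_factory=PSModelParams)

    def speed_pairs(self) -> list[tuple[float, float]]:
        s = self.speeds
        return [(s[i], s[j]) for i in range(len(s)) for j in range(i + 1, len(s))]


def run_experiment2(config: Exp2Config | None = None,
                    seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Simulate segregated/non-segregated blocks and the PS-model prediction.

    For each unordered speed pair, both segregated sub-conditions (symmetry
    carried by either component speed) and the non-segregated condition are
    simulated with the channel observer; the two segregated percent-corrects
    are averaged and pushed through :func:`predict_nonsegregated`.  Rows where
    the averaged segregated PC is at or below chance carry a NaN prediction.
    """
    config = config or Exp2Config()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observer = ChannelObserver(ps_params=config.ps_params, gain=config.gain)
    rows = []
    for s1, s2 in config.speed_pairs():
        seg_pcs = []
        for idx in (0, 1):
            trial = segregated_trial((s1, s2), idx, config.n_symmetric_dots, config.n_dots)
            seg_pcs.append(observer.respond_trials(trial, config.n_trials, rng).mean())
        nonseg = nonsegregated_trial((s1, s2), config.n_symmetric_dots, config.n_dots)
        pc_nonseg = observer.respond_trials(nonseg, config.n_trials, rng).mean()
        pc_seg = float(np.mean(seg_pcs))
        try:
            pc_pred = predict_nonsegregated(pc_seg, n_speeds=2,
                                            params_base=config.ps_params)
        except ValueError:
            pc_pred = np.nan
        rows.append({"speed_1": s1, "speed_2": s2,
                     "pc_segregated": pc_seg, "pc_nonsegregated": float(pc_nonseg),
                     "pc_nonsegregated_predicted": pc_pred,
                     "n_trials_per_subcondition": config.n_trials})
    return pd.DataFrame(rows)


def predict_from_table(table: pd.DataFrame, pc_column: str = "pc_segregated",
                       n_speeds: int = 2,
                       params: PSModelParams = PSModelParams()) -> pd.DataFrame:
    """Apply the non-segregated prediction to a user-supplied table of PCs.

    Lets measured (e.g. laboratory) segregated percent-corrects flow through
    the identical prediction path used for simulated data.  PCs at or below
    chance yield NaN predictions; the rows are retained.
    """
    out = table.copy()
    preds = []
    for pc in out[pc_column]:
        try:
            preds.append(predict_nonsegregated(float(pc), n_speeds, params))
        except ValueError:
            preds.append(np.nan)
    out["pc_nonsegregated_predicted"] = preds
    return out


def config_hash(config) -> str:
    """Stable short hash of a config dataclass, for output manifests."""
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str, kind: str):
    """Load an Exp1Config or Exp2Config from a YAML mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if kind == "exp1":
        return Exp1Config(**{k: tuple(v) if k == "speeds" else v for k, v in raw.items()})
    if kind == "exp2":
        if "ps_params" in raw:
            raw["ps_params"] = PSModelParams(**raw["ps_params"])
        return Exp2Config(**{k: tuple(v) if k == "speeds" else v for k, v in raw.items()})
    raise ValueError(f"unknown experiment kind {kind!r}")
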