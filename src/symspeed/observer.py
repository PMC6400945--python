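"""Simulated observers producing 2IFC responses.

Two synthetic stand-ins for human participants:

``ChannelObserver`` implements, trial by trial, exactly the stochastic
process that the probability-summation analysis assumes: one speed-selective
symmetry channel per stimulus speed, each contributing an independent
unit-variance normal deviate whose mean is d' = g * SL**tau in intervals
where that speed carries symmetry, with the max decision rule across
channels and intervals.  Its long-run performance therefore equals
``ps_model.pc_ps`` by construction, which makes it the oracle for the
segregated/non-segregated logic.

``LogisticObserver`` responds to a scalar symmetry level with a Bernoulli
draw from a guess-rate-floored logistic psychometric function; it is the
oracle for the staircase and fitting machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ps_model import PSModelParams

__all__ = ["TrialSpec", "ChannelObserver", "LogisticObserver",
           "segregated_trial", "nonsegregated_trial"]


@dataclass(frozen=True)
class TrialSpec:
    """Per-speed symmetric-dot composition of a 2IFC trial's target interval.

    ``sym_counts`` maps each stimulus speed to the number of symmetric dots
    drifting at it in the target; the foil carries none.  Per-speed total dot
    counts are matched between intervals by construction and do not enter the
    decision model.
    """

    sym_counts: dict[float, int]
    n_dots: int = 32

    @property
    def speeds(self) -> tuple[float, ...]:
        return tuple(self.sym_counts)


@dataclass
class ChannelObserver:
    """Ideal observer with independent speed-selective symmetry channels.

    Each channel's stimulus level is ``gain`` times the proportion of all
    dots that are symmetric and drift at the channel's speed; the channel's
    d' is g * SL**tau.  ``gain`` sets overall task difficulty: the default
    3.0 puts the full-strength 50%-symmetry segregated stimulus at d' = 1.5.
    """

    ps_params: PSModelParams = field(default_factory=PSModelParams)
    gain: float = 3.0

    def channel_sls(self, trial: TrialSpec) -> np.ndarray:
        """Per-channel stimulus levels, ordered as ``trial.speeds``."""
        return np.array([self.gain * c / trial.n_dots for c in trial.sym_counts.values()])

    def channel_dprimes(self, trial: TrialSpec) -> np.ndarray:
        p = self.ps_params
        return p.g * self.channel_sls(trial) ** p.tau

    def respond_trial(self, trial: TrialSpec, rng: np.random.Generator | int) -> bool:
        """One 2IFC decision: True iff the target interval is chosen."""
        return bool(self.respond_trials(trial, 1, rng)[0])

    def respond_trials(self, trial: TrialSpec, n_trials: int,
                       rng: np.random.Generator | int) -> np.ndarray:
        """Vectorized batch of independent 2IFC decisions (boolean array)."""
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        d = self.channel_dprimes(trial)
        q = d.size
        m = self.ps_params.m
        target = rng.standard_normal((n_trials, q)) + d
        others = rng.standard_normal((n_trials, m - 1, q))
        return target.max(axis=1) > others.max(axis=(1, 2))


@dataclass
class LogisticObserver:
    """Bernoulli observer on a guess-rate-floored logistic psychometric curve.

    PC(x) = guess + (1 - guess - lapse) / (1 + exp(-(x - alpha) / beta)),
    with ``x`` the symmetry level in percent.  ``alpha`` is the curve's
    midpoint and ``beta`` its slope scale, both in % symmetry.
    """

    alpha: float = 40.0
    beta: float = 8.0
    guess: float = 0.5
    lapse: float = 0.0

    def pc(self, level: float | np.ndarray) -> float | np.ndarray:
        """True probability of a correct response at ``level`` % symmetry."""
        z = (np.asarray(level, dtype=float) - self.alpha) / self.beta
        out = self.guess + (1.0 - self.guess - self.lapse) / (1.0 + np.exp(-z))
        return float(out) if np.isscalar(level) else out

    def threshold(self, pc_target: float = 0.80) -> float:
        """Symmetry level at which the true curve crosses ``pc_target``."""
        span = 1.0 - self.guess - self.lapse
        frac = (pc_target - self.guess) / span
        if not 0.0 < frac < 1.0:
            raise ValueError("target proportion correct outside the curve's range")
        return self.alpha + self.beta * np.log(frac / (1.0 - frac))

    def respond_level(self, level: float, rng: np.random.Generator | int) -> bool:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        return bool(rng.random() < self.pc(level))

    def respond_levels(self, levels: np.ndarray,
                       rng: np.random.Generator | int) -> np.ndarray:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        levels = np.asarray(levels, dtype=float)
        return rng.random(levels.shape) < self.pc(levels)


def segregated_trial(speeds: tuple[float, float], sym_speed_index: int,
                     n_sym: int = 16, n_dots: int = 32) -> TrialSpec:
    """Trial spec with all symmetric dots at one of the two speeds."""
    counts = {float(speeds[0]): 0, float(speeds[1]): 0}
    counts[float(speeds[sym_speed_index])] = n_sym
    return TrialSpec(counts, n_dots)


def nonsegregated_trial(speeds: tuple[float, float],
                        n_sym: int = 16, n_dots: int = 32) -> TrialSpec:
    """Trial spec with symmetric dots split equally across the two speeds."""
    return TrialSpec({float(speeds[0]): n_sym // 2, float(speeds[1]): n_sym - n_sym // 2},
                     n_dots)
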