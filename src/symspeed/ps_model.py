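"""Signal-detection-theory probability summation over speed-selective channels.

The observer monitors ``Q`` independent symmetry channels per interval of an
M-alternative forced-choice task.  In the target interval, ``n`` channels
carry signal with mean d' = g * SL**tau (SL is the per-channel stimulus
level, here proportional to the fraction of symmetric dots at the channel's
speed); the remaining Q - n channels, and all Q channels of each of the M - 1
non-target intervals, have mean zero.  All channel outputs are independent
unit-variance normal deviates, and the observer chooses the interval whose
maximum channel output is largest (the max decision rule).

Proportion correct is

    PC = ∫ [ n φ(t - d') Φ(t - d')^(n-1) Φ(t)^(Q-n)
           + (Q - n) φ(t) Φ(t)^(Q-n-1) Φ(t - d')^n ] Φ(t)^((M-1)Q) dt

the probability that the target interval's maximum exceeds the maxima of all
other intervals.  Two special cases anchor the implementation: PC(SL=0) = 1/M,
and for Q = n = 1, M = 2, PC = Φ(d'/√2).

The headline use is the segregated → non-segregated prediction: invert the
segregated PC to a stimulus level with Q channels and n = 1, split that level
equally over the channels (SL/Q), and evaluate PC with n = Q.  With g = tau = 1
this always predicts worse performance for the split signal — the
probability-summation signature of independent speed-selective channels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy import integrate, optimize, stats

__all__ = [
    "PSModelParams",
    "pc_ps",
    "sl_from_pc",
    "predict_nonsegregated",
    "mc_oracle_pc",
]

_NORM = stats.norm


@dataclass(frozen=True)
class PSModelParams:
    """Parameters of the probability-summation decision model.

    Attributes
    ----------
    g : float
        Gain converting stimulus level to d'.
    tau : float
        Transducer exponent relating physical to internal signal strength.
    m : int
        Number of forced-choice alternatives (2 for 2IFC).
    q : int
        Number of channels the observer monitors per interval.
    n : int
        Number of channels actually carrying signal in the target interval.
    """

    g: float = 1.0
    tau: float = 1.0
    m: int = 2
    q: int = 2
    n: int = 1

    def __post_init__(self) -> None:
        if self.g <= 0 or self.tau <= 0:
            raise ValueError("g and tau must be positive")
        if self.m < 2:
            raise ValueError("m must be at least 2")
        if not 1 <= self.n <= self.q:
            raise ValueError("need 1 <= n <= q")


def pc_ps(sl: float, params: PSModelParams = PSModelParams()) -> float:
    """Proportion correct under the max-rule model at stimulus level ``sl``.

    Computed by adaptive quadrature of the order-statistic integrand with
    tails truncated at +-10 around the two component means; absolute error is
    well below 1e-6.
    """
    if sl < 0:
        raise ValueError("stimulus level must be non-negative")
    p = params
    d = p.g * sl**p.tau
    k = (p.m - 1) * p.q

    def integrand(t: np.ndarray) -> np.ndarray:
        phi_sig = _NORM.pdf(t - d)
        cdf_sig = _NORM.cdf(t - d)
        phi_noi = _NORM.pdf(t)
        cdf_noi = _NORM.cdf(t)
        out = p.n * phi_sig * cdf_sig ** (p.n - 1) * cdf_noi ** (p.q - p.n)
        if p.q > p.n:
            out = out + (p.q - p.n) * phi_noi * cdf_noi ** (p.q - p.n - 1) * cdf_sig**p.n
        return out * cdf_noi**k

    val, _ = integrate.quad(integrand, -10.0, 10.0 + d, epsabs=1e-10, epsrel=1e-10, limit=200)
    return float(min(max(val, 1.0 / p.m), 1.0))


def sl_from_pc(pc: float, params: PSModelParams = PSModelParams()) -> float:
    """Invert :func:`pc_ps`: the unique stimulus level giving proportion correct ``pc``.

    Uses bracketed Brent root finding on a geometrically grown interval;
    the roundtrip error ``|pc_ps(sl_from_pc(pc)) - pc|`` is at most 1e-6.
    """
    chance = 1.0 / params.m
    if pc <= chance:
        raise ValueError("proportion correct at or below chance: stimulus level undefined")
    if pc >= 1.0:
        raise ValueError("proportion correct saturated at 1: stimulus level undefined")
    hi = 1.0
    for _ in range(60):
        if pc_ps(hi, params) > pc:
            break
        hi *= 2.0
    else:
        raise ValueError("proportion correct too close to 1 to invert")
    sl = optimize.brentq(lambda s: pc_ps(s, params) - pc, 0.0, hi, xtol=1e-12, rtol=1e-14)
    return float(sl)


def predict_nonsegregated(pc_segregated: float, n_speeds: int = 2,
                          params_base: PSModelParams = PSModelParams()) -> float:
    """Predict non-segregated proportion correct from the segregated one.

    The segregated PC is converted to a stimulus level assuming one active
    channel among ``n_speeds`` monitored (n = 1, Q = n_speeds); that level is
    divided by ``n_speeds`` and fed back through the forward model with all
    ``n_speeds`` channels active (n = Q), modelling the symmetry signal split
    equally across speeds.
    """
    if n_speeds < 2:
        raise ValueError("n_speeds must be at least 2")
    # the observer monitors one channel per speed present in the stimulus
    seg = replace(params_base, q=n_speeds, n=1)
    non = replace(params_base, q=n_speeds, n=n_speeds)
    sl = sl_from_pc(pc_segregated, seg)
    return pc_ps(sl / n_speeds, non)


class MCEstimate(NamedTuple):
    pc: float
    se: float
    n_trials: int


def mc_oracle_pc(sl: float, params: PSModelParams, n_trials: int,
                 rng: np.random.Generator | int) -> MCEstimate:
    """Monte-Carlo estimate of the max-rule proportion correct.

    Simulates the decision model trial by trial (vectorized in chunks) and
    returns the empirical proportion correct with its binomial standard
    error.  Serves as an independent check on the quadrature in
    :func:`pc_ps`; it shares no code with it.
    """
    if n_trials < 10_000:
        raise ValueError("use at least 10_000 trials for a meaningful oracle estimate")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = params
    d = p.g * sl**p.tau
    correct = 0
    chunk = 200_000
    done = 0
    while done < n_trials:
        b = min(chunk, n_trials - done)
        target = rng.standard_normal((b, p.q))
        target[:, : p.n] += d
        others = rng.standard_normal((b, p.m - 1, p.q))
        win = target.max(axis=1) > others.max(axis=(1, 2))
        correct += int(win.sum())
        done += b
    pc = correct / n_trials
    se = float(np.sqrt(pc * (1.0 - pc) / n_trials))
    return MCEstimate(pc, se, n_trials)
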