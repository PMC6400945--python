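"""Psychometric fitting and curve-level statistics.

Implements the analysis chain applied to staircase trial logs: pooled
maximum-likelihood logistic fits with the threshold read off at 80% correct,
nonparametric bootstrap standard errors of that threshold, the logit
transform used for percent-correct analyses, least-squares quadratic fits of
threshold against (log) signal-to-noise ratio, and the extra-sum-of-squares
F test comparing two quadratic curves.

The psychometric model is PC(x) = guess + (1 - guess - lapse) * sigmoid((x -
alpha)/beta) with a 2IFC guess rate of 0.5; the threshold is solved from the
fitted curve at PC = 0.80 rather than equated with alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "PsychometricFit",
    "QuadraticFit",
    "CurveComparison",
    "fit_logistic",
    "bootstrap_se",
    "logit",
    "fit_quadratic",
    "compare_quadratic_fits",
]


@dataclass
class PsychometricFit:
    """Fitted logistic psychometric function and derived threshold."""

    alpha: float
    beta: float
    guess: float
    lapse: float
    threshold80: float
    n_trials: int
    nll: float
    se_threshold: float | None = None

    def pc(self, level: float | np.ndarray) -> np.ndarray:
        z = (np.asarray(level, dtype=float) - self.alpha) / self.beta
        return self.guess + (1.0 - self.guess - self.lapse) * special.expit(z)

    def threshold(self, pc_target: float = 0.80) -> float:
        span = 1.0 - self.guess - self.lapse
        frac = (pc_target - self.guess) / span
        if not 0.0 < frac < 1.0:
            raise ValueError("target proportion correct outside the fitted curve's range")
        return self.alpha + self.beta * float(special.logit(frac))


def _bin_trials(levels: np.ndarray, correct: np.ndarray):
    """Pool trials into (level, n, k) counts: correct responses per level."""
    levels = np.asarray(levels, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    uniq, inv = np.unique(levels, return_inverse=True)
    n = np.bincount(inv, minlength=uniq.size)
    k = np.bincount(inv, weights=correct.astype(float), minlength=uniq.size)
    return uniq, n.astype(float), k


def _fit_binned(x: np.ndarray, n: np.ndarray, k: np.ndarray,
                guess: float, lapse: float,
                init: tuple[float, float] | None = None) -> tuple[float, float, float]:
    """MLE of (alpha, beta) from binned binomial counts; returns (a, b, nll).

    ``init`` (alpha, beta) restricts the search to a single warm start, used
    by the bootstrap where the original fit is an excellent guess.
    """
    span = 1.0 - guess - lapse

    def nll(theta):
        a, log_b = theta
        b = np.exp(log_b)
        p = guess + span * special.expit((x - a) / b)
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        return -(k * np.log(p) + (n - k) * np.log1p(-p)).sum()

    if init is not None:
        starts = [np.array([init[0], np.log(init[1])])]
    else:
        # initial alpha: level whose empirical PC is nearest the curve midpoint
        pc_emp = k / n
        mid = guess + span / 2.0
        a0 = float(x[np.argmin(np.abs(pc_emp - mid))])
        starts = [np.array([a0, b0]) for b0 in (np.log(2.0), np.log(8.0), np.log(20.0))]
    best = None
    for s0 in starts:
        res = optimize.minimize(nll, s0, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res
    a, log_b = best.x
    return float(a), float(np.exp(log_b)), float(best.fun)


def fit_logistic(trials, guess: float = 0.5, lapse: float = 0.0,
                 pc_target: float = 0.80) -> PsychometricFit:
    """Maximum-likelihood logistic fit to pooled (level, correct) trials.

    ``trials`` is a DataFrame with ``level`` and ``correct`` columns, or a
    pair of arrays.  Correct responses are pooled per level before fitting.
    The threshold is the level at which the fitted curve reaches
    ``pc_target`` (default 0.80).

    Raises
    ------
    ValueError
        If fewer than two distinct levels are present, or the data are
        degenerate (all responses correct or all incorrect).
    """
    if isinstance(trials, pd.DataFrame):
        levels, correct = trials["level"].to_numpy(), trials["correct"].to_numpy()
    else:
        levels, correct = trials
    x, n, k = _bin_trials(levels, correct)
    if x.size < 2:
        raise ValueError("need at least two distinct stimulus levels to fit")
    if k.sum() == 0:
        raise ValueError("degenerate data: every response incorrect")
    if k.sum() == n.sum():
        raise ValueError("degenerate data: every response correct")
    a, b, nll = _fit_binned(x, n, k, guess, lapse)
    fit = PsychometricFit(alpha=a, beta=b, guess=guess, lapse=lapse,
                          threshold80=np.nan, n_trials=int(n.sum()), nll=nll)
    fit.threshold80 = fit.threshold(pc_target)
    return fit


def bootstrap_se(trials, n_resamples: int = 1000,
                 rng: np.random.Generator | int = 0,
                 guess: float = 0.5, lapse: float = 0.0,
                 pc_target: float = 0.80) -> tuple[float, int]:
    """Bootstrap standard error of the 80%-correct threshold.

    Trials are resampled with replacement ``n_resamples`` times and the
    logistic fit repeated on each resample; the SE is the standard deviation
    of the resampled thresholds.  Resampling is performed on the binned
    (level, outcome) cells via a multinomial draw, which is distributionally
    identical to resampling individual trials.  Resamples whose fit fails
    (degenerate draw) are excluded; their count is returned alongside.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if isinstance(trials, pd.DataFrame):
        levels, correct = trials["level"].to_numpy(), trials["correct"].to_numpy()
    else:
        levels, correct = trials
    x, n, k = _bin_trials(levels, correct)
    n_total = int(n.sum())
    a0, b0, _ = _fit_binned(x, n, k, guess, lapse)
    # cells: (level, correct) and (level, incorrect)
    probs = np.concatenate([k, n - k]) / n_total
    thresholds = []
    failures = 0
    for _ in range(n_resamples):
        counts = rng.multinomial(n_total, probs)
        k_b = counts[: x.size].astype(float)
        n_b = k_b + counts[x.size:]
        keep = n_b > 0
        if keep.sum() < 2 or k_b.sum() in (0, n_b.sum()):
            failures += 1
            continue
        try:
            a, b, _ = _fit_binned(x[keep], n_b[keep], k_b[keep], guess, lapse,
                                  init=(a0, b0))
            fit = PsychometricFit(a, b, guess, lapse, np.nan, n_total, 0.0)
            thresholds.append(fit.threshold(pc_target))
        except (ValueError, RuntimeError):
            failures += 1
    if failures:
        warnings.warn(f"{failures} of {n_resamples} bootstrap refits failed and were excluded")
    if len(thresholds) < 2:
        raise ValueError("too few successful bootstrap refits to estimate an SE")
    return float(np.std(thresholds, ddof=1)), failures


def logit(p, continuity: float | None = None):
    """Log-odds transform log(p / (1 - p)).

    ``p`` in (0, 1); values of exactly 0 or 1 raise unless a ``continuity``
    correction is supplied, in which case p is squeezed into
    [continuity, 1 - continuity] first.
    """
    p = np.asarray(p, dtype=float)
    if continuity is not None:
        p = np.clip(p, continuity, 1.0 - continuity)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("logit undefined at 0 or 1; pass a continuity correction")
    out = special.logit(p)
    return float(out) if out.ndim == 0 else out


@dataclass
class QuadraticFit:
    """Least-squares quadratic y = a x^2 + b x + c with fit diagnostics."""

    a: float
    b: float
    c: float
    rss: float
    df: int

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a * x**2 + self.b * x + self.c


def fit_quadratic(x, y) -> QuadraticFit:
    """Ordinary least-squares quadratic fit of thresholds against an axis."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need at least 4 (x, y) points for a quadratic fit")
    design = np.column_stack([x**2, x, np.ones_like(x)])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("rank-deficient design: x values do not span a quadratic")
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return QuadraticFit(float(coef[0]), float(coef[1]), float(coef[2]),
                        float(resid @ resid), int(x.size - 3))


@dataclass
class CurveComparison:
    """Extra-sum-of-squares F test of one shared vs two separate quadratics."""

    f: float
    df1: int
    df2: int
    p: float
    rss_shared: float
    rss_separate: float


def compare_quadratic_fits(data1, data2) -> CurveComparison:
    """Test whether two datasets require different quadratic curves.

    Fits one quadratic to the pooled data (the nested model) and separate
    quadratics to each dataset, then compares with the extra-sum-of-squares
    F statistic on (3, N - 6) degrees of freedom — (3, 12) for two 9-point
    curves.
    """
    (x1, y1), (x2, y2) = data1, data2
    fit1, fit2 = fit_quadratic(x1, y1), fit_quadratic(x2, y2)
    pooled = fit_quadratic(np.concatenate([x1, x2]), np.concatenate([y1, y2]))
    rss_sep = fit1.rss + fit2.rss
    n_total = len(x1) + len(x2)
    df1 = 3
    df2 = n_total - 6
    if df2 < 1:
        raise ValueError("not enough points to compare two quadratics")
    if rss_sep <= 0:
        # both curves fit their data perfectly; F is infinite unless pooled also fits
        f = 0.0 if pooled.rss <= 1e-12 else np.inf
    else:
        f = (pooled.rss - rss_sep) / df1 / (rss_sep / df2)
        f = max(f, 0.0)
    p = float(stats.f.sf(f, df1, df2))
    return CurveComparison(float(f), df1, df2, p, pooled.rss, rss_sep)
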