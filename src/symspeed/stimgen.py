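"""Dynamic dot-pattern stimulus generation for mirror-symmetry detection.

Stimuli are limited-lifetime dot kinematograms presented in a square window:
a subset of dots forms mirror pairs about the vertical axis (x = 0) and drifts
in mirror-symmetric directions, while the remaining "noise" dots are randomly
positioned with equal numbers in each half.  Five conditions are supported:

``speed``
    symmetric dots drift at one speed, noise dots at another (possibly equal);
``flicker``
    dots are relocated at the end of their lifetime but do not drift;
``static``
    a single pattern held for the whole interval;
``segregated``
    all symmetric dots share one of the two stimulus speeds (chosen at
    random), all noise dots the other;
``non_segregated``
    symmetric dots and noise dots are each split half/half across the two
    speeds, pair members sharing one speed.

Every drifting dot travels a fixed distance (1.18 deg by default) before it
"dies" and is relocated, so lifetime duration varies inversely with speed.
Mirror pairs are relocated simultaneously to fresh mirrored positions with a
fresh mirrored direction; different pairs die asynchronously.

Coordinates: origin at the window centre, x positive rightward, y positive
upward, mirror axis x = 0; angles in radians, 0 = rightward, counter-clockwise
positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "StimulusParams",
    "DotPattern",
    "FrameSequence",
    "LifetimeInfo",
    "compute_lifetime",
    "make_symmetric_pattern",
    "assign_directions",
    "assign_speeds",
    "advance_frame",
    "make_trial",
    "render_frames",
    "frames_to_table",
]

CONDITIONS = ("speed", "flicker", "static", "segregated", "non_segregated")

#: conditions in which dots drift between relocations
_MOTION_CONDITIONS = ("speed", "segregated", "non_segregated")


class LifetimeInfo(NamedTuple):
    """Frame-quantized lifetime of a drifting element and derived quantities."""

    frames: int
    ms: float
    temporal_frequency_hz: float
    effective_speed: float


def compute_lifetime(
    speed: float, travel_distance: float = 1.18, refresh_rate: float = 85.0
) -> LifetimeInfo:
    """Lifetime of an element travelling ``travel_distance`` at ``speed``.

    The travel time is quantized to a whole number of display frames; the
    lifetime in ms, the relocation temporal frequency (1000 / lifetime_ms)
    and the frame-derived effective speed (travel_distance / lifetime) are
    all computed from the quantized value.

    Parameters
    ----------
    speed : float
        Drift speed in deg/s.  For flicker conditions pass the speed whose
        lifetime is being matched.
    travel_distance : float
        Distance in degrees each element covers before relocation.
    refresh_rate : float
        Display refresh rate in Hz.

    Returns
    -------
    LifetimeInfo
        ``(frames, ms, temporal_frequency_hz, effective_speed)``.

    Examples
    --------
    >>> compute_lifetime(3.33).ms
    352.94117647058823
    >>> compute_lifetime(10.0).frames
    10
    """
    if speed <= 0 or travel_distance <= 0 or refresh_rate <= 0:
        raise ValueError("speed, travel_distance and refresh_rate must be positive")
    frames = int(round(travel_distance / speed * refresh_rate))
    if frames < 1:
        raise ValueError("lifetime shorter than one frame; reduce speed or raise refresh rate")
    ms = frames / refresh_rate * 1000.0
    return LifetimeInfo(frames, ms, 1000.0 / ms, travel_distance / (frames / refresh_rate))


@dataclass(frozen=True)
class StimulusParams:
    """Geometry and timing of one stimulus interval.

    Defaults reproduce the canonical display: a 13.74 deg square window with
    32 dots of 0.24 deg diameter (density 0.17 dots/deg^2) shown for 400 ms
    at 85 Hz (34 frames), each drifting element travelling 1.18 deg per life.
    """

    window_size: float = 13.74
    n_dots: int = 32
    dot_diameter: float = 0.24
    refresh_rate: float = 85.0
    duration_ms: float = 400.0
    travel_distance: float = 1.18
    speeds: tuple[float, ...] = (3.33,)
    proportion_symmetric: float = 0.5
    condition: str = "speed"
    min_separation: float | None = None  # optional minimum inter-dot distance, degrees

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")
        if self.n_dots <= 0 or self.n_dots % 2:
            raise ValueError("n_dots must be a positive even count")
        if not 0.0 <= self.proportion_symmetric <= 1.0:
            raise ValueError("proportion_symmetric must lie in [0, 1]")
        if self.window_size <= 0 or self.dot_diameter <= 0:
            raise ValueError("window_size and dot_diameter must be positive")
        if not self.speeds or any(s <= 0 for s in self.speeds):
            raise ValueError("speeds must be a non-empty tuple of positive values")
        object.__setattr__(self, "speeds", tuple(float(s) for s in self.speeds))

    @property
    def n_frames(self) -> int:
        """Number of display frames in one interval (34 for 400 ms at 85 Hz)."""
        return int(round(self.duration_ms / 1000.0 * self.refresh_rate))

    @property
    def dot_density(self) -> float:
        """Dots per square degree."""
        return self.n_dots / self.window_size**2

    @property
    def n_symmetric_dots(self) -> int:
        """Symmetric dot count implied by proportion_symmetric, pair-quantized."""
        pairs = int(round(self.proportion_symmetric * self.n_dots / 2))
        return 2 * pairs


@dataclass
class DotPattern:
    """Per-dot state for one frame.

    Arrays are aligned by dot index.  ``pair_id`` is >= 0 for the two members
    of a mirror pair and -1 for noise dots; ``birth_half`` records the half
    (-1 left, +1 right) a noise dot was born in so relocation preserves equal
    per-half noise counts.
    """

    x: np.ndarray
    y: np.ndarray
    pair_id: np.ndarray
    speed: np.ndarray
    direction: np.ndarray
    age: np.ndarray
    lifetime: np.ndarray
    birth_half: np.ndarray

    @property
    def n_dots(self) -> int:
        return self.x.size

    @property
    def is_symmetric(self) -> np.ndarray:
        return self.pair_id >= 0

    def copy(self) -> "DotPattern":
        return DotPattern(*(getattr(self, f).copy() for f in (
            "x", "y", "pair_id", "speed", "direction", "age", "lifetime", "birth_half")))

    def check_mirror(self, atol: float = 1e-9) -> bool:
        """True iff every mirror pair is exactly mirrored in position and direction."""
        for pid in np.unique(self.pair_id[self.pair_id >= 0]):
            i, j = np.flatnonzero(self.pair_id == pid)
            left, right = (i, j) if self.x[i] < self.x[j] else (j, i)
            if abs(self.x[left] + self.x[right]) > atol or abs(self.y[left] - self.y[right]) > atol:
                return False
            dd = (self.direction[right] - (np.pi - self.direction[left])) % (2 * np.pi)
            if min(dd, 2 * np.pi - dd) > atol:
                return False
            if self.age[i] != self.age[j] or self.lifetime[i] != self.lifetime[j]:
                return False
        return True


@dataclass
class FrameSequence:
    """Ordered frames of one stimulus interval plus its generating parameters."""

    frames: list[DotPattern]
    params: StimulusParams
    n_symmetric_dots: int = 0

    @property
    def n_frames(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# construction helpers

def _sample_left_positions(n: int, params: StimulusParams, rng: np.random.Generator,
                           x_lo: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Uniform positions in the left half, keeping pair partners off the axis."""
    half = params.window_size / 2.0
    r = params.dot_diameter / 2.0
    hi = -r  # pair members never coincide on the axis
    lo = -half if x_lo is None else x_lo
    x = rng.uniform(lo, hi, size=n)
    y = rng.uniform(-half, half, size=n)
    return x, y


def _sample_half_positions(n: int, side: int, params: StimulusParams,
                           rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    half = params.window_size / 2.0
    x = rng.uniform(0.0, half, size=n) * side
    y = rng.uniform(-half, half, size=n)
    return x, y


def _enforce_separation(pattern: DotPattern, params: StimulusParams,
                        rng: np.random.Generator, max_iter: int = 200) -> None:
    """Resample overlapping dots until all centres are >= one diameter apart."""
    if params.min_separation is None:
        return
    d_min = params.min_separation
    for _ in range(max_iter):
        dx = pattern.x[:, None] - pattern.x[None, :]
        dy = pattern.y[:, None] - pattern.y[None, :]
        dist = np.hypot(dx, dy)
        np.fill_diagonal(dist, np.inf)
        bad = np.flatnonzero(dist.min(axis=1) < d_min)
        if bad.size == 0:
            return
        for i in bad:
            if pattern.pair_id[i] >= 0:
                members = np.flatnonzero(pattern.pair_id == pattern.pair_id[i])
                xl, yl = _sample_left_positions(1, params, rng)
                for m in members:
                    sgn = -1.0 if pattern.x[m] < 0 else 1.0
                    pattern.x[m], pattern.y[m] = sgn * abs(xl[0]), yl[0]
            else:
                side = int(pattern.birth_half[i])
                xs, ys = _sample_half_positions(1, side, params, rng)
                pattern.x[i], pattern.y[i] = xs[0], ys[0]
    warnings.warn("minimum separation not achieved after resampling; pattern left as-is")


def make_symmetric_pattern(params: StimulusParams, n_symmetric_dots: int,
                           rng: np.random.Generator | int) -> DotPattern:
    """Build one frame with ``n_symmetric_dots`` in mirror pairs, the rest noise.

    Pairs are placed by sampling left-half positions uniformly and reflecting
    them about x = 0; noise dots are placed uniformly with equal counts in
    each half.  All dots start at the first configured speed; starting ages
    are uniform whole frames in [0, lifetime), shared within a pair so pairs
    die together.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = params.n_dots
    if n_symmetric_dots % 2:
        raise ValueError("n_symmetric_dots must be even (dots come in mirror pairs)")
    if not 0 <= n_symmetric_dots <= n:
        raise ValueError("n_symmetric_dots must lie in [0, n_dots]")
    n_pairs = n_symmetric_dots // 2
    n_noise = n - n_symmetric_dots
    if n_noise % 2:
        raise ValueError("noise dot count must be even to balance the two halves")

    x = np.empty(n)
    y = np.empty(n)
    pair_id = np.full(n, -1, dtype=int)
    birth_half = np.empty(n, dtype=int)

    xl, yl = _sample_left_positions(n_pairs, params, rng)
    x[:n_pairs], y[:n_pairs] = xl, yl
    x[n_pairs:2 * n_pairs], y[n_pairs:2 * n_pairs] = -xl, yl
    pair_id[:n_pairs] = np.arange(n_pairs)
    pair_id[n_pairs:2 * n_pairs] = np.arange(n_pairs)
    birth_half[:n_pairs] = -1
    birth_half[n_pairs:2 * n_pairs] = 1

    k = n_noise // 2
    for block, side in ((slice(2 * n_pairs, 2 * n_pairs + k), -1),
                        (slice(2 * n_pairs + k, n), 1)):
        xs, ys = _sample_half_positions(k, side, params, rng)
        x[block], y[block] = xs, ys
        birth_half[block] = side

    lt = compute_lifetime(params.speeds[0], params.travel_distance, params.refresh_rate).frames
    speed = np.full(n, params.speeds[0])
    lifetime = np.full(n, lt, dtype=int)
    age = np.empty(n, dtype=int)
    pair_ages = rng.integers(0, lt, size=n_pairs) if n_pairs else np.empty(0, dtype=int)
    age[:n_pairs] = pair_ages
    age[n_pairs:2 * n_pairs] = pair_ages
    age[2 * n_pairs:] = rng.integers(0, lt, size=n_noise)

    # placeholder directions, already mirrored (left 0, right pi) so the pair
    # invariants hold before assign_directions runs
    direction = np.zeros(n)
    direction[n_pairs:2 * n_pairs] = np.pi
    pattern = DotPattern(x, y, pair_id, speed, direction, age, lifetime, birth_half)
    _enforce_separation(pattern, params, rng)
    return pattern


def assign_directions(pattern: DotPattern, rng: np.random.Generator | int) -> DotPattern:
    """Assign drift directions: mirrored within pairs, mirrored-multiset noise.

    Each pair's left member gets an independent uniform direction and the
    right member its mirror image pi - theta.  Left-half noise directions are
    sampled uniformly; the mirrored multiset of those directions is randomly
    permuted over the right-half noise dots, so both halves share one
    direction distribution without dot-level symmetry.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = pattern.copy()
    for pid in np.unique(out.pair_id[out.pair_id >= 0]):
        i, j = np.flatnonzero(out.pair_id == pid)
        left, right = (i, j) if out.x[i] < out.x[j] else (j, i)
        theta = rng.uniform(0.0, 2 * np.pi)
        out.direction[left] = theta
        out.direction[right] = (np.pi - theta) % (2 * np.pi)
    noise = np.flatnonzero(out.pair_id < 0)
    left_noise = noise[out.birth_half[noise] < 0]
    right_noise = noise[out.birth_half[noise] > 0]
    thetas = rng.uniform(0.0, 2 * np.pi, size=left_noise.size)
    out.direction[left_noise] = thetas
    out.direction[right_noise] = rng.permutation((np.pi - thetas) % (2 * np.pi))
    return out


def _set_lifetimes(pattern: DotPattern, params: StimulusParams,
                   rng: np.random.Generator) -> None:
    """Recompute lifetimes from current speeds and redraw starting ages."""
    for s in np.unique(pattern.speed):
        lt = compute_lifetime(s, params.travel_distance, params.refresh_rate).frames
        pattern.lifetime[pattern.speed == s] = lt
    done = np.zeros(pattern.n_dots, dtype=bool)
    for i in range(pattern.n_dots):
        if done[i]:
            continue
        if pattern.pair_id[i] >= 0:
            members = np.flatnonzero(pattern.pair_id == pattern.pair_id[i])
        else:
            members = np.array([i])
        a = rng.integers(0, pattern.lifetime[i])
        pattern.age[members] = a
        done[members] = True


def assign_speeds(pattern: DotPattern, condition: str,
                  speed_pair: tuple[float, float],
                  rng: np.random.Generator | int,
                  params: StimulusParams | None = None) -> DotPattern:
    """Distribute the two stimulus speeds over symmetric and noise dots.

    ``speed``: symmetric dots at S1, noise dots at S2.  ``segregated``: the
    symmetric pattern's speed is drawn at random from {S1, S2} (so observers
    cannot predict which speed carries the symmetry signal) and noise takes
    the other.  ``non_segregated``: half the pairs and half the noise dots at
    each speed, pair members sharing one speed, noise balanced per half.
    Lifetimes are recomputed from the new speeds and starting ages redrawn.
    """
    if condition not in _MOTION_CONDITIONS:
        raise ValueError(f"condition must be one of {_MOTION_CONDITIONS}, got {condition!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    params = params or StimulusParams(speeds=tuple(speed_pair), condition=condition)
    s1, s2 = float(speed_pair[0]), float(speed_pair[1])
    out = pattern.copy()
    sym = out.is_symmetric
    noise = ~sym

    if condition == "speed":
        out.speed[sym] = s1
        out.speed[noise] = s2
    elif condition == "segregated":
        s_sym = s1 if rng.random() < 0.5 else s2
        out.speed[sym] = s_sym
        out.speed[noise] = s2 if s_sym == s1 else s1
    else:  # non_segregated
        pids = np.unique(out.pair_id[sym])
        rng.shuffle(pids)
        fast = np.isin(out.pair_id, pids[: pids.size // 2])
        out.speed[sym & fast] = s1
        out.speed[sym & ~fast] = s2
        for side in (-1, 1):
            idx = np.flatnonzero(noise & (out.birth_half == side))
            idx = rng.permutation(idx)
            out.speed[idx[: idx.size // 2]] = s1
            out.speed[idx[idx.size // 2:]] = s2

    _set_lifetimes(out, params, rng)
    return out


def _relocate(pattern: DotPattern, dead: np.ndarray, params: StimulusParams,
              rng: np.random.Generator) -> None:
    """Relocate dead dots in place: pairs together to mirrored positions."""
    handled = np.zeros(pattern.n_dots, dtype=bool)
    for i in np.flatnonzero(dead):
        if handled[i]:
            continue
        if pattern.pair_id[i] >= 0:
            members = np.flatnonzero(pattern.pair_id == pattern.pair_id[i])
            xl, yl = _sample_left_positions(1, params, rng)
            theta = rng.uniform(0.0, 2 * np.pi)
            for m in members:
                left = pattern.birth_half[m] < 0
                pattern.x[m] = xl[0] if left else -xl[0]
                pattern.y[m] = yl[0]
                pattern.direction[m] = theta if left else (np.pi - theta) % (2 * np.pi)
                pattern.age[m] = 0
            handled[members] = True
        else:
            side = int(pattern.birth_half[i])
            xs, ys = _sample_half_positions(1, side, params, rng)
            pattern.x[i], pattern.y[i] = xs[0], ys[0]
            pattern.direction[i] = rng.uniform(0.0, 2 * np.pi)
            pattern.age[i] = 0
            handled[i] = True


def advance_frame(pattern: DotPattern, condition: str, params: StimulusParams,
                  rng: np.random.Generator | int) -> DotPattern:
    """Advance the pattern by one display frame.

    Motion conditions displace each dot by speed/refresh_rate along its
    direction and increment ages; flicker only ages; static returns the
    pattern unchanged.  Dots whose age reaches their lifetime — or that drift
    outside the window, which is treated as death — are relocated, pairs
    simultaneously to fresh mirrored positions with a fresh mirrored
    direction.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if condition == "static":
        return pattern.copy()
    out = pattern.copy()
    if condition in _MOTION_CONDITIONS:
        step = out.speed / params.refresh_rate
        out.x += step * np.cos(out.direction)
        out.y += step * np.sin(out.direction)
    out.age += 1
    half = params.window_size / 2.0
    escaped = (np.abs(out.x) > half) | (np.abs(out.y) > half)
    # a pair is mirrored, so if one member escapes both do; still propagate
    for pid in np.unique(out.pair_id[(out.pair_id >= 0)]):
        members = out.pair_id == pid
        if escaped[members].any():
            escaped |= members
    dead = (out.age >= out.lifetime) | escaped
    if dead.any():
        _relocate(out, dead, params, rng)
    return out


def make_trial(params: StimulusParams, n_symmetric_dots: int,
               rng: np.random.Generator | int) -> tuple[FrameSequence, FrameSequence]:
    """Generate matched target and foil intervals for one 2IFC trial.

    The target contains ``n_symmetric_dots`` in mirror pairs; the foil has
    every dot randomly positioned but the same per-speed dot counts per half
    and the same mirrored-multiset direction construction, so the two
    intervals differ only in positional symmetry.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cond = params.condition
    speeds = params.speeds if len(params.speeds) >= 2 else (params.speeds[0],) * 2

    target0 = make_symmetric_pattern(params, n_symmetric_dots, rng)
    target0 = assign_directions(target0, rng)
    if cond in _MOTION_CONDITIONS:
        target0 = assign_speeds(target0, cond, (speeds[0], speeds[1]), rng, params)

    # foil: all noise, per-half per-speed counts copied from the target
    foil0 = make_symmetric_pattern(params, 0, rng)
    foil0 = assign_directions(foil0, rng)
    for side in (-1, 1):
        t_speeds = target0.speed[target0.birth_half == side]
        f_idx = np.flatnonzero(foil0.birth_half == side)
        foil0.speed[f_idx] = rng.permutation(t_speeds)
    _set_lifetimes(foil0, params, rng)

    sequences = []
    for pat in (target0, foil0):
        frames = [pat]
        for _ in range(params.n_frames - 1):
            pat = advance_frame(pat, cond, params, rng)
            frames.append(pat)
        sequences.append(frames)
    return (FrameSequence(sequences[0], params, n_symmetric_dots),
            FrameSequence(sequences[1], params, 0))


def render_frames(seq: FrameSequence, pixels_per_degree: float = 16.0) -> np.ndarray:
    """Rasterize a frame sequence to a uint8 image stack.

    White discs of the configured diameter on a mid-grey background.  Dots
    whose disc extends past the canvas are clipped with a warning.
    """
    if pixels_per_degree <= 0:
        raise ValueError("pixels_per_degree must be positive")
    p = seq.params
    size = int(round(p.window_size * pixels_per_degree))
    radius_px = p.dot_diameter / 2.0 * pixels_per_degree
    half = p.window_size / 2.0
    stack = np.full((seq.n_frames, size, size), 128, dtype=np.uint8)
    yy, xx = np.mgrid[0:size, 0:size]
    clipped = False
    for k, frame in enumerate(seq.frames):
        for x, y in zip(frame.x, frame.y):
            cx = (x + half) * pixels_per_degree
            cy = (half - y) * pixels_per_degree  # image rows grow downward
            if not (radius_px <= cx <= size - radius_px and radius_px <= cy <= size - radius_px):
                clipped = True
            mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2
            stack[k][mask] = 255
    if clipped:
        warnings.warn("some dots extended past the canvas and were clipped")
    return stack


def frames_to_table(seq: FrameSequence) -> pd.DataFrame:
    """Tidy per-frame dot coordinates for export as delimited text."""
    rows = []
    for k, frame in enumerate(seq.frames):
        for i in range(frame.n_dots):
            rows.append((k, i, int(frame.pair_id[i]), frame.x[i], frame.y[i],
                         frame.speed[i], frame.direction[i], bool(frame.pair_id[i] >= 0)))
    return pd.DataFrame(rows, columns=["frame", "dot_id", "pair_id", "x_deg", "y_deg",
                                       "speed", "direction", "is_symmetric"])
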