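"""One-up, three-down adaptive staircases with two interleaved tracks.

The staircase controls the percentage of symmetric dots in the target
interval.  Because symmetric dots come in mirror pairs of a 32-dot pattern,
levels are quantized to whole pairs — multiples of 100/16 = 6.25% — and the
default step is one pair.  After every incorrect response the level rises by
one step; after three consecutive correct responses it falls by one step.
The rule's fixed point is the level at which p^3 = 1/2, i.e. a true
proportion correct of (1/2)^(1/3) ~ 0.7937.

A run interleaves two 75-trial tracks, one starting at 100% symmetry and one
at 0%, and logs every trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PAIR_QUANTUM", "StaircaseTrack", "convergence_pc", "run_interleaved"]

#: level change represented by one mirror pair of a 32-dot pattern, in % symmetry
PAIR_QUANTUM = 100.0 / 16.0


def convergence_pc(down_rule: int) -> float:
    """Proportion correct at which a 1-up, ``down_rule``-down staircase has zero drift.

    The level is as likely to move down (after ``down_rule`` consecutive
    correct responses) as up, so p**down_rule = 1/2.
    """
    if down_rule < 1:
        raise ValueError("down_rule must be at least 1")
    return float(0.5 ** (1.0 / down_rule))


@dataclass
class StaircaseTrack:
    """State of one adaptive track.

    Levels are % symmetry clipped to [0, 100]; ``step`` defaults to one
    mirror pair (6.25%).  The track terminates after ``max_trials`` updates.
    """

    level: float = 100.0
    step: float = PAIR_QUANTUM
    down_rule: int = 3
    max_trials: int = 75
    consecutive_correct: int = 0
    n_trials: int = 0
    history: list[tuple[float, bool]] = field(default_factory=list)

    @property
    def terminated(self) -> bool:
        return self.n_trials >= self.max_trials

    def update(self, correct: bool) -> "StaircaseTrack":
        """Record one response at the current level and move the level."""
        if self.terminated:
            raise RuntimeError("staircase track already terminated")
        self.history.append((self.level, bool(correct)))
        self.n_trials += 1
        if correct:
            self.consecutive_correct += 1
            if self.consecutive_correct >= self.down_rule:
                self.level -= self.step
                self.consecutive_correct = 0
        else:
            self.consecutive_correct = 0
            self.level += self.step
        self.level = float(np.clip(self.level, 0.0, 100.0))
        return self


def run_interleaved(observer, rng: np.random.Generator | int, *,
                    n_trials_per_track: int = 75,
                    starts: tuple[float, float] = (100.0, 0.0),
                    step: float = PAIR_QUANTUM,
                    down_rule: int = 3,
                    randomize_order: bool = False) -> pd.DataFrame:
    """Run two interleaved staircase tracks against an observer.

    ``observer`` needs a ``respond_level(level, rng) -> bool`` method.  Track
    selection is strict alternation by default; ``randomize_order=True`` draws
    the next non-terminated track at random instead.  Returns the per-trial
    log with columns ``trial, track, level, correct``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    tracks = [StaircaseTrack(level=s, step=step, down_rule=down_rule,
                             max_trials=n_trials_per_track) for s in starts]
    rows = []
    trial = 0
    while any(not t.terminated for t in tracks):
        open_ids = [i for i, t in enumerate(tracks) if not t.terminated]
        if randomize_order:
            i = int(rng.choice(open_ids))
        else:
            i = open_ids[trial % len(tracks) if len(open_ids) == len(tracks) else 0]
        track = tracks[i]
        level = track.level
        correct = bool(observer.respond_level(level, rng))
        track.update(correct)
        rows.append((trial, i, level, correct))
        trial += 1
    return pd.DataFrame(rows, columns=["trial", "track", "level", "correct"])
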