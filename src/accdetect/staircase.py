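"""Adaptive staircase simulation for behavioural masked thresholds.

Models the TEN-test procedure used alongside the EEG session: a
2-down/1-up track with asymmetric steps (4 dB down after the required
correct responses, 2 dB up after a miss) starting at 70 dB HL.  The
listener is a logistic psychometric function of level; an infinite
slope gives a deterministic step-function listener.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["StaircaseResult", "simulate_staircase"]


@dataclass
class StaircaseResult:
    """Full audit trail of one adaptive track."""

    threshold_db: float
    converged: bool
    track: list = field(default_factory=list)  # (level_db, correct) per trial
    reversal_levels: list = field(default_factory=list)
    rule: str = "2-down-1-up"

    @property
    def n_trials(self) -> int:
        return len(self.track)


def _p_correct(level_db: float, threshold_db: float, slope: Optional[float]) -> float:
    if slope is None or math.isinf(slope):
        return 1.0 if level_db >= threshold_db else 0.0
    return 1.0 / (1.0 + math.exp(-slope * (level_db - threshold_db)))


def simulate_staircase(
    true_threshold_db: float,
    down_step_db: float = 4.0,
    up_step_db: float = 2.0,
    start_db: float = 70.0,
    psychometric_slope: Optional[float] = None,
    rule: str = "2-down-1-up",
    n_reversals_stop: int = 8,
    n_reversals_average: int = 4,
    min_trials: int = 60,
    max_trials: int = 400,
    floor_db: Optional[float] = None,
    ceiling_db: Optional[float] = None,
    seed: Optional[int] = None,
) -> StaircaseResult:
    """Run one adaptive track and estimate the threshold.

    The track stops at the later of ``n_reversals_stop`` reversals and
    ``min_trials`` trials; the threshold is the mean of the last
    ``n_reversals_average`` reversal levels.  If the hard cap
    ``max_trials`` is hit first (e.g. a listener pinned at the level
    floor never reverses), the estimate is flagged ``converged=False``
    and falls back to the final presented level when there are too few
    reversals.
    """
    if down_step_db <= 0 or up_step_db <= 0:
        raise ValueError("step sizes must be positive")
    if rule not in ("2-down-1-up", "1-down-1-up"):
        raise ValueError(f"unknown rule {rule!r}")
    if psychometric_slope is not None and not math.isinf(psychometric_slope):
        if psychometric_slope <= 0:
            raise ValueError("psychometric_slope must be positive")
    n_down = 2 if rule == "2-down-1-up" else 1
    rng = np.random.default_rng(seed)

    level = float(start_db)
    consecutive_correct = 0
    last_direction = 0  # -1 down, +1 up
    track: list = []
    reversal_levels: list = []

    while len(track) < max_trials:
        p = _p_correct(level, true_threshold_db, psychometric_slope)
        correct = bool(rng.random() < p) if 0.0 < p < 1.0 else p >= 1.0
        track.append((level, correct))

        if correct:
            consecutive_correct += 1
            step = -down_step_db if consecutive_correct >= n_down else 0.0
            if step:
                consecutive_correct = 0
        else:
            consecutive_correct = 0
            step = up_step_db

        if step:
            direction = -1 if step < 0 else 1
            if last_direction and direction != last_direction:
                reversal_levels.append(level)
            last_direction = direction
            level += step
            if floor_db is not None:
                level = max(level, floor_db)
            if ceiling_db is not None:
                level = min(level, ceiling_db)

        if len(reversal_levels) >= n_reversals_stop and len(track) >= min_trials:
            break

    converged = len(reversal_levels) >= n_reversals_stop
    if len(reversal_levels) >= n_reversals_average:
        threshold = float(np.mean(reversal_levels[-n_reversals_average:]))
    elif reversal_levels:
        threshold = float(np.mean(reversal_levels))
        converged = False
    else:
        threshold = float(track[-1][0])
        converged = False

    return StaircaseResult(
        threshold_db=threshold,
        converged=converged,
        track=track,
        reversal_levels=reversal_levels,
        rule=rule,
    )
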