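"""Interval-timing task simulation with dual asymmetric staircases.

The task asks an agent to reproduce a 1 s interval. A response within
``tolerance`` ms of the target is a win (+100 points), otherwise a loss
(−100 points). Separate staircases per difficulty condition adjust the
tolerance after each valenced outcome — easy blocks shrink it by 3 ms on a
win and grow it by 12 ms on a loss, hard blocks the reverse (−12/+3) — so
that long-run accuracy is clamped near ``up/(up+down)``: ~80% easy, ~20%
hard. An optional fraction of trials receives a neutral outcome (0 points)
irrespective of timing error.

Units follow the task convention: response times and errors in seconds,
tolerances in milliseconds; :func:`s_to_ms` centralizes the conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "AgentConfig",
    "BehavioralTrial",
    "staircase_update",
    "staircase_level_update",
    "effective_tolerance",
    "simulate_agent_trial",
    "run_session",
    "reject_trials",
    "rt_change_table",
    "trials_to_frame",
    "frame_to_trials",
    "s_to_ms",
]

EASY = "easy"
HARD = "hard"
CONDITIONS = (EASY, HARD)
OUTCOMES = ("win", "loss", "neutral", "missing")

#: points delivered per outcome
SCORE_DELTA = {"win": 100, "loss": -100, "neutral": 0, "missing": 0}
#: reward value entering the RL model per outcome
REWARD = {"win": 1.0, "loss": -1.0, "neutral": 0.0, "missing": float("nan")}


def s_to_ms(x: float) -> float:
    """Seconds to milliseconds (the single conversion point)."""
    return x * 1000.0


@dataclass(frozen=True)
class TaskConfig:
    """Task parameters.

    ``step_easy``/``step_hard`` are (win_delta, loss_delta) in ms applied to
    the tolerance after a win/loss of that condition. Defaults follow the
    standard version: four blocks of 75 trials, tolerance bounded at
    15–200 ms, no neutral outcomes.
    """

    trials_per_block: int = 75
    block_order: tuple[str, ...] = (EASY, EASY, HARD, HARD)
    target_interval: float = 1.0
    step_easy: tuple[float, float] = (-3.0, 12.0)
    step_hard: tuple[float, float] = (-12.0, 3.0)
    tolerance_bounds: tuple[float, float] = (15.0, 200.0)
    neutral_rate: float = 0.0
    initial_tolerance: dict[str, float] = field(
        default_factory=lambda: {EASY: 100.0, HARD: 30.0}
    )
    #: unrecorded staircase trials per condition before the first block,
    #: emulating the task's training that initializes each staircase at the
    #: observer's performance level (15 per condition in the task; a longer
    #: burn-in equilibrates the staircase fully for clamped-rate estimates)
    staircase_burnin: int = 15

    def __post_init__(self) -> None:
        floor, ceiling = self.tolerance_bounds
        if not floor < ceiling:
            raise ValueError("tolerance floor must be below ceiling")
        if self.trials_per_block <= 0:
            raise ValueError("trials_per_block must be positive")
        if not 0.0 <= self.neutral_rate < 1.0:
            raise ValueError("neutral_rate must be in [0, 1)")
        for cond in self.block_order:
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
        # easy shrinks slowly on wins and grows fast on losses; hard the reverse
        if not (abs(self.step_easy[0]) < self.step_easy[1]):
            raise ValueError("easy staircase must shrink on win less than it grows on loss")
        if not (abs(self.step_hard[0]) > self.step_hard[1]):
            raise ValueError("hard staircase must shrink on win more than it grows on loss")

    def steps(self, condition: str) -> tuple[float, float]:
        if condition == EASY:
            return self.step_easy
        if condition == HARD:
            return self.step_hard
        raise ValueError(f"unknown condition {condition!r}")


@dataclass(frozen=True)
class AgentConfig:
    """Stationary observer: responds at target + bias + N(0, timing_sd),
    omitting the response with probability ``lapse_rate``."""

    timing_bias: float = 0.0
    timing_sd: float = 0.06
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.timing_sd <= 0:
            raise ValueError("timing_sd must be positive")
        if not 0.0 <= self.lapse_rate < 1.0:
            raise ValueError("lapse_rate must be in [0, 1)")


@dataclass(frozen=True)
class BehavioralTrial:
    """One task trial; ``tolerance`` is the value in effect on this trial
    (recorded before the post-outcome staircase update)."""

    trial_index: int
    block_index: int
    condition: str
    tolerance: float  # ms
    rt: float | None  # s, None if response omitted
    outcome: str
    error: float | None = None  # s, rt − target

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")

    @property
    def reward(self) -> float:
        return REWARD[self.outcome]

    @property
    def score_delta(self) -> int:
        return SCORE_DELTA[self.outcome]


#: how far (in ms) the internal staircase level may walk past the tolerance
#: bounds before being guard-clamped; deep enough that ordinary sub-floor
#: excursions never feel it (a shallow guard re-introduces part of the
#: clamp bias the free level exists to avoid) while still bounding agents
#: whose equilibrium lies outside the bounds entirely
_LEVEL_MARGIN = 600.0


def effective_tolerance(level_ms: float, config: TaskConfig) -> float:
    """Tolerance in effect for scoring: the staircase level clamped to the
    configured bounds."""
    floor, ceiling = config.tolerance_bounds
    return float(min(max(level_ms, floor), ceiling))


def staircase_level_update(
    condition: str, level_ms: float, outcome: str, config: TaskConfig
) -> float:
    """Post-trial update of the *internal* staircase level.

    Wins/losses apply the condition's delta; neutral and missing outcomes
    leave the level untouched (no valenced feedback is delivered). The
    level itself is allowed to walk past the tolerance bounds (only the
    tolerance in effect is clamped) so that the asymmetric-step equilibrium
    ``accuracy = up/(up+down)`` holds even when it sits at a bound; a wide
    guard margin keeps the level from drifting indefinitely when the
    equilibrium is unreachable for a given observer.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    if outcome in ("neutral", "missing"):
        return level_ms
    win_delta, loss_delta = config.steps(condition)
    delta = win_delta if outcome == "win" else loss_delta
    floor, ceiling = config.tolerance_bounds
    return float(
        min(max(level_ms + delta, floor - _LEVEL_MARGIN), ceiling + _LEVEL_MARGIN)
    )


def staircase_update(
    condition: str, tolerance_ms: float, outcome: str, config: TaskConfig
) -> float:
    """One observable staircase step: apply the condition's win/loss delta
    to the in-effect tolerance and clamp to the configured bounds.

    E.g. hard condition at 20 ms after a win: 20 − 12 = 8, clamped to the
    15 ms floor. Session simulation uses :func:`staircase_level_update`
    underneath so consecutive sub-floor steps are remembered.
    """
    return effective_tolerance(
        staircase_level_update(condition, tolerance_ms, outcome, config), config
    )


def simulate_agent_trial(
    agent: AgentConfig,
    tolerance_ms: float,
    neutral_rate: float,
    rng: np.random.Generator,
    target_interval: float = 1.0,
    trial_index: int = 0,
    block_index: int = 0,
    condition: str = EASY,
) -> BehavioralTrial:
    """Simulate one trial of a stationary observer at a given tolerance.

    Draw order per trial is fixed (timing noise, lapse, neutral) so that a
    session is reproducible from its seed regardless of outcomes.
    """
    noise = rng.normal(0.0, agent.timing_sd)
    lapse = rng.random() < agent.lapse_rate
    neutral = rng.random() < neutral_rate
    if lapse:
        return BehavioralTrial(trial_index, block_index, condition,
                               tolerance_ms, None, "missing", None)
    rt = target_interval + agent.timing_bias + noise
    error = rt - target_interval
    if neutral:
        outcome = "neutral"
    else:
        outcome = "win" if abs(error) * 1000.0 <= tolerance_ms else "loss"
    return BehavioralTrial(trial_index, block_index, condition,
                           tolerance_ms, float(rt), outcome, float(error))


def run_session(
    config: TaskConfig, agent: AgentConfig, seed: int
) -> list[BehavioralTrial]:
    """Simulate a full session of ``len(block_order)`` blocks.

    Staircase state is carried within condition across blocks (an easy
    block resumes the tolerance the previous easy block ended on).
    """
    rng = np.random.default_rng(seed)
    level = dict(config.initial_tolerance)
    conditions_used = sorted(set(config.block_order))
    for condition in conditions_used:
        for _ in range(config.staircase_burnin):
            warm = simulate_agent_trial(
                agent, effective_tolerance(level[condition], config),
                config.neutral_rate, rng,
                target_interval=config.target_interval, condition=condition,
            )
            level[condition] = staircase_level_update(
                condition, level[condition], warm.outcome, config
            )
    trials: list[BehavioralTrial] = []
    idx = 0
    for block_index, condition in enumerate(config.block_order):
        for _ in range(config.trials_per_block):
            trial = simulate_agent_trial(
                agent, effective_tolerance(level[condition], config),
                config.neutral_rate, rng,
                target_interval=config.target_interval,
                trial_index=idx, block_index=block_index, condition=condition,
            )
            trials.append(trial)
            level[condition] = staircase_level_update(
                condition, level[condition], trial.outcome, config
            )
            idx += 1
    return trials


def reject_trials(
    trials: list[BehavioralTrial], sd_mult: float = 3.0
) -> list[BehavioralTrial]:
    """Behavioral trial rejection: drop missing responses, RTs outside
    [0.5, 1.5] s, and RTs more than ``sd_mult`` session SDs from the session
    mean (mean/SD computed over the range-surviving RTs)."""
    in_range = [
        t for t in trials
        if t.rt is not None and 0.5 <= t.rt <= 1.5
    ]
    if not in_range:
        return []
    rts = np.array([t.rt for t in in_range])
    mean, sd = rts.mean(), rts.std(ddof=1) if len(rts) > 1 else 0.0
    if sd == 0 or math.isnan(sd):
        return in_range
    return [t for t in in_range if abs(t.rt - mean) <= sd_mult * sd]


def trials_to_frame(trials: list[BehavioralTrial]) -> pd.DataFrame:
    """Trial list → tidy table with the fixed column contract
    (trial_index, block_index, condition, tolerance_ms, rt_s, outcome, reward)."""
    return pd.DataFrame(
        {
            "trial_index": [t.trial_index for t in trials],
            "block_index": [t.block_index for t in trials],
            "condition": [t.condition for t in trials],
            "tolerance_ms": [t.tolerance for t in trials],
            "rt_s": [t.rt if t.rt is not None else np.nan for t in trials],
            "outcome": [t.outcome for t in trials],
            "reward": [t.reward for t in trials],
        }
    )


def frame_to_trials(frame: pd.DataFrame) -> list[BehavioralTrial]:
    """Inverse of :func:`trials_to_frame` (error recomputed as rt − 1 s
    only if an ``error_s`` column is absent; missing rt → None)."""
    out = []
    for row in frame.itertuples(index=False):
        rt = None if pd.isna(row.rt_s) else float(row.rt_s)
        error = None if rt is None else rt - 1.0
        if hasattr(row, "error_s") and not pd.isna(getattr(row, "error_s")):
            error = float(row.error_s)
        out.append(
            BehavioralTrial(
                int(row.trial_index), int(row.block_index), str(row.condition),
                float(row.tolerance_ms), rt, str(row.outcome), error,
            )
        )
    return out


def rt_change_table(trials: list[BehavioralTrial]) -> pd.DataFrame:
    """Trial-to-trial RT adjustment table.

    One row per trial with a valid immediate predecessor in the same block:
    ``rt_change = rt_i − rt_{i−1}``. The first trial of each block, trials
    following a missing/removed trial (non-consecutive trial_index), and
    trials whose own RT is missing contribute no row. ``prev_outcome`` is a
    3-level factor (win/loss/neutral) when neutral trials exist.
    """
    rows = []
    for prev, cur in zip(trials, trials[1:]):
        if cur.block_index != prev.block_index:
            continue  # first trial of a block never pairs across the boundary
        if cur.trial_index != prev.trial_index + 1:
            continue  # a dropped/missing trial breaks the chain
        if prev.rt is None or cur.rt is None:
            continue
        if prev.outcome == "missing":
            continue
        rows.append(
            {
                "trial_index": cur.trial_index,
                "block_index": cur.block_index,
                "condition": cur.condition,
                "rt_change": cur.rt - prev.rt,
                "prev_rt": prev.rt,
                "prev_outcome": prev.outcome,
                "prev_trial_index": prev.trial_index,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "trial_index", "block_index", "condition", "rt_change",
            "prev_rt", "prev_outcome", "prev_trial_index",
        ],
    )
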