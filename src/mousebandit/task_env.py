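"""Trial schedule and stochastic outcomes for the probabilistic two-choice task.

The task is a two-armed bandit over two options (red, blue) played over two
blocks (gain, loss).  One option is "good": in the gain block it yields +1
with probability ``p_good`` (the other with ``p_bad``); in the loss block the
*bad* option yields -1 with probability ``p_good`` (mirror image under a sign
flip).  The good/bad assignment swaps with a per-trial hazard, making the
environment volatile.  Outcomes are always shown but only count toward the
participant's points on exploitation trials (a fixed fraction of trials).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

OPTIONS = ("red", "blue")
BLOCKS = ("gain", "loss")
SIDES = ("left", "right")


class ConfigurationError(ValueError):
    """Invalid task or model configuration."""


@dataclass(frozen=True)
class TaskConfig:
    """Design constants of the task.

    Defaults are the study conditions: 180 trials per block (360 total),
    outcome probabilities 0.9/0.1, switch hazard 0.2 per trial, 25%
    exploitation trials, 40 starting points.
    """

    n_trials_per_block: int = 180
    block_order: tuple[str, str] = ("gain", "loss")
    p_good: float = 0.9
    p_bad: float = 0.1
    switch_hazard: float = 0.2
    exploit_fraction: float = 0.25
    start_points: int = 40
    points_floor: int | None = None  # None: points may go negative
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_block < 1:
            raise ConfigurationError("n_trials_per_block must be >= 1")
        for name in ("p_good", "p_bad", "switch_hazard", "exploit_fraction"):
            v = getattr(self, name)
            if not np.isfinite(v) or not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be a finite probability, got {v!r}")
        if abs(self.p_good + self.p_bad - 1.0) > 1e-12:
            raise ConfigurationError("p_good + p_bad must equal 1")
        if not (0.0 < self.exploit_fraction < 1.0):
            raise ConfigurationError("exploit_fraction must lie strictly in (0, 1)")
        for b in self.block_order:
            if b not in BLOCKS:
                raise ConfigurationError(f"unknown block {b!r}")


@dataclass(frozen=True)
class TrialDesign:
    """One trial's design flags (no behaviour)."""

    block: str
    trial_index: int  # 1-based within block
    is_exploitation: bool
    good_option: str
    position_red: str  # side on which the red option is shown
    switched: bool  # did the good/bad assignment swap at this trial?

    @property
    def option_positions(self) -> dict[str, str]:
        other = "left" if self.position_red == "right" else "right"
        return {"red": self.position_red, "blue": other}


@dataclass(frozen=True)
class OutcomeRecord:
    outcome: int  # +1 gain, -1 loss, 0 nothing
    counted: bool
    points_after: int


def generate_schedule(config: TaskConfig, rng: np.random.Generator | None = None) -> list[TrialDesign]:
    """Generate the full two-block trial schedule.

    Exploitation trials are placed by seeded permutation with the exact count
    ``round(exploit_fraction * n)`` per block, so the printed counts (90/270
    at the defaults) are reproduced exactly.  Switch events are i.i.d.
    Bernoulli(``switch_hazard``) on every trial after the first of a block and
    swap the good/bad assignment of both options simultaneously.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    designs: list[TrialDesign] = []
    n = config.n_trials_per_block
    for block in config.block_order:
        n_exploit = int(round(config.exploit_fraction * n))
        exploit_idx = set(rng.permutation(n)[:n_exploit].tolist())
        good = OPTIONS[int(rng.integers(2))]
        for t in range(n):
            switched = bool(t > 0 and rng.random() < config.switch_hazard)
            if switched:
                good = OPTIONS[1 - OPTIONS.index(good)]
            designs.append(
                TrialDesign(
                    block=block,
                    trial_index=t + 1,
                    is_exploitation=t in exploit_idx,
                    good_option=good,
                    position_red=SIDES[int(rng.integers(2))],
                    switched=switched,
                )
            )
    return designs


def draw_outcome(
    design: TrialDesign,
    choice: str,
    config: TaskConfig,
    rng: np.random.Generator,
    points_before: int,
) -> OutcomeRecord:
    """Draw the stochastic outcome of one choice.

    Gain block: the chosen option yields +1 with probability ``p_good`` if it
    is the good option, else ``p_bad``; otherwise nothing.  Loss block: the
    *bad* option yields -1 with probability ``p_good``, the good option with
    ``p_bad``.  Points update only on exploitation trials.
    """
    if choice not in OPTIONS:
        raise ValueError(f"unknown option {choice!r}")
    chose_good = choice == design.good_option
    if design.block == "gain":
        p_point = config.p_good if chose_good else config.p_bad
        outcome = 1 if rng.random() < p_point else 0
    else:
        p_point = config.p_bad if chose_good else config.p_good
        outcome = -1 if rng.random() < p_point else 0
    counted = design.is_exploitation
    points_after = points_before + (outcome if counted else 0)
    if config.points_floor is not None:
        points_after = max(points_after, config.points_floor)
    return OutcomeRecord(outcome=outcome, counted=counted, points_after=points_after)


def label_optimality(designs: Sequence[TrialDesign], choices: Sequence[str]) -> list[str | None]:
    """Label each choice optimal/suboptimal relative to *experienced* probabilities.

    The optimal option at trial t is the one that was good under the most
    recently sampled set of probabilities, i.e. the previous trial's good
    option — even if the schedule switched underneath at trial t.  The first
    trial of each block is undefined (``None``) and should be excluded.
    """
    if len(designs) == 0:
        raise ValueError("empty history")
    if len(designs) != len(choices):
        raise ValueError("designs and choices must have equal length")
    labels: list[str | None] = []
    prev: TrialDesign | None = None
    for design, choice in zip(designs, choices):
        if prev is None or prev.block != design.block:
            labels.append(None)
        else:
            labels.append("optimal" if choice == prev.good_option else "suboptimal")
        prev = design
    return labels


def experience_counts(designs: Sequence[TrialDesign]) -> list[int]:
    """Trials of experience with the latest set of probabilities.

    Resets to 0 at each block start and at each switch event; otherwise
    increments by one per trial.
    """
    counts: list[int] = []
    prev_block = None
    exp = 0
    for d in designs:
        if d.block != prev_block or d.switched:
            exp = 0
        counts.append(exp)
        exp += 1
        prev_block = d.block
    return counts


def schedule_frame(designs: Sequence[TrialDesign]) -> pd.DataFrame:
    """Schedule as a tidy table, one row per trial (global 1-based index)."""
    rows = [dataclasses.asdict(d) for d in designs]
    df = pd.DataFrame(rows)
    df.insert(0, "trial", np.arange(1, len(df) + 1))
    df["trial_type"] = np.where(df["is_exploitation"], "exploitation", "learning")
    df["experience"] = experience_counts(designs)
    return df
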