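"""Two-lever bandit environments with probabilistic reversals.

Implements the dynamic probabilistic reversal learning (dynaPRL) task — three
block types of differing reward-probability contrast that switch within a
session — and the simpler single-contrast PRL task used during training.

Conventions
-----------
Actions are coded 0 (``A1``, the left lever) and 1 (``A2``, the right lever).
Outcomes are binary; reward volume is metadata (the magnitude manipulation
never enters the binary outcome consumed by the learning models). Trial and
block-trial indices are 1-based in exported tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

# canonical column order for trial tables
TRIAL_COLUMNS = [
    "session_id",
    "trial_index",
    "block_id",
    "block_type",
    "block_trial_index",
    "choice",
    "outcome",
    "reward_volume",
    "better_action",
    "valid",
]

BLOCK_TYPES = ("HC", "LC", "NC")
ACTION_LABELS = ("A1", "A2")


@dataclass(frozen=True)
class BlockSpec:
    """One reward-probability block.

    ``better_side`` is 0/1 (action index of the higher-probability lever) or
    None for no-contrast blocks where the two levers are equivalent.
    """

    block_type: str
    p_reward_better: float
    p_reward_worse: float
    better_side: Optional[int]
    scheduled_length: int

    def __post_init__(self) -> None:
        if self.block_type not in BLOCK_TYPES:
            raise ValueError(f"unknown block type {self.block_type!r}")
        if not (0.0 <= self.p_reward_worse <= self.p_reward_better <= 1.0):
            raise ValueError("require 0 <= p_worse <= p_better <= 1")
        if self.block_type == "NC":
            if self.better_side is not None:
                raise ValueError("NC block has no better side")
            if self.p_reward_better != self.p_reward_worse:
                raise ValueError("NC block must have equal probabilities")
        else:
            if self.better_side not in (0, 1):
                raise ValueError("contrast block needs better_side in {0, 1}")

    def p_reward(self, action: int) -> float:
        """Reward probability of pressing ``action`` in this block."""
        if self.better_side is None:
            return self.p_reward_better
        return self.p_reward_better if action == self.better_side else self.p_reward_worse


@dataclass(frozen=True)
class MagnitudeRule:
    """Reward-volume manipulation inside contrast blocks.

    After ``onset_trial`` trials of an HC/LC block have passed, a fraction of
    rewarded trials delivers a halved or doubled volume (equal odds).
    """

    onset_trial: int = 12
    fraction: float = 0.40
    volume_standard: float = 33.0
    volume_halved: float = 16.0
    volume_doubled: float = 66.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")


@dataclass(frozen=True)
class TaskConfig:
    """dynaPRL task parameters.

    ``block_menu`` maps block type to (p_better, p_worse). Default contrasts
    are HC 0.8/0.1, LC 0.6/0.3, NC 0.45/0.45. Blocks last 15-30 trials; the
    scheduled switch is deferred (or, with ``defer_mode='hasten'``, forced)
    while the last ``consecutive_error_defer`` choices in a contrast block are
    all incorrect.
    """

    block_menu: dict = field(
        default_factory=lambda: {"HC": (0.80, 0.10), "LC": (0.60, 0.30), "NC": (0.45, 0.45)}
    )
    min_len: int = 15
    max_len: int = 30
    consecutive_error_defer: int = 4
    defer_mode: str = "defer"  # "defer" | "hasten"
    magnitude_rule: MagnitudeRule = field(default_factory=MagnitudeRule)
    no_nc_repeat: bool = True
    no_better_side_repeat: bool = True

    def __post_init__(self) -> None:
        if not self.block_menu:
            raise ValueError("block menu must not be empty")
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")
        if self.defer_mode not in ("defer", "hasten"):
            raise ValueError("defer_mode must be 'defer' or 'hasten'")
        for bt, (pb, pw) in self.block_menu.items():
            if bt not in BLOCK_TYPES:
                raise ValueError(f"unknown block type {bt!r} in menu")
            if not (0.0 <= pw <= pb <= 1.0):
                raise ValueError(f"bad probabilities for {bt}: {(pb, pw)}")


@dataclass(frozen=True)
class PRLConfig:
    """Training-stage PRL task: fixed 0.70/0.10 contrast with EMA-gated reversals.

    A reversal becomes eligible once the exponential moving average of
    correctness (smoothing 2/(ema_window+1)) exceeds ``threshold``; it then
    occurs with probability ``p_reversal`` per trial and is forced after
    ``force_after`` eligible trials without one.
    """

    p_reward_better: float = 0.70
    p_reward_worse: float = 0.10
    threshold: float = 0.75
    ema_window: int = 8
    p_reversal: float = 0.10
    force_after: int = 20
    reward_volume: float = 33.0


@dataclass
class TrialRecord:
    session_id: str
    trial_index: int
    block_id: int
    block_type: str
    block_trial_index: int
    choice: int
    outcome: int
    reward_volume: float
    better_action: Optional[int]
    valid: bool = True


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Tidy trial table with A1/A2 labels, one row per trial."""
    rows = []
    for r in records:
        rows.append(
            {
                "session_id": r.session_id,
                "trial_index": r.trial_index,
                "block_id": r.block_id,
                "block_type": r.block_type,
                "block_trial_index": r.block_trial_index,
                "choice": ACTION_LABELS[r.choice],
                "outcome": r.outcome,
                "reward_volume": r.reward_volume,
                "better_action": "none" if r.better_action is None else ACTION_LABELS[r.better_action],
                "valid": r.valid,
            }
        )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def draw_next_block(
    history: Sequence[BlockSpec], config: TaskConfig, rng: np.random.Generator
) -> BlockSpec:
    """Draw the next block honoring the transition constraints.

    Neutral (NC) blocks are never repeated, and the better side never repeats
    across consecutive contrast blocks. Scheduled length is uniform on
    [min_len, max_len].
    """
    menu = list(config.block_menu.keys())
    prev = history[-1] if history else None

    candidates = list(menu)
    if prev is not None and config.no_nc_repeat and prev.block_type == "NC":
        candidates = [bt for bt in candidates if bt != "NC"]
    if not candidates:
        raise ValueError("no admissible block type given the transition constraints")

    block_type = candidates[rng.integers(len(candidates))]
    p_better, p_worse = config.block_menu[block_type]

    if block_type == "NC":
        better_side = None
    elif (
        prev is not None
        and config.no_better_side_repeat
        and prev.better_side is not None
    ):
        better_side = 1 - prev.better_side
    else:
        better_side = int(rng.integers(2))

    length = int(rng.integers(config.min_len, config.max_len + 1))
    return BlockSpec(block_type, p_better, p_worse, better_side, length)


def step(
    block: BlockSpec,
    choice: int,
    block_trial_index: int,
    rng: np.random.Generator,
    config: TaskConfig,
    *,
    session_id: str = "S0",
    trial_index: int = 1,
    block_id: int = 0,
) -> TrialRecord:
    """Play one trial of ``block``: Bernoulli outcome plus volume metadata."""
    if choice not in (0, 1):
        raise ValueError("choice must be 0 (A1) or 1 (A2)")
    if block_trial_index < 1:
        raise ValueError("block_trial_index is 1-based")

    p = block.p_reward(choice)
    outcome = int(rng.random() < p)

    mag = config.magnitude_rule
    volume = 0.0
    if outcome:
        volume = mag.volume_standard
        if block.block_type in ("HC", "LC") and block_trial_index > mag.onset_trial:
            if rng.random() < mag.fraction:
                volume = mag.volume_halved if rng.random() < 0.5 else mag.volume_doubled

    return TrialRecord(
        session_id=session_id,
        trial_index=trial_index,
        block_id=block_id,
        block_type=block.block_type,
        block_trial_index=block_trial_index,
        choice=choice,
        outcome=outcome,
        reward_volume=volume,
        better_action=block.better_side,
    )


def maybe_transition(
    block: BlockSpec,
    trials_elapsed: int,
    recent_outcomes_correct: Sequence[bool],
    config: TaskConfig,
) -> bool:
    """Decide whether the block ends after ``trials_elapsed`` trials.

    The scheduled switch is modified by the consecutive-error rule in contrast
    blocks only: under ``defer_mode='defer'`` the switch waits until the streak
    of incorrect choices is broken; under ``'hasten'`` a streak of
    ``consecutive_error_defer`` errors triggers an early switch.
    """
    if trials_elapsed < 1:
        raise ValueError("trials_elapsed must be >= 1")
    k = config.consecutive_error_defer
    streak = (
        len(recent_outcomes_correct) >= k
        and not any(recent_outcomes_correct[-k:])
    )
    is_contrast = block.block_type in ("HC", "LC")
    if config.defer_mode == "hasten" and is_contrast and streak:
        return True
    due = trials_elapsed >= block.scheduled_length
    if due and config.defer_mode == "defer" and is_contrast and streak:
        return False
    return due


def run_dynaprl_session(
    agent,
    config: TaskConfig,
    rng: np.random.Generator,
    n_trials: int,
    session_id: str = "S0",
) -> pd.DataFrame:
    """Simulate one dynaPRL session of ``n_trials`` with a generative agent.

    ``agent`` must expose ``choose(rng) -> int`` and ``observe(choice, outcome)``.
    """
    records: list[TrialRecord] = []
    blocks: list[BlockSpec] = [draw_next_block([], config, rng)]
    block_trial = 0
    correct_history: list[bool] = []

    for t in range(1, n_trials + 1):
        block = blocks[-1]
        block_trial += 1
        choice = agent.choose(rng)
        rec = step(
            block,
            choice,
            block_trial,
            rng,
            config,
            session_id=session_id,
            trial_index=t,
            block_id=len(blocks) - 1,
        )
        records.append(rec)
        agent.observe(choice, rec.outcome)
        # "correct" means pressing the better lever; in NC blocks no choice is
        # incorrect, so the error streak can only form in contrast blocks.
        correct = block.better_side is None or choice == block.better_side
        correct_history.append(correct)
        if maybe_transition(block, block_trial, correct_history, config):
            blocks.append(draw_next_block(blocks, config, rng))
            block_trial = 0
            correct_history = []
    return records_to_frame(records)


def run_prl_session(
    agent,
    config_prl: PRLConfig,
    rng: np.random.Generator,
    n_trials: int,
    session_id: str = "S0",
) -> pd.DataFrame:
    """Simulate one PRL session with EMA-gated probabilistic reversals."""
    records: list[TrialRecord] = []
    better = int(rng.integers(2))
    alpha_ema = 2.0 / (config_prl.ema_window + 1.0)
    ema = 0.0
    eligible_trials = 0
    block_id = 0
    block_trial = 0

    for t in range(1, n_trials + 1):
        block_trial += 1
        choice = agent.choose(rng)
        p = config_prl.p_reward_better if choice == better else config_prl.p_reward_worse
        outcome = int(rng.random() < p)
        records.append(
            TrialRecord(
                session_id=session_id,
                trial_index=t,
                block_id=block_id,
                block_type="HC",
                block_trial_index=block_trial,
                choice=choice,
                outcome=outcome,
                reward_volume=config_prl.reward_volume if outcome else 0.0,
                better_action=better,
            )
        )
        agent.observe(choice, outcome)

        correct = float(choice == better)
        ema = ema + alpha_ema * (correct - ema)
        reverse = False
        if ema > config_prl.threshold:
            eligible_trials += 1
            if rng.random() < config_prl.p_reversal:
                reverse = True
            elif eligible_trials >= config_prl.force_after:
                reverse = True  # forced reversal
        if reverse:
            better = 1 - better
            eligible_trials = 0
            ema = 0.0
            block_id += 1
            block_trial = 0
    return records_to_frame(records)


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"session_id": str})
    df["valid"] = df["valid"].astype(bool)
    return df
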