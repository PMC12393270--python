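"""Model-independent win-stay / lose-shift analyses.

A trial is a win-stay (WS) event if it was rewarded and the next valid trial
of the same session repeats the choice; a lose-shift (LS) event if it was
unrewarded and the next choice differs. Probabilities are micro-averaged:
event counts are pooled across sessions first, then divided (p(WS) = total
WSs / total wins in the trials of interest).

Stratifiers, all taken from the *outcome* trial:

``phase``
    early = first 6 trials after a block transition (block_trial_index <= 6),
    late = 7th trial onward.
``block_type``
    HC / LC / NC contrast.
``action_class``
    better / worse lever by reward probability; ``none`` in NC blocks, which
    are excluded from better/worse strata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

EARLY_PHASE_TRIALS = 6


def classify_events(trials: pd.DataFrame) -> pd.DataFrame:
    """One stay/shift event per valid trial with a valid successor in-session.

    Returns a DataFrame with columns: session_id, trial_index, outcome_class
    (win/loss), stay (bool), phase, block_type, action_class.
    """
    t = trials[trials["valid"]].copy()
    t = t.sort_values(["session_id", "trial_index"], kind="stable")

    next_choice = t.groupby("session_id")["choice"].shift(-1)
    has_next = next_choice.notna()

    events = t.loc[has_next, ["session_id", "trial_index", "block_type"]].copy()
    events["outcome_class"] = np.where(t.loc[has_next, "outcome"] == 1, "win", "loss")
    events["stay"] = (next_choice[has_next] == t.loc[has_next, "choice"]).to_numpy()
    events["phase"] = np.where(
        t.loc[has_next, "block_trial_index"] <= EARLY_PHASE_TRIALS, "early", "late"
    )
    better = t.loc[has_next, "better_action"]
    choice = t.loc[has_next, "choice"]
    events["action_class"] = np.select(
        [better == "none", choice == better],
        ["none", "better"],
        default="worse",
    )
    return events.reset_index(drop=True)


@dataclass
class BehaviorSummary:
    """Stratified WS/LS probabilities with their pooled counts."""

    table: pd.DataFrame  # one row per stratum
    stratify_by: tuple

    def action_difference(self) -> pd.DataFrame:
        """Better-minus-worse WS and LS probabilities within remaining strata."""
        if "action_class" not in self.stratify_by:
            raise ValueError("action difference needs action_class stratification")
        others = [s for s in self.stratify_by if s != "action_class"]
        tab = self.table.set_index(list(self.stratify_by))
        better = tab.xs("better", level="action_class")
        worse = tab.xs("worse", level="action_class")
        diff = pd.DataFrame(
            {
                "ws_diff": better["p_ws"] - worse["p_ws"],
                "ls_diff": better["p_ls"] - worse["p_ls"],
            }
        )
        if not others:
            diff = diff.reset_index(drop=True)
        return diff.reset_index()


def summarize(
    events: pd.DataFrame,
    stratify_by: Sequence[str] = ("phase", "block_type", "action_class"),
) -> BehaviorSummary:
    """Pooled-count WS/LS probabilities per stratum.

    A stratum with zero wins (or losses) reports p_ws (p_ls) as NaN with the
    zero denominator kept in the table.
    """
    strat = list(stratify_by)
    ev = events.copy()
    count_cols = ["n_wins", "n_ws", "p_ws", "n_losses", "n_ls", "p_ls"]
    if len(ev) == 0:
        return BehaviorSummary(
            table=pd.DataFrame(columns=strat + count_cols),
            stratify_by=tuple(stratify_by),
        )
    if not strat:
        ev["_all"] = "all"
        strat = ["_all"]

    def agg(group):
        wins = group["outcome_class"] == "win"
        losses = ~wins
        n_wins = int(wins.sum())
        n_losses = int(losses.sum())
        n_ws = int((wins & group["stay"]).sum())
        n_ls = int((losses & ~group["stay"]).sum())
        return pd.Series(
            {
                "n_wins": n_wins,
                "n_ws": n_ws,
                "p_ws": n_ws / n_wins if n_wins else np.nan,
                "n_losses": n_losses,
                "n_ls": n_ls,
                "p_ls": n_ls / n_losses if n_losses else np.nan,
            }
        )

    table = (
        ev.groupby(strat, observed=True, sort=True)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    if strat == ["_all"]:
        table = table.drop(columns="_all")
    return BehaviorSummary(table=table, stratify_by=tuple(stratify_by))


def overall_ws_ls(trials: pd.DataFrame) -> tuple[float, float]:
    """Overall (p_WS, p_LS) across all valid trials."""
    summary = summarize(classify_events(trials), stratify_by=())
    row = summary.table.iloc[0]
    return float(row["p_ws"]), float(row["p_ls"])


def perseveration_curve(
    trials: pd.DataFrame,
    n_pre: int = 5,
    n_post: int = 12,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Probability of choosing the pre-reversal better lever around transitions.

    For each block transition the reference action is the better lever of the
    *outgoing* block (drawn at random for NC blocks). Offsets run from
    ``-n_pre`` (pre-reversal) to ``n_post`` (post-reversal); offset -1 is the
    last trial before the switch and offset 1 the first after it. Returns a
    DataFrame of (offset, p_perseveration, n_blocks).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    t = trials[trials["valid"]].sort_values(["session_id", "trial_index"], kind="stable")

    hits: dict[int, int] = {k: 0 for k in list(range(-n_pre, 0)) + list(range(1, n_post + 1))}
    counts: dict[int, int] = dict.fromkeys(hits, 0)
    n_transitions = 0

    for _, sess in t.groupby("session_id", sort=False):
        block_ids = sess["block_id"].to_numpy()
        choices = sess["choice"].to_numpy()
        better = sess["better_action"].to_numpy()
        switch_pos = np.flatnonzero(block_ids[1:] != block_ids[:-1]) + 1
        for pos in switch_pos:
            ref = better[pos - 1]
            if ref == "none":
                ref = ("A1", "A2")[rng.integers(2)]
            n_transitions += 1
            for off in hits:
                idx = pos + off if off < 0 else pos + off - 1
                if 0 <= idx < len(choices):
                    # stay within the two blocks flanking this transition
                    if off < 0 and block_ids[idx] != block_ids[pos - 1]:
                        continue
                    if off > 0 and block_ids[idx] != block_ids[pos]:
                        continue
                    counts[off] += 1
                    hits[off] += int(choices[idx] == ref)

    if n_transitions == 0:
        raise ValueError("no block transitions in the trial table")
    offsets = sorted(hits)
    return pd.DataFrame(
        {
            "offset": offsets,
            "p_perseveration": [
                hits[o] / counts[o] if counts[o] else np.nan for o in offsets
            ],
            "n_blocks": [counts[o] for o in offsets],
        }
    )
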