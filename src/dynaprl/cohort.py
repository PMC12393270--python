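"""Ground-truth-known synthetic cohorts and hand-built test fixtures.

A cohort is two groups of simulated subjects playing the dynaPRL task, each
subject's generative parameters drawn from group-level normal distributions;
a between-group delta shifts the group means of chosen parameters in opposite
directions (group A up by delta/2, group B down by delta/2). The table of
true per-subject parameters is returned alongside the trials so downstream
parameter- and group-difference recovery can be scored. A small fraction of
trials is marked invalid — emulating omitted responses — and excluded from
every analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .models import (
    MODEL_REGISTRY,
    GenerativeAgent,
    params_from_vector,
)
from .task import TaskConfig, run_dynaprl_session

# default group-level means: a moderately learning, moderately decisive agent
DEFAULT_MEANS = {
    "standard": {"alpha": 0.35, "beta": 4.0},
    "avgrpe": {"alpha": 0.35, "beta": 4.0, "hw": 0.55},
    "grs": {"alpha": 0.35, "beta": 4.0, "alpha_r": 0.4, "w_r": -0.5},
    "asym5": {
        "alpha_pos": 0.40,
        "alpha_neg": 0.30,
        "gamma_pos": 0.92,
        "gamma_neg": 0.85,
        "beta": 3.5,
    },
}

DEFAULT_SDS = {
    "alpha": 0.05,
    "alpha_pos": 0.04,
    "alpha_neg": 0.04,
    "gamma_pos": 0.03,
    "gamma_neg": 0.03,
    "beta": 0.5,
    "hw": 0.08,
    "alpha_r": 0.08,
    "w_r": 0.15,
}


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a two-group synthetic cohort."""

    model_id: str = "asym5"
    n_subjects_a: int = 9
    n_subjects_b: int = 5
    sessions_per_subject: int = 30
    trials_per_session: int = 300
    means: Mapping[str, float] = None
    sds: Mapping[str, float] = None
    deltas: Mapping[str, float] = field(default_factory=dict)
    invalid_rate: float = 0.005
    seed: int = 0

    def resolved_means(self) -> dict:
        base = dict(DEFAULT_MEANS[self.model_id])
        if self.means:
            base.update(self.means)
        return base

    def resolved_sds(self) -> dict:
        names = MODEL_REGISTRY[self.model_id]["names"]
        base = {n: DEFAULT_SDS[n] for n in names}
        if self.sds:
            base.update(self.sds)
        return base

    def validate(self) -> None:
        names = MODEL_REGISTRY[self.model_id]["names"]
        bounds = dict(zip(names, MODEL_REGISTRY[self.model_id]["bounds"]))
        means = self.resolved_means()
        sds = self.resolved_sds()
        for name, delta in self.deltas.items():
            if name not in names:
                raise ValueError(f"delta for unknown parameter {name!r}")
        for name in names:
            lo, hi = bounds[name]
            for sign in (+0.5, -0.5):
                m = means[name] + sign * self.deltas.get(name, 0.0)
                # ~99% of N(m, sd) draws must fall inside the bounds
                if m - 2.6 * sds[name] < lo or m + 2.6 * sds[name] > hi:
                    raise ValueError(
                        f"group mean {m:.3f} +/- 2.6 sd for {name!r} leaves bounds ({lo}, {hi})"
                    )
        if not 0.0 <= self.invalid_rate < 1.0:
            raise ValueError("invalid_rate must lie in [0, 1)")
        if min(self.n_subjects_a, self.n_subjects_b) < 1:
            raise ValueError("each group needs at least one subject")


def _sample_subject_params(
    spec: CohortSpec, group_sign: float, rng: np.random.Generator
) -> np.ndarray:
    names = MODEL_REGISTRY[spec.model_id]["names"]
    bounds = MODEL_REGISTRY[spec.model_id]["bounds"]
    means = spec.resolved_means()
    sds = spec.resolved_sds()
    out = np.empty(len(names))
    for i, name in enumerate(names):
        m = means[name] + 0.5 * group_sign * spec.deltas.get(name, 0.0)
        lo, hi = bounds[i]
        margin = 1e-3
        out[i] = np.clip(rng.normal(m, sds[name]), lo + margin, hi - margin)
    return out


def generate_cohort(
    spec: CohortSpec,
    task_config: Optional[TaskConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a two-group cohort on the dynaPRL task.

    Returns ``(trials, groups, truth)``: the pooled trial table (with a
    ``subject_id`` column), the subject-to-group map, and the true generative
    parameters per subject. Fully determined by ``spec.seed``.
    """
    spec.validate()
    if task_config is None:
        task_config = TaskConfig()
    rng = np.random.default_rng(spec.seed)
    names = MODEL_REGISTRY[spec.model_id]["names"]

    trial_tables = []
    group_rows = []
    truth_rows = []
    subj_counter = 0
    for group, sign, n_subj in (
        ("A", +1.0, spec.n_subjects_a),
        ("B", -1.0, spec.n_subjects_b),
    ):
        for _ in range(n_subj):
            subject_id = f"{group}{subj_counter:02d}"
            subj_counter += 1
            vec = _sample_subject_params(spec, sign, rng)
            params = params_from_vector(spec.model_id, vec)
            group_rows.append({"subject_id": subject_id, "group": group})
            truth_rows.append(
                {"subject_id": subject_id, "group": group, **dict(zip(names, vec))}
            )
            for s in range(spec.sessions_per_subject):
                agent = GenerativeAgent(params)
                table = run_dynaprl_session(
                    agent,
                    task_config,
                    rng,
                    spec.trials_per_session,
                    session_id=f"{subject_id}_s{s:03d}",
                )
                table.insert(0, "subject_id", subject_id)
                trial_tables.append(table)

    trials = pd.concat(trial_tables, ignore_index=True)
    if spec.invalid_rate > 0:
        invalid = rng.random(len(trials)) < spec.invalid_rate
        trials.loc[invalid, "valid"] = False
    groups = pd.DataFrame(group_rows)
    truth = pd.DataFrame(truth_rows)
    return trials, groups, truth


def trials_by_subject(trials: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a pooled cohort table into per-subject tables (insertion order)."""
    return {str(s): g for s, g in trials.groupby("subject_id", sort=False)}


# ---------------------------------------------------------------------------
# hand-built fixtures
# ---------------------------------------------------------------------------

def _mini_session(
    session_id: str,
    choices: list[str],
    outcomes: list[int],
    block_type: str = "HC",
    better_action: str = "A1",
    valid: Optional[list[bool]] = None,
) -> pd.DataFrame:
    n = len(choices)
    return pd.DataFrame(
        {
            "session_id": session_id,
            "trial_index": np.arange(1, n + 1),
            "block_id": 0,
            "block_type": block_type,
            "block_trial_index": np.arange(1, n + 1),
            "choice": choices,
            "outcome": outcomes,
            "reward_volume": [33.0 * o for o in outcomes],
            "better_action": better_action,
            "valid": valid if valid is not None else [True] * n,
        }
    )


def make_fixtures() -> dict[str, pd.DataFrame]:
    """Tiny hand-built sessions with fully workable expected values.

    * ``wsls4``: choices (A1, A1, A2, A2), outcomes (1, 0, 1, 0) — events are
      win-stay, loss-shift, win-stay; p(WS) = 2/2, p(LS) = 1/1.
    * ``rewards2``: two rewarded A1 presses then one more trial; under the GRS
      model with alpha_r = 0.5 the reward trace runs (0, 0.5, 0.75).
    * ``nll3``: three-trial session for hand-unrolled likelihood traces.
    * ``all_invalid``: a session of omitted responses; every downstream
      computation must treat it as empty rather than crash.
    """
    return {
        "wsls4": _mini_session("fx_wsls", ["A1", "A1", "A2", "A2"], [1, 0, 1, 0]),
        "rewards2": _mini_session("fx_rt", ["A1", "A1", "A1"], [1, 1, 0]),
        "nll3": _mini_session("fx_nll", ["A1", "A2", "A1"], [1, 0, 1]),
        "all_invalid": _mini_session(
            "fx_invalid", ["A1", "A2"], [0, 1], valid=[False, False]
        ),
    }
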