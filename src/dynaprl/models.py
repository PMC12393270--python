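"""The four reinforcement-learning models, in likelihood and generative modes.

Models
------
``standard``
    Delta-rule value learning for the chosen action with learning rate alpha;
    softmax action selection with inverse temperature beta.
``avgrpe``
    The value update is an exponential-like running average of prediction
    errors, avgRPE_t = alpha*RPE_t + hW*avgRPE_{t-1}; its absolute value is the
    trial-by-trial uncertainty proxy. At hW = 0 this reduces exactly to the
    standard model.
``grs``
    A global reward state — an exponential moving average of past binary
    outcomes (the R-trace) — enters the prediction error with weight wR:
    RPE_t = R_t + wR*Rtrace_t - V_t. At wR = 0 this reduces to the standard
    model.
``asym5``
    Five parameters: valence-specific learning rates (alpha_pos after wins,
    alpha_neg after losses) for the chosen action, valence-specific retention
    factors (gamma_pos, gamma_neg) multiplying the unchosen action's value,
    and beta. Decay rates are conventionally reported as 1 - gamma.

Action values are initialized at 0 for both levers at the start of every
session and carried across block transitions within a session.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import _kernels
from .task import TaskConfig, run_dynaprl_session, ACTION_LABELS

BETA_MAX = 20.0
P_FLOOR = _kernels.P_FLOOR

MODEL_IDS = ("standard", "avgrpe", "grs", "asym5")

LATENT_COLUMNS = [
    "V_A1",
    "V_A2",
    "rpe",
    "avg_rpe",
    "abs_avg_rpe",
    "r_trace",
    "p_choice",
]


def _check(name: str, value: float, lo: float, hi: float) -> None:
    if not np.isfinite(value) or not (lo <= value <= hi):
        raise ValueError(f"{name}={value} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class StandardParams:
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        _check("alpha", self.alpha, 0.0, 1.0)
        _check("beta", self.beta, 0.0, BETA_MAX)


@dataclass(frozen=True)
class AvgRPEParams:
    alpha: float
    beta: float
    hw: float

    def __post_init__(self) -> None:
        _check("alpha", self.alpha, 0.0, 1.0)
        _check("beta", self.beta, 0.0, BETA_MAX)
        _check("hw", self.hw, 0.0, 0.75)


@dataclass(frozen=True)
class GRSParams:
    alpha: float
    beta: float
    alpha_r: float
    w_r: float

    def __post_init__(self) -> None:
        _check("alpha", self.alpha, 0.0, 1.0)
        _check("beta", self.beta, 0.0, BETA_MAX)
        _check("alpha_r", self.alpha_r, 0.0, 1.0)
        _check("w_r", self.w_r, -1.0, 1.0)


@dataclass(frozen=True)
class AsymParams:
    alpha_pos: float
    alpha_neg: float
    gamma_pos: float
    gamma_neg: float
    beta: float

    def __post_init__(self) -> None:
        _check("alpha_pos", self.alpha_pos, 0.0, 1.0)
        _check("alpha_neg", self.alpha_neg, 0.0, 1.0)
        _check("gamma_pos", self.gamma_pos, 0.0, 1.0)
        _check("gamma_neg", self.gamma_neg, 0.0, 1.0)
        _check("beta", self.beta, 0.0, BETA_MAX)

    @property
    def decay_pos(self) -> float:
        """Reported decay rate 1 - gamma_pos."""
        return 1.0 - self.gamma_pos

    @property
    def decay_neg(self) -> float:
        return 1.0 - self.gamma_neg


ParamsType = Union[StandardParams, AvgRPEParams, GRSParams, AsymParams]

# model registry: id -> (params class, parameter order, bounds for fitting)
_EPS = 1e-3
MODEL_REGISTRY = {
    "standard": {
        "cls": StandardParams,
        "names": ("alpha", "beta"),
        "bounds": ((_EPS, 1.0 - _EPS), (0.0, BETA_MAX)),
    },
    "avgrpe": {
        "cls": AvgRPEParams,
        "names": ("alpha", "beta", "hw"),
        "bounds": ((_EPS, 1.0 - _EPS), (0.0, BETA_MAX), (0.0, 0.75)),
    },
    "grs": {
        "cls": GRSParams,
        "names": ("alpha", "beta", "alpha_r", "w_r"),
        "bounds": ((_EPS, 1.0 - _EPS), (0.0, BETA_MAX), (0.0, 1.0), (-1.0, 1.0)),
    },
    "asym5": {
        "cls": AsymParams,
        "names": ("alpha_pos", "alpha_neg", "gamma_pos", "gamma_neg", "beta"),
        "bounds": (
            (_EPS, 1.0 - _EPS),
            (_EPS, 1.0 - _EPS),
            (_EPS, 1.0),
            (_EPS, 1.0),
            (0.0, BETA_MAX),
        ),
    },
}


def params_from_vector(model_id: str, vector) -> ParamsType:
    spec = MODEL_REGISTRY[model_id]
    return spec["cls"](**dict(zip(spec["names"], map(float, vector))))


def params_to_vector(params: ParamsType) -> np.ndarray:
    return np.array([getattr(params, f.name) for f in fields(params)], dtype=float)


def model_id_of(params: ParamsType) -> str:
    for mid, spec in MODEL_REGISTRY.items():
        if isinstance(params, spec["cls"]):
            return mid
    raise TypeError(f"unknown parameter type {type(params)!r}")


# ---------------------------------------------------------------------------
# elementary operations (single-trial, used by tests and the generative agent)
# ---------------------------------------------------------------------------

def softmax_choice_prob(values, beta: float) -> np.ndarray:
    """Softmax over a pair of action values; invariant to a shared offset."""
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)) or not np.isfinite(beta):
        raise ValueError("softmax requires finite values and beta")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    x = beta * (v - v.max())
    e = np.exp(x)
    return e / e.sum()


def standard_update(V, choice: int, R: int, alpha: float):
    """One delta-rule step: returns (V', RPE); only the chosen value moves."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    V = np.array(V, dtype=float)
    rpe = R - V[choice]
    V[choice] += alpha * rpe
    return V, rpe


def avg_rpe_update(V, avg_rpe_prev: float, choice: int, R: int, params: AvgRPEParams):
    """RPE-history step: returns (V', avgRPE); V(choice) += avgRPE."""
    V = np.array(V, dtype=float)
    rpe = R - V[choice]
    avg = params.alpha * rpe + params.hw * avg_rpe_prev
    V[choice] += avg
    return V, avg


def grs_update(V, rtrace_prev: float, R_prev: int, choice: int, R: int, params: GRSParams):
    """Reward-trace step: returns (V', Rtrace, RPE)."""
    V = np.array(V, dtype=float)
    rtrace = rtrace_prev + (R_prev - rtrace_prev) * params.alpha_r
    rpe = R + params.w_r * rtrace - V[choice]
    V[choice] += params.alpha * rpe
    return V, rtrace, rpe


def asym_update(V, choice: int, R: int, params: AsymParams):
    """Valence-split step: chosen value learns, unchosen value is retained."""
    V = np.array(V, dtype=float)
    rpe = R - V[choice]
    other = 1 - choice
    if R == 1:
        V[choice] += params.alpha_pos * rpe
        V[other] *= params.gamma_pos
    else:
        V[choice] += params.alpha_neg * rpe
        V[other] *= params.gamma_neg
    return V


# ---------------------------------------------------------------------------
# session-level likelihood
# ---------------------------------------------------------------------------

def encode_session(trials: pd.DataFrame):
    """Valid trials of one session as (choices, rewards) int8 arrays."""
    t = trials[trials["valid"]]
    if len(t) == 0:
        raise ValueError("session has no valid trials")
    if t["session_id"].nunique() != 1:
        raise ValueError("expected trials from a single session")
    choices = (t["choice"].to_numpy() == ACTION_LABELS[1]).astype(np.int8)
    rewards = t["outcome"].to_numpy().astype(np.int8)
    return choices, rewards


def session_negative_log_likelihood(
    trials: pd.DataFrame, model_id: str, params: ParamsType
):
    """Negative log-likelihood of one session plus its latent trace.

    Values are carried forward across block transitions and start at 0.
    Returns ``(nll, latent)`` where ``latent`` is a DataFrame aligned row-for-
    row with the session's valid trials (columns: V_A1, V_A2, rpe, avg_rpe,
    abs_avg_rpe, r_trace, p_choice; fields a model does not define are NaN).
    """
    choices, rewards = encode_session(trials)
    n = len(choices)
    latent = pd.DataFrame(np.nan, index=range(n), columns=LATENT_COLUMNS)

    if model_id == "standard":
        p = params if isinstance(params, StandardParams) else StandardParams(*params)
        nll, V, rpe, pc = _kernels.standard_trace(choices, rewards, p.alpha, p.beta)
    elif model_id == "avgrpe":
        p = params if isinstance(params, AvgRPEParams) else AvgRPEParams(*params)
        nll, V, rpe, avg, pc = _kernels.avgrpe_trace(
            choices, rewards, p.alpha, p.beta, p.hw
        )
        latent["avg_rpe"] = avg
        latent["abs_avg_rpe"] = np.abs(avg)
    elif model_id == "grs":
        p = params if isinstance(params, GRSParams) else GRSParams(*params)
        nll, V, rpe, rtr, pc = _kernels.grs_trace(
            choices, rewards, p.alpha, p.beta, p.alpha_r, p.w_r
        )
        latent["r_trace"] = rtr
    elif model_id == "asym5":
        p = params if isinstance(params, AsymParams) else AsymParams(*params)
        nll, V, rpe, pc = _kernels.asym5_trace(
            choices,
            rewards,
            p.alpha_pos,
            p.alpha_neg,
            p.gamma_pos,
            p.gamma_neg,
            p.beta,
        )
    else:
        raise KeyError(f"unknown model id {model_id!r}")

    latent["V_A1"] = V[:, 0]
    latent["V_A2"] = V[:, 1]
    latent["rpe"] = rpe
    latent["p_choice"] = pc
    return float(nll), latent


def nll_encoded(model_id: str, choices: np.ndarray, rewards: np.ndarray, vector) -> float:
    """nLL of one encoded session at a raw parameter vector (no trace built)."""
    v = vector
    if model_id == "standard":
        return float(_kernels.standard_trace(choices, rewards, v[0], v[1])[0])
    if model_id == "avgrpe":
        return float(_kernels.avgrpe_trace(choices, rewards, v[0], v[1], v[2])[0])
    if model_id == "grs":
        return float(_kernels.grs_trace(choices, rewards, v[0], v[1], v[2], v[3])[0])
    if model_id == "asym5":
        return float(
            _kernels.asym5_trace(choices, rewards, v[0], v[1], v[2], v[3], v[4])[0]
        )
    raise KeyError(f"unknown model id {model_id!r}")


def trials_nll(trials: pd.DataFrame, model_id: str, vector) -> float:
    """nLL of a (possibly multi-session) trial table at a raw parameter vector."""
    total = 0.0
    for _, sess in trials.groupby("session_id", sort=False):
        choices, rewards = encode_session(sess)
        total += nll_encoded(model_id, choices, rewards, vector)
    return total


def compute_latents(trials: pd.DataFrame, model_id: str, params: ParamsType) -> pd.DataFrame:
    """Latent trace for every valid trial of a (multi-session) table.

    Returns the valid-trial rows of ``trials`` with latent columns appended,
    preserving the original index.
    """
    pieces = []
    for _, sess in trials.groupby("session_id", sort=False):
        _, latent = session_negative_log_likelihood(sess, model_id, params)
        valid = sess[sess["valid"]].reset_index()
        out = pd.concat([valid, latent], axis=1).set_index("index")
        pieces.append(out)
    merged = pd.concat(pieces)
    return merged.loc[merged.index.sort_values()]


# ---------------------------------------------------------------------------
# generative mode
# ---------------------------------------------------------------------------

class GenerativeAgent:
    """Plays the task by sampling choices from the model's softmax policy.

    Exposes the ``choose``/``observe`` protocol consumed by the session
    runners in :mod:`dynaprl.task`. Latent state is reset with the agent, so a
    fresh agent per session gives the per-session value reset the likelihood
    assumes.
    """

    def __init__(self, params: ParamsType):
        self.params = params
        self.model_id = model_id_of(params)
        self.reset()

    def reset(self) -> None:
        self.V = np.zeros(2)
        self.avg_rpe = 0.0
        self.r_trace = 0.0
        self.r_prev = 0

    def choose(self, rng: np.random.Generator) -> int:
        p = softmax_choice_prob(self.V, self.params.beta)
        return int(rng.random() < p[1])

    def observe(self, choice: int, outcome: int) -> None:
        p = self.params
        if self.model_id == "standard":
            self.V, _ = standard_update(self.V, choice, outcome, p.alpha)
        elif self.model_id == "avgrpe":
            self.V, self.avg_rpe = avg_rpe_update(self.V, self.avg_rpe, choice, outcome, p)
        elif self.model_id == "grs":
            self.V, self.r_trace, _ = grs_update(
                self.V, self.r_trace, self.r_prev, choice, outcome, p
            )
            # the trace updates from the *previous* outcome; remember this one
            self.r_prev = outcome
        else:
            self.V = asym_update(self.V, choice, outcome, p)


def simulate_agent(
    model_id: str,
    params: ParamsType,
    env: TaskConfig,
    n_sessions: int,
    trials_per_session: int,
    rng: np.random.Generator,
    session_prefix: str = "S",
) -> pd.DataFrame:
    """Simulate ``n_sessions`` dynaPRL sessions under the model's policy."""
    if model_id_of(params) != model_id:
        raise ValueError("params do not match model_id")
    tables = []
    for s in range(n_sessions):
        agent = GenerativeAgent(params)
        tables.append(
            run_dynaprl_session(
                agent, env, rng, trials_per_session, session_id=f"{session_prefix}{s:03d}"
            )
        )
    return pd.concat(tables, ignore_index=True)
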