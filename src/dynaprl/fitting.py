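"""Per-session maximum-likelihood fitting and BIC model comparison.

Each session is fit independently with a bounded local optimizer started from
``n_restarts`` random points inside the parameter bounds; the restart with the
lowest negative log-likelihood wins. Session fits are summarized per subject
by mean BIC; the natural-log BIC convention is used throughout:

    BIC = 2*nLL + nParams*ln(nObs)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .models import (
    MODEL_REGISTRY,
    encode_session,
    nll_encoded,
    params_from_vector,
)

MIN_VALID_TRIALS = 20


@dataclass
class FitResult:
    model_id: str
    params: dict
    nll: float
    n_obs: int
    n_params: int
    bic: float
    n_restarts: int
    converged: bool
    seed: int
    session_id: Optional[str] = None

    @property
    def vector(self) -> np.ndarray:
        names = MODEL_REGISTRY[self.model_id]["names"]
        return np.array([self.params[n] for n in names])


def bic(nll: float, n_params: int, n_obs: int) -> float:
    """Bayesian Information Criterion, natural-log convention."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return 2.0 * nll + n_params * np.log(n_obs)


def fit_session(
    trials: pd.DataFrame,
    model_id: str,
    n_restarts: int = 10,
    seed: int = 0,
    min_valid_trials: int = MIN_VALID_TRIALS,
) -> FitResult:
    """Fit one session by multi-restart bounded MLE.

    Deterministic given ``seed``: restart initial points are drawn uniformly
    within bounds from a generator seeded with it. L-BFGS-B is tried first;
    a bounded Powell search is the gradient-free fallback when it fails.
    """
    spec = MODEL_REGISTRY[model_id]
    bounds = spec["bounds"]
    names = spec["names"]
    valid = trials[trials["valid"]]
    n_obs = len(valid)
    if n_obs < min_valid_trials:
        raise ValueError(
            f"session has {n_obs} valid trials; need >= {min_valid_trials}"
        )
    session_ids = valid["session_id"].unique()
    session_id = session_ids[0] if len(session_ids) == 1 else None

    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    # encode once; the optimizer loop then runs on compiled kernels only
    encoded = [encode_session(sess) for _, sess in valid.groupby("session_id", sort=False)]

    def objective(x):
        xc = np.clip(x, lo, hi)
        return sum(nll_encoded(model_id, c, r, xc) for c, r in encoded)

    best_x = None
    best_nll = np.inf
    any_converged = False
    for _ in range(n_restarts):
        x0 = rng.uniform(lo, hi)
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        if not res.success:
            res = minimize(objective, x0, method="Powell", bounds=bounds)
        if res.success:
            any_converged = True
        if res.fun < best_nll:
            best_nll = float(res.fun)
            best_x = np.clip(res.x, lo, hi)

    if best_x is None:  # pragma: no cover - optimizer always returns a point
        raise RuntimeError("all restarts failed")

    return FitResult(
        model_id=model_id,
        params=dict(zip(names, map(float, best_x))),
        nll=best_nll,
        n_obs=n_obs,
        n_params=len(names),
        bic=float(bic(best_nll, len(names), n_obs)),
        n_restarts=n_restarts,
        converged=any_converged,
        seed=seed,
        session_id=session_id,
    )


def fit_sessions(
    trials: pd.DataFrame,
    model_id: str,
    n_restarts: int = 10,
    seed: int = 0,
) -> list[FitResult]:
    """Fit every session in a trial table; seeds are derived per session."""
    results = []
    for i, (sid, sess) in enumerate(trials.groupby("session_id", sort=False)):
        results.append(
            fit_session(sess, model_id, n_restarts=n_restarts, seed=seed + 7919 * i)
        )
    return results


def fits_to_frame(fits: Sequence[FitResult]) -> pd.DataFrame:
    rows = []
    for f in fits:
        row = {
            "session_id": f.session_id,
            "model_id": f.model_id,
            "nll": f.nll,
            "n_obs": f.n_obs,
            "n_params": f.n_params,
            "bic": f.bic,
            "converged": f.converged,
        }
        row.update(f.params)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_models(
    trials_by_session: pd.DataFrame,
    model_ids: Sequence[str],
    n_restarts: int = 10,
    seed: int = 0,
) -> dict:
    """Session-level BIC comparison across models.

    Returns a dict with a per-session BIC table (wide, one column per model),
    mean and summed BIC per model, and — when at least two models are given —
    per-session winners with a parsimony tie-break (fewer parameters wins).
    """
    per_model = {}
    for m in model_ids:
        fits = fit_sessions(trials_by_session, m, n_restarts=n_restarts, seed=seed)
        per_model[m] = {f.session_id: f.bic for f in fits}
    table = pd.DataFrame(per_model)
    table.index.name = "session_id"

    out = {
        "bic_by_session": table,
        "mean_bic": table.mean(axis=0),
        "sum_bic": table.sum(axis=0),
    }
    if len(model_ids) >= 2:
        n_params = {m: len(MODEL_REGISTRY[m]["names"]) for m in model_ids}

        def winner(row):
            best = row.min()
            tied = [m for m in row.index if np.isclose(row[m], best)]
            return min(tied, key=lambda m: n_params[m])

        winners = table.apply(winner, axis=1)
        out["winner_by_session"] = winners
        out["winner_counts"] = winners.value_counts()
        out["overall_winner"] = out["mean_bic"].idxmin()
    return out
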