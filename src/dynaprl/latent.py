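"""Trial-by-trial latent-state analyses of stay/shift behavior.

All analyses operate on a merged table — the valid trials of a session with
model-derived latent columns attached (see
:func:`dynaprl.models.compute_latents`) — and relate the stay/shift decision
after each win or loss to a latent quantity via binomial logistic regression
on the z-scored predictor. The regression coefficient (log-odds slope) is the
"correlation" reported throughout.

Three analyses:

* :func:`k_sweep` — blend the current and previous trials' prediction errors
  as wRPE_t = k*RPE_t + (1-k)*RPE_{t-1} over a grid of k in [0.5, 1], and find
  the k whose wRPE correlates most strongly with WS and with LS decisions.
* :func:`latent_choice_correlation` — per-stratum slope of WS (or LS) on the
  unsigned avgRPE (uncertainty proxy) or the reward trace (GRS).
* :func:`median_split_interaction` — p(WS) in the four cells of a 2x2 median
  split on GRS and |avgRPE|.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .behavior import EARLY_PHASE_TRIALS

K_GRID = np.round(np.arange(0.5, 1.0 + 1e-9, 0.025), 3)
MIN_EVENTS = 30
MIN_CELL_TRIALS = 10


def weighted_rpe(rpe_t, rpe_prev, k: float):
    """Blend of current and previous prediction errors, weight k on current."""
    if not 0.5 <= k <= 1.0:
        raise ValueError("k must lie in [0.5, 1]")
    return k * np.asarray(rpe_t) + (1.0 - k) * np.asarray(rpe_prev)


def zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("constant predictor cannot be z-scored")
    return (x - x.mean()) / sd


def logistic_slope(y: np.ndarray, x: np.ndarray) -> float:
    """Log-odds slope of binary y on z-scored x; NaN when degenerate."""
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        return np.nan
    try:
        xz = zscore(x)
    except ValueError:
        return np.nan
    X = sm.add_constant(xz)
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
    except Exception:
        return np.nan
    coef = float(res.params[1])
    return coef if np.isfinite(coef) else np.nan


def stay_events(df: pd.DataFrame) -> pd.DataFrame:
    """Per-trial stay/shift events with latent columns and previous-trial RPE.

    ``df`` must be a merged trials+latent table (valid trials only). Adds
    ``stay``, ``rpe_prev`` (0 on a session's first trial), ``phase`` and
    ``action_class``; keeps only trials with a successor in the same session.
    """
    t = df.sort_values(["session_id", "trial_index"], kind="stable").copy()
    grp = t.groupby("session_id")
    next_choice = grp["choice"].shift(-1)
    t["stay"] = (next_choice == t["choice"]).where(next_choice.notna())
    if "rpe" in t.columns:
        t["rpe_prev"] = grp["rpe"].shift(1, fill_value=0.0)
    t["phase"] = np.where(t["block_trial_index"] <= EARLY_PHASE_TRIALS, "early", "late")
    t["action_class"] = np.select(
        [t["better_action"] == "none", t["choice"] == t["better_action"]],
        ["none", "better"],
        default="worse",
    )
    out = t[next_choice.notna()].copy()
    out["stay"] = out["stay"].astype(bool)
    return out


@dataclass
class KSweepResult:
    k_grid: np.ndarray
    coef_ws: np.ndarray
    coef_ls: np.ndarray
    best_k_ws: float
    best_k_ls: float
    n_ws: int
    n_ls: int
    flagged_ws: bool
    flagged_ls: bool


def _sweep_class(events: pd.DataFrame, indicator: np.ndarray) -> tuple[np.ndarray, float, bool]:
    n = len(events)
    coefs = np.full(len(K_GRID), np.nan)
    if n < MIN_EVENTS:
        return coefs, np.nan, True
    rpe = events["rpe"].to_numpy()
    rpe_prev = events["rpe_prev"].to_numpy()
    for i, k in enumerate(K_GRID):
        coefs[i] = logistic_slope(indicator, weighted_rpe(rpe, rpe_prev, k))
    if np.all(np.isnan(coefs)):
        return coefs, np.nan, True
    best = float(K_GRID[np.nanargmax(np.abs(coefs))])
    return coefs, best, False


def k_sweep(df: pd.DataFrame) -> KSweepResult:
    """Sweep k over [0.5, 1] (step 0.025) for WS and LS separately.

    ``df`` is a merged trials+latent table carrying the standard-RL ``rpe``
    column. WS: stay indicator among win trials; LS: shift indicator among
    loss trials. The reported best k maximizes |slope|.
    """
    ev = stay_events(df)
    wins = ev[ev["outcome"] == 1]
    losses = ev[ev["outcome"] == 0]
    coef_ws, best_ws, flag_ws = _sweep_class(wins, wins["stay"].to_numpy(dtype=float))
    coef_ls, best_ls, flag_ls = _sweep_class(
        losses, (~losses["stay"]).to_numpy(dtype=float)
    )
    return KSweepResult(
        k_grid=K_GRID.copy(),
        coef_ws=coef_ws,
        coef_ls=coef_ls,
        best_k_ws=best_ws,
        best_k_ls=best_ls,
        n_ws=len(wins),
        n_ls=len(losses),
        flagged_ws=flag_ws,
        flagged_ls=flag_ls,
    )


def latent_choice_correlation(
    df: pd.DataFrame,
    predictor: str,
    outcome: str,
    strata: Sequence[str] = ("block_type",),
    restrict_better_late: bool = True,
) -> pd.DataFrame:
    """Logistic slope of WS (or LS) on a z-scored latent predictor, per stratum.

    ``predictor`` is a latent column (``abs_avg_rpe`` for the uncertainty
    proxy, ``r_trace`` for the GRS); ``outcome`` is ``"WS"`` or ``"LS"``. By
    default the analysis is restricted to better-action trials in the late
    phase, the regime where the asymmetric win/loss weighting operates.
    Degenerate strata (constant predictor, or all-stay/all-shift) report a NaN
    coefficient rather than failing.
    """
    if outcome not in ("WS", "LS"):
        raise ValueError("outcome must be 'WS' or 'LS'")
    ev = stay_events(df)
    if restrict_better_late:
        ev = ev[(ev["phase"] == "late") & (ev["action_class"] == "better")]
    ev = ev[ev["outcome"] == (1 if outcome == "WS" else 0)]

    rows = []
    keys = list(strata) if strata else []
    groups = ev.groupby(keys, observed=True) if keys else [((), ev)]
    for key, g in groups:
        if keys and not isinstance(key, tuple):
            key = (key,)
        indicator = g["stay"] if outcome == "WS" else ~g["stay"]
        coef = logistic_slope(indicator.to_numpy(dtype=float), g[predictor].to_numpy())
        rows.append(
            dict(zip(keys, key))
            | {"outcome": outcome, "predictor": predictor, "coef": coef, "n": len(g)}
        )
    return pd.DataFrame(rows)


def median_split_interaction(
    df: pd.DataFrame,
    strata: Sequence[str] = ("block_type",),
) -> pd.DataFrame:
    """p(WS) in the 2x2 median split of GRS and |avgRPE|.

    Uses better-action, late-phase win trials. Medians are computed within
    each stratum over the analyzed trials; values at or below the median are
    "low" (ties go low, deterministically). Cells with fewer than 10 trials
    are flagged ``low_n``.
    """
    for col in ("r_trace", "abs_avg_rpe"):
        if col not in df.columns:
            raise ValueError(f"merged table must carry {col!r}")
    ev = stay_events(df)
    ev = ev[
        (ev["phase"] == "late") & (ev["action_class"] == "better") & (ev["outcome"] == 1)
    ]

    rows = []
    keys = list(strata) if strata else []
    groups = ev.groupby(keys, observed=True) if keys else [((), ev)]
    for key, g in groups:
        if keys and not isinstance(key, tuple):
            key = (key,)
        med_grs = g["r_trace"].median()
        med_unc = g["abs_avg_rpe"].median()
        hi_grs = g["r_trace"] > med_grs
        hi_unc = g["abs_avg_rpe"] > med_unc
        for grs_level, grs_mask in (("high", hi_grs), ("low", ~hi_grs)):
            for unc_level, unc_mask in (("high", hi_unc), ("low", ~hi_unc)):
                cell = g[grs_mask & unc_mask]
                n = len(cell)
                rows.append(
                    dict(zip(keys, key))
                    | {
                        "grs": grs_level,
                        "abs_avg_rpe": unc_level,
                        "p_ws": cell["stay"].mean() if n else np.nan,
                        "n": n,
                        "low_n": n < MIN_CELL_TRIALS,
                    }
                )
    return pd.DataFrame(rows)
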