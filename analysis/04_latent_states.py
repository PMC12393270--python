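#!/usr/bin/env python
"""Trial-by-trial latent-state analyses on the simulated cohort.

Per session, fits the standard RL model (for RPEs), the avgRPE model (for the
unsigned-avgRPE uncertainty proxy) and the GRS model (for the reward trace),
attaches the latent traces to the trials, and runs:

* the k-sweep — how much weight the previous trial's RPE carries in WS/LS
  decisions;
* logistic regressions of WS and LS on |avgRPE| and on the GRS, for better
  actions in the late phase, per block type;
* the 2x2 GRS x |avgRPE| median-split of p(WS).
"""

import argparse
from pathlib import Path

import pandas as pd

from dynaprl import latent
from dynaprl.fitting import fit_session
from dynaprl.models import LATENT_COLUMNS, compute_latents, params_from_vector
from dynaprl.task import read_trials_csv


def merged_latents(trials, seed: int, restarts: int) -> pd.DataFrame:
    parts = []
    for _, sess in trials.groupby("session_id", sort=False):
        part = None
        for model_id, cols in (
            ("standard", ["rpe"]),
            ("avgrpe", ["abs_avg_rpe"]),
            ("grs", ["r_trace"]),
        ):
            f = fit_session(sess, model_id, n_restarts=restarts, seed=seed)
            lat = compute_latents(sess, model_id, params_from_vector(model_id, f.vector))
            if part is None:
                part = lat.drop(columns=[c for c in LATENT_COLUMNS if c not in cols])
            else:
                part[cols] = lat[cols]
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--restarts", type=int, default=5)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/latent"))
    args = ap.parse_args()

    trials = read_trials_csv(args.cohort / "trials.csv")
    merged = merged_latents(trials, args.seed, args.restarts)
    args.out.mkdir(parents=True, exist_ok=True)

    ks = latent.k_sweep(merged)
    pd.DataFrame({"k": ks.k_grid, "coef_ws": ks.coef_ws, "coef_ls": ks.coef_ls}).to_csv(
        args.out / "ksweep.csv", index=False
    )
    print(f"k-sweep: best k (WS) = {ks.best_k_ws}, best k (LS) = {ks.best_k_ls} "
          f"(1.0 = only the current trial's RPE matters)")

    rows = []
    for predictor in ("abs_avg_rpe", "r_trace"):
        for outcome in ("WS", "LS"):
            rows.append(latent.latent_choice_correlation(merged, predictor, outcome))
    corr = pd.concat(rows, ignore_index=True)
    corr.to_csv(args.out / "latent_correlations.csv", index=False)
    print("\nlogistic slopes (better actions, late phase):")
    print(corr.round(3).to_string(index=False))

    cells = latent.median_split_interaction(merged)
    cells.to_csv(args.out / "median_split.csv", index=False)
    print("\nGRS x |avgRPE| median-split p(WS):")
    print(cells.round(3).to_string(index=False))
    print(f"\ntables -> {args.out}")


if __name__ == "__main__":
    main()
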