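#!/usr/bin/env python
"""Hierarchical two-group comparison of the asymmetric five-parameter model.

Fits both groups jointly: each subject's parameters are drawn from group-level
distributions (mean mu +/- delta/2, SD sigma, on an unconstrained scale) and
the directed Bayes Factor quantifies the posterior evidence that a parameter
is higher in group A. Compare the dBFs against the generative deltas written
by 01_simulate_cohort.py.
"""

import argparse
from pathlib import Path

import pandas as pd

from dynaprl.cohort import trials_by_subject
from dynaprl.hierarchical import MCMCConfig, fit_hierarchical
from dynaprl.task import read_trials_csv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--draws", type=int, default=1000)
    ap.add_argument("--warmup", type=int, default=500)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/hierarchical"))
    args = ap.parse_args()

    trials = read_trials_csv(args.cohort / "trials.csv")
    groups = pd.read_csv(args.cohort / "groups.csv", dtype=str)
    res = fit_hierarchical(
        trials_by_subject(trials),
        dict(zip(groups["subject_id"], groups["group"])),
        MCMCConfig(n_draws=args.draws, n_warmup=args.warmup, seed=args.seed),
    )

    args.out.mkdir(parents=True, exist_ok=True)
    summary = res.summary()
    summary.to_csv(args.out / "group_posterior.csv", index=False)
    res.subject_means.to_csv(args.out / "subject_means.csv", index=False)

    print(f"groups: {res.group_order[0]} (+delta/2) vs {res.group_order[1]} (-delta/2); "
          f"{res.n_draws} draws; converged = {res.converged}")
    print(summary.round(3).to_string(index=False))
    print("\ndBF > 1 favors group A higher; > 3 is the conventional moderate-"
          "evidence cutoff. Expect alpha_pos and alpha_neg above 1 and "
          "gamma_neg below 1 for the cohort simulated by 01.")
    print(f"\ntables -> {args.out}")


if __name__ == "__main__":
    main()
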