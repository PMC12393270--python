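"""Two-group hierarchical Bayesian fitting of the asymmetric five-parameter model.

Each subject's five parameters (alpha_pos, alpha_neg, gamma_pos, gamma_neg,
beta) are drawn, on an unconstrained scale, from group-level normal
distributions with mean mu +/- delta/2 (group A gets +delta/2, group B
-delta/2) and standard deviation sigma, then mapped to their bounds by a
logistic transform (beta to (0, beta_max) by a scaled logistic). Priors on
the unconstrained scale: mu ~ N(0, 1), delta ~ N(0, 0.5), sigma ~
half-N(0.5), one (mu, delta, sigma) triple per parameter.

Sampling is Metropolis-within-Gibbs (compiled): exact bivariate-normal Gibbs
draws for (mu, delta), slice updates for sigma, and adaptive random-walk
Metropolis on each subject-level parameter, run as independent chains whose
agreement is summarized by split R-hat. The directed Bayes Factor (dBF) for
a parameter is the ratio of posterior mass of delta above zero to the mass
below zero — values above 1 mean group A sits higher.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit

from ._kernels import hier_gibbs_chain
from .models import BETA_MAX, encode_session

PARAM_NAMES = ("alpha_pos", "alpha_neg", "gamma_pos", "gamma_neg", "beta")
N_PAR = 5


@dataclass(frozen=True)
class MCMCConfig:
    """Desk-scale MCMC settings: 2 chains of 1,000 kept sweeps after 500 warm-up."""

    n_chains: int = 2
    n_draws: int = 1000
    n_warmup: int = 500
    seed: int = 0
    mu_prior_sd: float = 1.0
    delta_prior_sd: float = 0.5
    sigma_prior_sd: float = 0.5
    beta_max: float = BETA_MAX
    rhat_threshold: float = 1.05


@dataclass
class GroupPosterior:
    """Posterior summary for one model parameter's group structure."""

    name: str
    mu_draws: np.ndarray
    delta_draws: np.ndarray
    sigma_draws: np.ndarray
    dbf: float
    hdi_80: tuple
    hdi_95: tuple
    rhat: float


@dataclass
class HierarchicalResult:
    posteriors: dict
    group_order: tuple
    subject_ids: tuple
    subject_means: pd.DataFrame  # posterior-mean parameters per subject, natural scale
    converged: bool
    n_draws: int
    config: MCMCConfig

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, gp in self.posteriors.items():
            rows.append(
                {
                    "parameter": name,
                    "delta_mean": gp.delta_draws.mean(),
                    "dbf": gp.dbf,
                    "hdi80_lo": gp.hdi_80[0],
                    "hdi80_hi": gp.hdi_80[1],
                    "hdi95_lo": gp.hdi_95[0],
                    "hdi95_hi": gp.hdi_95[1],
                    "rhat": gp.rhat,
                }
            )
        return pd.DataFrame(rows)


def directed_bayes_factor(delta_draws: np.ndarray, min_draws: int = 1000) -> float:
    """Ratio of posterior mass above zero to mass below zero.

    With all draws on one side the ratio is capped at the number of draws
    (never infinite); draws exactly at zero are ignored.
    """
    d = np.asarray(delta_draws, dtype=float)
    n = d.size
    if n < min_draws:
        raise ValueError(f"need >= {min_draws} draws, got {n}")
    n_pos = int((d > 0).sum())
    n_neg = int((d < 0).sum())
    if n_neg == 0:
        return float(n)
    if n_pos == 0:
        return 1.0 / float(n)
    return n_pos / n_neg


def _prepare_data(trials_by_subject: Mapping[str, pd.DataFrame], group_labels: Mapping[str, str]):
    subject_ids = tuple(trials_by_subject.keys())
    groups = [group_labels[s] for s in subject_ids]
    order = []
    for g in groups:
        if g not in order:
            order.append(g)
    if len(order) != 2:
        raise ValueError(f"need exactly two groups, got {order}")
    counts = pd.Series(groups).value_counts()
    if counts.min() < 2:
        raise ValueError("each group needs at least two subjects")
    signs = np.array([1.0 if g == order[0] else -1.0 for g in groups])

    choices_all, rewards_all = [], []
    subj_starts = [0]
    sess_starts = [0]
    for sid in subject_ids:
        trials = trials_by_subject[sid]
        n_sessions = 0
        for _, sess in trials.groupby("session_id", sort=False):
            c, r = encode_session(sess)
            choices_all.append(c)
            rewards_all.append(r)
            sess_starts.append(sess_starts[-1] + len(c))
            n_sessions += 1
        subj_starts.append(subj_starts[-1] + n_sessions)

    return (
        subject_ids,
        tuple(order),
        signs,
        np.concatenate(choices_all).astype(np.int8),
        np.concatenate(rewards_all).astype(np.int8),
        np.array(subj_starts, dtype=np.int64),
        np.array(sess_starts, dtype=np.int64),
    )


def fit_hierarchical(
    trials_by_subject: Mapping[str, pd.DataFrame],
    group_labels: Mapping[str, str],
    config: MCMCConfig = MCMCConfig(),
) -> HierarchicalResult:
    """Sample the two-group hierarchical posterior of the asym5 model.

    ``trials_by_subject`` maps subject id to that subject's trial table (one
    or more sessions); ``group_labels`` maps subject id to its group. Group A
    (the first label encountered) takes +delta/2. Deterministic for a fixed
    config seed. Non-convergence (any hyperparameter split R-hat above the
    threshold) flags the result via ``converged`` rather than raising.
    """
    (
        subject_ids,
        group_order,
        signs,
        choices,
        rewards,
        subj_starts,
        sess_starts,
    ) = _prepare_data(trials_by_subject, group_labels)

    n_subj = len(subject_ids)
    hyper_chains = []
    u_chains = []
    for c in range(config.n_chains):
        hyper, u = hier_gibbs_chain(
            choices,
            rewards,
            subj_starts,
            sess_starts,
            signs,
            config.mu_prior_sd,
            config.delta_prior_sd,
            config.sigma_prior_sd,
            config.beta_max,
            config.n_warmup,
            config.n_draws,
            (config.seed * 1000003 + 7919 * c) % (2**31 - 1),
        )
        hyper_chains.append(hyper)
        u_chains.append(u)
    hyper = np.stack(hyper_chains)  # (chains, draws, 15)
    u_all = np.stack(u_chains)  # (chains, draws, n_subj*5)
    n_draws = config.n_chains * config.n_draws

    posteriors = {}
    max_rhat = 0.0
    for p, name in enumerate(PARAM_NAMES):
        mu = hyper[:, :, p].ravel()
        delta_chains = hyper[:, :, N_PAR + p]
        delta = delta_chains.ravel()
        sigma = hyper[:, :, 2 * N_PAR + p].ravel()
        rhat = float(az.rhat(az.convert_to_dataset(delta_chains))["x"].values)
        max_rhat = max(max_rhat, rhat)
        hdi80 = az.hdi(delta, hdi_prob=0.80)
        hdi95 = az.hdi(delta, hdi_prob=0.95)
        posteriors[name] = GroupPosterior(
            name=name,
            mu_draws=mu,
            delta_draws=delta,
            sigma_draws=sigma,
            dbf=directed_bayes_factor(delta, min_draws=min(1000, n_draws)),
            hdi_80=(float(hdi80[0]), float(hdi80[1])),
            hdi_95=(float(hdi95[0]), float(hdi95[1])),
            rhat=rhat,
        )

    # subject-level posterior means on the natural scale
    flat_u = u_all.reshape(n_draws, n_subj * N_PAR)
    subj_rows = []
    for j, sid in enumerate(subject_ids):
        row = {"subject_id": sid, "group": group_labels[sid]}
        for p, name in enumerate(PARAM_NAMES):
            v = expit(flat_u[:, j * N_PAR + p])
            if name == "beta":
                v = config.beta_max * v
            row[name] = float(v.mean())
        subj_rows.append(row)

    return HierarchicalResult(
        posteriors=posteriors,
        group_order=group_order,
        subject_ids=subject_ids,
        subject_means=pd.DataFrame(subj_rows),
        converged=max_rhat < config.rhat_threshold,
        n_draws=n_draws,
        config=config,
    )
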