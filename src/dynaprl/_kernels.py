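"""Compiled inner loops for model likelihoods and latent traces.

Each ``*_trace`` kernel walks one session chronologically, carrying action
values across block transitions, and returns the full latent trace plus the
summed negative log-likelihood of the observed choices. Choices are 0/1,
rewards 0/1. A floor keeps log probabilities finite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

P_FLOOR = 1e-9


@njit(cache=True)
def _softmax_p(v_c, v_o, beta):
    # probability of the chosen action under a two-action softmax
    x = beta * (v_c - v_o)
    if x > 35.0:
        p = 1.0
    elif x < -35.0:
        p = 0.0
    else:
        p = 1.0 / (1.0 + np.exp(-x))
    if p < P_FLOOR:
        p = P_FLOOR
    elif p > 1.0 - P_FLOOR:
        p = 1.0 - P_FLOOR
    return p


@njit(cache=True)
def standard_trace(choices, rewards, alpha, beta):
    """Delta-rule value learning; returns (nll, V, rpe, p_choice)."""
    n = choices.shape[0]
    V = np.zeros((n, 2))
    rpe = np.zeros(n)
    p_choice = np.zeros(n)
    v0 = 0.0
    v1 = 0.0
    nll = 0.0
    for t in range(n):
        V[t, 0] = v0
        V[t, 1] = v1
        c = choices[t]
        vc = v0 if c == 0 else v1
        vo = v1 if c == 0 else v0
        p = _softmax_p(vc, vo, beta)
        p_choice[t] = p
        nll -= np.log(p)
        e = rewards[t] - vc
        rpe[t] = e
        if c == 0:
            v0 += alpha * e
        else:
            v1 += alpha * e
    return nll, V, rpe, p_choice


@njit(cache=True)
def avgrpe_trace(choices, rewards, alpha, beta, hw):
    """RPE-history model: avgRPE_t = alpha*RPE_t + hW*avgRPE_{t-1} updates V directly."""
    n = choices.shape[0]
    V = np.zeros((n, 2))
    rpe = np.zeros(n)
    avg = np.zeros(n)
    p_choice = np.zeros(n)
    v0 = 0.0
    v1 = 0.0
    a_prev = 0.0
    nll = 0.0
    for t in range(n):
        V[t, 0] = v0
        V[t, 1] = v1
        c = choices[t]
        vc = v0 if c == 0 else v1
        vo = v1 if c == 0 else v0
        p = _softmax_p(vc, vo, beta)
        p_choice[t] = p
        nll -= np.log(p)
        e = rewards[t] - vc
        rpe[t] = e
        a = alpha * e + hw * a_prev
        avg[t] = a
        if c == 0:
            v0 += a
        else:
            v1 += a
        a_prev = a
    return nll, V, rpe, avg, p_choice


@njit(cache=True)
def grs_trace(choices, rewards, alpha, beta, alphar, wr):
    """Global-reward-state model: reward trace biases the prediction error."""
    n = choices.shape[0]
    V = np.zeros((n, 2))
    rpe = np.zeros(n)
    rtrace = np.zeros(n)
    p_choice = np.zeros(n)
    v0 = 0.0
    v1 = 0.0
    tr = 0.0
    r_prev = 0.0
    nll = 0.0
    for t in range(n):
        if t > 0:
            tr = tr + (r_prev - tr) * alphar
        rtrace[t] = tr
        V[t, 0] = v0
        V[t, 1] = v1
        c = choices[t]
        vc = v0 if c == 0 else v1
        vo = v1 if c == 0 else v0
        p = _softmax_p(vc, vo, beta)
        p_choice[t] = p
        nll -= np.log(p)
        e = rewards[t] + wr * tr - vc
        rpe[t] = e
        if c == 0:
            v0 += alpha * e
        else:
            v1 += alpha * e
        r_prev = rewards[t]
    return nll, V, rpe, rtrace, p_choice


@njit(cache=True)
def asym5_trace(choices, rewards, a_pos, a_neg, g_pos, g_neg, beta):
    """Valence-split learning rates for the chosen action, valence-split
    multiplicative retention of the unchosen action's value."""
    n = choices.shape[0]
    V = np.zeros((n, 2))
    rpe = np.zeros(n)
    p_choice = np.zeros(n)
    v0 = 0.0
    v1 = 0.0
    nll = 0.0
    for t in range(n):
        V[t, 0] = v0
        V[t, 1] = v1
        c = choices[t]
        vc = v0 if c == 0 else v1
        vo = v1 if c == 0 else v0
        p = _softmax_p(vc, vo, beta)
        p_choice[t] = p
        nll -= np.log(p)
        r = rewards[t]
        e = r - vc
        rpe[t] = e
        if r == 1:
            vc_new = vc + a_pos * e
            vo_new = vo * g_pos
        else:
            vc_new = vc + a_neg * e
            vo_new = vo * g_neg
        if c == 0:
            v0 = vc_new
            v1 = vo_new
        else:
            v1 = vc_new
            v0 = vo_new
    return nll, V, rpe, p_choice


@njit(cache=True)
def asym5_nll_sessions(choices, rewards, starts, a_pos, a_neg, g_pos, g_neg, beta):
    """Summed asym5 nLL over concatenated sessions (values reset per session).

    ``starts`` has length n_sessions+1 with slice boundaries into the flat
    choice/reward arrays.
    """
    nll = 0.0
    for s in range(starts.shape[0] - 1):
        v0 = 0.0
        v1 = 0.0
        for t in range(starts[s], starts[s + 1]):
            c = choices[t]
            vc = v0 if c == 0 else v1
            vo = v1 if c == 0 else v0
            nll -= np.log(_softmax_p(vc, vo, beta))
            r = rewards[t]
            e = r - vc
            if r == 1:
                vc_new = vc + a_pos * e
                vo_new = vo * g_pos
            else:
                vc_new = vc + a_neg * e
                vo_new = vo * g_neg
            if c == 0:
                v0 = vc_new
                v1 = vo_new
            else:
                v1 = vc_new
                v0 = vo_new
    return nll


@njit(cache=True)
def subject_loglik(choices, rewards, sess_starts, s_lo, s_hi, ap, an, gp, gn, bb):
    """asym5 log-likelihood of one subject's sessions (values reset per session)."""
    ll = 0.0
    for s in range(s_lo, s_hi):
        v0 = 0.0
        v1 = 0.0
        for t in range(sess_starts[s], sess_starts[s + 1]):
            c = choices[t]
            vc = v0 if c == 0 else v1
            vo = v1 if c == 0 else v0
            ll += np.log(_softmax_p(vc, vo, bb))
            r = rewards[t]
            e = r - vc
            if r == 1:
                vc_new = vc + ap * e
                vo_new = vo * gp
            else:
                vc_new = vc + an * e
                vo_new = vo * gn
            if c == 0:
                v0 = vc_new
                v1 = vo_new
            else:
                v1 = vc_new
                v0 = vo_new
    return ll


@njit(cache=True)
def _expit(u):
    if u > 35.0:
        return 1.0
    if u < -35.0:
        return 0.0
    return 1.0 / (1.0 + np.exp(-u))


@njit(cache=True)
def _subject_ll_from_u(choices, rewards, sess_starts, s_lo, s_hi, u, beta_max):
    ap = _expit(u[0])
    an = _expit(u[1])
    gp = _expit(u[2])
    gn = _expit(u[3])
    bb = beta_max * _expit(u[4])
    return subject_loglik(choices, rewards, sess_starts, s_lo, s_hi, ap, an, gp, gn, bb)


@njit(cache=True)
def _slice_sample_log_sigma(lam0, n, ss, prior_sd):
    """One slice-sampling update of lambda = log(sigma).

    Target: -n*lam - ss*exp(-2lam)/2 - exp(2lam)/(2 prior_sd^2) + lam
    (half-normal prior on sigma with the log-scale Jacobian).
    """

    def f(lam):
        return (
            -n * lam
            - 0.5 * ss * np.exp(-2.0 * lam)
            - 0.5 * np.exp(2.0 * lam) / (prior_sd * prior_sd)
            + lam
        )

    y = f(lam0) + np.log(np.random.random())
    w = 0.5
    lo = lam0 - w * np.random.random()
    hi = lo + w
    for _ in range(50):
        if f(lo) <= y:
            break
        lo -= w
    for _ in range(50):
        if f(hi) <= y:
            break
        hi += w
    for _ in range(100):
        lam = lo + (hi - lo) * np.random.random()
        if f(lam) >= y:
            return lam
        if lam < lam0:
            lo = lam
        else:
            hi = lam
    return lam0


@njit(cache=True)
def hier_gibbs_chain(
    choices,
    rewards,
    subj_starts,
    sess_starts,
    group_signs,
    mu_prior_sd,
    delta_prior_sd,
    sigma_prior_sd,
    beta_max,
    n_warmup,
    n_draws,
    seed,
):
    """One MCMC chain for the two-group hierarchical asym5 model.

    Centered parameterization: subject j's unconstrained parameters
    u[j, p] ~ N(mu_p + 0.5*sign_j*delta_p, sigma_p), mapped through a logistic
    (scaled to beta_max for the inverse temperature). Per sweep: exact Gibbs
    draw of (mu_p, delta_p), slice update of sigma_p, and adaptive
    random-walk Metropolis on each u[j, p]. Returns (hyper_draws, u_draws)
    with hyper columns [mu(5), delta(5), sigma(5)].
    """
    np.random.seed(seed)
    n_subj = group_signs.shape[0]
    n_par = 5
    nA = 0.0
    for j in range(n_subj):
        if group_signs[j] > 0:
            nA += 1.0
    nB = n_subj - nA

    u = np.zeros((n_subj, n_par))
    ll = np.empty(n_subj)
    for j in range(n_subj):
        ll[j] = _subject_ll_from_u(
            choices, rewards, sess_starts, subj_starts[j], subj_starts[j + 1], u[j], beta_max
        )
    mu = np.zeros(n_par)
    delta = np.zeros(n_par)
    sigma = np.full(n_par, 0.3)
    step = np.full((n_subj, n_par), 0.3)

    hyper_draws = np.empty((n_draws, 3 * n_par))
    u_draws = np.empty((n_draws, n_subj * n_par))

    total = n_warmup + n_draws
    for sweep in range(total):
        # --- subject-level Metropolis, componentwise -----------------------
        for j in range(n_subj):
            mj_sign = group_signs[j]
            for p in range(n_par):
                m = mu[p] + 0.5 * mj_sign * delta[p]
                old = u[j, p]
                prop = old + step[j, p] * np.random.normal()
                u[j, p] = prop
                ll_new = _subject_ll_from_u(
                    choices,
                    rewards,
                    sess_starts,
                    subj_starts[j],
                    subj_starts[j + 1],
                    u[j],
                    beta_max,
                )
                log_acc = (
                    ll_new
                    - ll[j]
                    - 0.5 * ((prop - m) / sigma[p]) ** 2
                    + 0.5 * ((old - m) / sigma[p]) ** 2
                )
                if np.log(np.random.random()) < log_acc:
                    ll[j] = ll_new
                    if sweep < n_warmup:
                        step[j, p] *= 1.02
                else:
                    u[j, p] = old
                    if sweep < n_warmup:
                        step[j, p] *= 0.98
                if step[j, p] < 0.01:
                    step[j, p] = 0.01
                elif step[j, p] > 3.0:
                    step[j, p] = 3.0

        # --- hyperparameters ----------------------------------------------
        for p in range(n_par):
            # group means of u
            sA = 0.0
            sB = 0.0
            for j in range(n_subj):
                if group_signs[j] > 0:
                    sA += u[j, p]
                else:
                    sB += u[j, p]
            ubarA = sA / nA
            ubarB = sB / nB
            prec = 1.0 / (sigma[p] * sigma[p])
            # 2x2 precision for (mu, delta): priors + group-mean likelihoods
            l00 = 1.0 / (mu_prior_sd * mu_prior_sd) + (nA + nB) * prec
            l01 = 0.5 * (nA - nB) * prec
            l11 = 1.0 / (delta_prior_sd * delta_prior_sd) + 0.25 * (nA + nB) * prec
            b0 = (nA * ubarA + nB * ubarB) * prec
            b1 = 0.5 * (nA * ubarA - nB * ubarB) * prec
            det = l00 * l11 - l01 * l01
            m0 = (l11 * b0 - l01 * b1) / det
            m1 = (l00 * b1 - l01 * b0) / det
            # Cholesky of the 2x2 covariance (inverse precision)
            c00 = l11 / det
            c01 = -l01 / det
            c11 = l00 / det
            a = np.sqrt(c00)
            b_ = c01 / a
            c_ = np.sqrt(c11 - b_ * b_)
            z0 = np.random.normal()
            z1 = np.random.normal()
            mu[p] = m0 + a * z0
            delta[p] = m1 + b_ * z0 + c_ * z1

            ss = 0.0
            for j in range(n_subj):
                d = u[j, p] - (mu[p] + 0.5 * group_signs[j] * delta[p])
                ss += d * d
            lam = _slice_sample_log_sigma(np.log(sigma[p]), n_subj, ss, sigma_prior_sd)
            sigma[p] = np.exp(lam)

        if sweep >= n_warmup:
            k = sweep - n_warmup
            for p in range(n_par):
                hyper_draws[k, p] = mu[p]
                hyper_draws[k, n_par + p] = delta[p]
                hyper_draws[k, 2 * n_par + p] = sigma[p]
            for j in range(n_subj):
                for p in range(n_par):
                    u_draws[k, j * n_par + p] = u[j, p]
    return hyper_draws, u_draws


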