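"""Independent reference implementations used as oracles.

Deliberately plain, step-by-step Python with explicit recursions — written
separately from the package's compiled kernels so agreement between the two
routes is meaningful.
"""

import math

P_FLOOR = 1e-9


def softmax_pair(v_chosen, v_other, beta):
    num = math.exp(beta * v_chosen)
    den = num + math.exp(beta * v_other)
    p = num / den
    return min(max(p, P_FLOOR), 1.0 - P_FLOOR)


def standard_session(choices, rewards, alpha, beta):
    """Returns (nll, list of (V1, V2, rpe, p)) by literal recursion."""
    V = [0.0, 0.0]
    nll = 0.0
    trace = []
    for c, r in zip(choices, rewards):
        p = softmax_pair(V[c], V[1 - c], beta)
        rpe = r - V[c]
        trace.append((V[0], V[1], rpe, p))
        nll -= math.log(p)
        V[c] = V[c] + alpha * rpe
    return nll, trace


def avgrpe_session(choices, rewards, alpha, beta, hw):
    V = [0.0, 0.0]
    avg_prev = 0.0
    nll = 0.0
    trace = []
    for c, r in zip(choices, rewards):
        p = softmax_pair(V[c], V[1 - c], beta)
        rpe = r - V[c]
        avg = alpha * rpe + hw * avg_prev
        trace.append((V[0], V[1], rpe, avg, p))
        nll -= math.log(p)
        V[c] = V[c] + avg
        avg_prev = avg
    return nll, trace


def grs_session(choices, rewards, alpha, beta, alpha_r, w_r):
    V = [0.0, 0.0]
    rtrace = 0.0
    nll = 0.0
    trace = []
    for t, (c, r) in enumerate(zip(choices, rewards)):
        if t > 0:
            rtrace = rtrace + (rewards[t - 1] - rtrace) * alpha_r
        p = softmax_pair(V[c], V[1 - c], beta)
        rpe = r + w_r * rtrace - V[c]
        trace.append((V[0], V[1], rpe, rtrace, p))
        nll -= math.log(p)
        V[c] = V[c] + alpha * rpe
    return nll, trace


def asym5_session(choices, rewards, a_pos, a_neg, g_pos, g_neg, beta):
    V = [0.0, 0.0]
    nll = 0.0
    trace = []
    for c, r in zip(choices, rewards):
        p = softmax_pair(V[c], V[1 - c], beta)
        rpe = r - V[c]
        trace.append((V[0], V[1], rpe, p))
        nll -= math.log(p)
        if r == 1:
            V[c] = V[c] + a_pos * rpe
            V[1 - c] = V[1 - c] * g_pos
        else:
            V[c] = V[c] + a_neg * rpe
            V[1 - c] = V[1 - c] * g_neg
    return nll, trace


def brute_wsls(rows):
    """Stratified WS/LS counts by exhaustive enumeration.

    ``rows`` is a list of dicts with keys session_id, trial_index, choice,
    outcome, block_trial_index, block_type, better_action, valid. Returns
    {(phase, block_type, action_class): [n_wins, n_ws, n_losses, n_ls]}.
    """
    by_session = {}
    for row in rows:
        if row["valid"]:
            by_session.setdefault(row["session_id"], []).append(row)
    counts = {}
    for sess in by_session.values():
        sess = sorted(sess, key=lambda r: r["trial_index"])
        for cur, nxt in zip(sess, sess[1:]):
            phase = "early" if cur["block_trial_index"] <= 6 else "late"
            if cur["better_action"] == "none":
                action_class = "none"
            elif cur["choice"] == cur["better_action"]:
                action_class = "better"
            else:
                action_class = "worse"
            key = (phase, cur["block_type"], action_class)
            c = counts.setdefault(key, [0, 0, 0, 0])
            stay = nxt["choice"] == cur["choice"]
            if cur["outcome"] == 1:
                c[0] += 1
                if stay:
                    c[1] += 1
            else:
                c[2] += 1
                if not stay:
                    c[3] += 1
    return counts


def brute_median_split(values_a, values_b, stays):
    """2x2 median-split p(WS) by enumeration; ties go to 'low'."""
    med_a = sorted(values_a)
    med_b = sorted(values_b)

    def median(xs):
        n = len(xs)
        return xs[n // 2] if n % 2 else 0.5 * (xs[n // 2 - 1] + xs[n // 2])

    ma, mb = median(med_a), median(med_b)
    cells = {}
    for a, b, s in zip(values_a, values_b, stays):
        key = ("high" if a > ma else "low", "high" if b > mb else "low")
        n, k = cells.get(key, (0, 0))
        cells[key] = (n + 1, k + int(s))
    return {k: (k2[1] / k2[0], k2[0]) for k, k2 in cells.items()}
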