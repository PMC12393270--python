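"""Model equations: hand-worked examples, reductions, and trace oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from dynaprl import models
from dynaprl.models import (
    AsymParams,
    AvgRPEParams,
    GRSParams,
    StandardParams,
    asym_update,
    avg_rpe_update,
    grs_update,
    session_negative_log_likelihood,
    softmax_choice_prob,
    standard_update,
)


class TestSoftmax:
    def test_equal_values_give_half(self):
        assert np.allclose(softmax_choice_prob((0.0, 0.0), 7.3), [0.5, 0.5])

    def test_zero_beta_is_random_choice(self):
        assert np.allclose(softmax_choice_prob((5.0, -3.0), 0.0), [0.5, 0.5])

    def test_hand_value(self):
        p = softmax_choice_prob((1.0, 0.0), 2.0)
        assert np.allclose(p, [0.8808, 0.1192], atol=5e-5)

    def test_offset_invariance_and_normalization(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            v = rng.normal(size=2)
            beta = rng.uniform(0, 20)
            p = softmax_choice_prob(v, beta)
            q = softmax_choice_prob(v + rng.normal(), beta)
            assert abs(p.sum() - 1.0) < 1e-12
            assert np.allclose(p, q, atol=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            softmax_choice_prob((np.nan, 0.0), 1.0)


class TestUpdates:
    def test_standard_hand_values(self):
        V, rpe = standard_update([0.0, 0.2], 0, 1, 0.5)
        assert rpe == 1.0 and V[0] == 0.5 and V[1] == 0.2
        V, rpe = standard_update([0.5, 0.2], 0, 0, 0.2)
        assert rpe == -0.5 and np.isclose(V[0], 0.4) and V[1] == 0.2

    def test_standard_alpha_bounds(self):
        with pytest.raises(ValueError):
            standard_update([0.0, 0.0], 0, 1, 1.5)

    def test_avgrpe_reduces_to_standard_at_zero_history_weight(self):
        p = AvgRPEParams(alpha=0.3, beta=2.0, hw=0.0)
        V1, avg = avg_rpe_update([0.1, 0.4], 0.0, 1, 1, p)
        V2, rpe = standard_update([0.1, 0.4], 1, 1, 0.3)
        assert np.allclose(V1, V2) and np.isclose(avg, 0.3 * rpe)

    def test_avgrpe_unrolled_two_rewards(self):
        # alpha=0.5, hw=0.5, RPE sequence forced to (1, 1)
        p = AvgRPEParams(alpha=0.5, beta=1.0, hw=0.5)
        avg = 0.0
        avg = p.alpha * 1.0 + p.hw * avg
        assert avg == 0.5
        avg = p.alpha * 1.0 + p.hw * avg
        assert avg == 0.75

    def test_avgrpe_zero_rpe_fixed_point(self):
        p = AvgRPEParams(alpha=0.4, beta=1.0, hw=0.5)
        V, avg = avg_rpe_update([1.0, 0.3], 0.0, 0, 1, p)  # R=1, V=1 -> RPE=0
        assert avg == 0.0 and np.allclose(V, [1.0, 0.3])

    def test_grs_trace_unrolled(self):
        p = GRSParams(alpha=0.3, beta=1.0, alpha_r=0.5, w_r=0.2)
        V, rt1, _ = grs_update([0.0, 0.0], 0.0, 1, 0, 1, p)
        assert rt1 == 0.5
        _, rt2, _ = grs_update(V, rt1, 1, 0, 1, p)
        assert rt2 == 0.75

    def test_grs_limits(self):
        # alpha_r = 1: trace equals previous reward; alpha_r = 0: frozen
        p1 = GRSParams(0.3, 1.0, 1.0, 0.0)
        _, rt, _ = grs_update([0, 0], 0.4, 1, 0, 1, p1)
        assert rt == 1.0
        p0 = GRSParams(0.3, 1.0, 0.0, 0.0)
        _, rt, _ = grs_update([0, 0], 0.4, 1, 0, 1, p0)
        assert rt == 0.4

    def test_grs_zero_weight_matches_standard_rpe(self):
        p = GRSParams(alpha=0.3, beta=1.0, alpha_r=0.7, w_r=0.0)
        V1, _, rpe1 = grs_update([0.2, 0.1], 0.5, 1, 0, 1, p)
        V2, rpe2 = standard_update([0.2, 0.1], 0, 1, 0.3)
        assert np.allclose(V1, V2) and rpe1 == rpe2

    def test_asym_hand_values(self):
        p = AsymParams(0.6, 0.2, 0.8, 0.5, 1.0)
        V = asym_update([0.0, 0.5], 0, 1, p)
        assert np.allclose(V, [0.6, 0.4])
        V = asym_update([0.5, 0.5], 0, 0, p)
        assert np.allclose(V, [0.4, 0.25])

    def test_asym_nests_standard(self):
        p = AsymParams(0.3, 0.3, 1.0, 1.0, 1.0)
        V1 = asym_update([0.2, 0.7], 1, 1, p)
        V2, _ = standard_update([0.2, 0.7], 1, 1, 0.3)
        assert np.allclose(V1, V2)


def _session_df(choices, rewards, session_id="T0"):
    n = len(choices)
    return pd.DataFrame(
        {
            "session_id": session_id,
            "trial_index": np.arange(1, n + 1),
            "block_id": 0,
            "block_type": "HC",
            "block_trial_index": np.arange(1, n + 1),
            "choice": [("A1", "A2")[c] for c in choices],
            "outcome": rewards,
            "reward_volume": 0.0,
            "better_action": "A1",
            "valid": True,
        }
    )


class TestSessionLikelihood:
    def test_single_symmetric_trial_is_ln2(self):
        df = _session_df([0], [1])
        nll, _ = session_negative_log_likelihood(df, "standard", StandardParams(0.5, 3.0))
        assert np.isclose(nll, np.log(2))

    def test_zero_beta_gives_n_ln2(self):
        df = _session_df([0, 1, 1, 0, 1], [1, 0, 1, 1, 0])
        nll, _ = session_negative_log_likelihood(df, "standard", StandardParams(0.5, 0.0))
        assert np.isclose(nll, 5 * np.log(2))

    def test_empty_session_rejected(self, fixtures):
        with pytest.raises(ValueError):
            session_negative_log_likelihood(
                fixtures["all_invalid"], "standard", StandardParams(0.5, 1.0)
            )

    @pytest.mark.parametrize(
        "model_id,params,oracle",
        [
            ("standard", StandardParams(0.5, 1.0), lambda c, r: oracles.standard_session(c, r, 0.5, 1.0)),
            ("avgrpe", AvgRPEParams(0.4, 2.0, 0.6), lambda c, r: oracles.avgrpe_session(c, r, 0.4, 2.0, 0.6)),
            ("grs", GRSParams(0.4, 2.0, 0.5, -0.4), lambda c, r: oracles.grs_session(c, r, 0.4, 2.0, 0.5, -0.4)),
            ("asym5", AsymParams(0.5, 0.3, 0.9, 0.7, 2.0), lambda c, r: oracles.asym5_session(c, r, 0.5, 0.3, 0.9, 0.7, 2.0)),
        ],
    )
    def test_matches_reference_recursion_on_random_sessions(self, model_id, params, oracle):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(3, 40))
            choices = rng.integers(0, 2, n).tolist()
            rewards = rng.integers(0, 2, n).tolist()
            df = _session_df(choices, rewards)
            nll, latent = session_negative_log_likelihood(df, model_id, params)
            nll_ref, trace_ref = oracle(choices, rewards)
            assert abs(nll - nll_ref) < 1e-12
            V1_ref = [t[0] for t in trace_ref]
            assert np.allclose(latent["V_A1"], V1_ref, atol=1e-12)

    def test_nesting_equalities_on_fixed_session(self, standard_trials):
        sess = standard_trials[standard_trials["session_id"] == "S000"]
        base, _ = session_negative_log_likelihood(sess, "standard", StandardParams(0.37, 3.1))
        for model_id, params in (
            ("avgrpe", AvgRPEParams(0.37, 3.1, 0.0)),
            ("grs", GRSParams(0.37, 3.1, 0.5, 0.0)),
            ("asym5", AsymParams(0.37, 0.37, 1.0, 1.0, 3.1)),
        ):
            nll, _ = session_negative_log_likelihood(sess, model_id, params)
            assert abs(nll - base) < 1e-10

    def test_invalid_trials_are_excluded(self):
        df = _session_df([0, 1, 0, 1], [1, 1, 0, 0])
        df.loc[1, "valid"] = False
        nll, latent = session_negative_log_likelihood(df, "standard", StandardParams(0.5, 2.0))
        # dropping row 1 leaves choices (0, 0, 1), rewards (1, 0, 0)
        assert len(latent) == 3
        nll_ref, _ = oracles.standard_session([0, 0, 1], [1, 0, 0], 0.5, 2.0)
        assert abs(nll - nll_ref) < 1e-12


class TestTraceProperties:
    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=1, max_size=60))
    def test_rtrace_stays_in_unit_interval(self, pairs):
        choices = [p[0] for p in pairs]
        rewards = [p[1] for p in pairs]
        df = _session_df(choices, rewards)
        _, latent = session_negative_log_likelihood(
            df, "grs", GRSParams(0.4, 2.0, 0.6, 0.8)
        )
        assert ((latent["r_trace"] >= 0) & (latent["r_trace"] <= 1)).all()

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=1, max_size=60))
    def test_choice_probabilities_sum_to_one(self, pairs):
        df = _session_df([p[0] for p in pairs], [p[1] for p in pairs])
        _, latent = session_negative_log_likelihood(
            df, "avgrpe", AvgRPEParams(0.3, 4.0, 0.5)
        )
        p1 = latent["p_choice"].to_numpy()
        assert ((p1 > 0) & (p1 < 1)).all()


class TestGenerativeMode:
    def test_greedy_agent_exploits_after_learning(self, task_config):
        rng = np.random.default_rng(23)
        params = StandardParams(alpha=0.5, beta=15.0)
        trials = models.simulate_agent("standard", params, task_config, 10, 300, rng)
        hc_late = trials[
            (trials["block_type"] == "HC") & (trials["block_trial_index"] > 6)
        ]
        frac_better = (hc_late["choice"] == hc_late["better_action"]).mean()
        assert frac_better > 0.75

    def test_zero_beta_agent_chooses_at_random(self, task_config):
        rng = np.random.default_rng(24)
        trials = models.simulate_agent(
            "standard", StandardParams(0.5, 0.0), task_config, 5, 400, rng
        )
        assert abs((trials["choice"] == "A1").mean() - 0.5) < 0.03

    def test_mean_abs_avgrpe_orders_block_types(self, task_config):
        """Uncertainty proxy highest with no contrast, lowest with high contrast."""
        rng = np.random.default_rng(25)
        params = AvgRPEParams(alpha=0.35, beta=4.0, hw=0.55)
        trials = models.simulate_agent("avgrpe", params, task_config, 30, 300, rng)
        merged = models.compute_latents(trials, "avgrpe", params)
        means = merged.groupby("block_type")["abs_avg_rpe"].mean()
        assert means["NC"] > means["LC"] > means["HC"]
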