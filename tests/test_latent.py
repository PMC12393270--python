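"""Latent-state analyses: k blending, logistic slopes, median splits."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import oracles
from dynaprl import latent, models
from dynaprl.latent import (
    K_GRID,
    k_sweep,
    latent_choice_correlation,
    median_split_interaction,
    stay_events,
    weighted_rpe,
)


class TestWeightedRPE:
    def test_full_weight_on_current(self):
        assert weighted_rpe(0.7, -0.3, 1.0) == 0.7

    def test_hand_value(self):
        assert np.isclose(weighted_rpe(1.0, -1.0, 0.8), 0.6)

    def test_constancy(self):
        for k in (0.5, 0.725, 1.0):
            assert np.isclose(weighted_rpe(0.4, 0.4, k), 0.4)

    def test_k_outside_range_rejected(self):
        with pytest.raises(ValueError):
            weighted_rpe(1.0, 0.0, 0.4)

    def test_grid_has_21_points(self):
        assert len(K_GRID) == 21
        assert K_GRID[0] == 0.5 and K_GRID[-1] == 1.0
        assert np.allclose(np.diff(K_GRID), 0.025)


@pytest.fixture(scope="module")
def merged_standard(task_config):
    """Standard-model latents on simulated standard-RL behavior."""
    rng = np.random.default_rng(55)
    params = models.StandardParams(alpha=0.35, beta=4.0)
    trials = models.simulate_agent("standard", params, task_config, 10, 300, rng)
    return models.compute_latents(trials, "standard", params)


class TestStayEvents:
    def test_first_trial_has_zero_previous_rpe(self, merged_standard):
        ev = stay_events(merged_standard)
        firsts = ev.groupby("session_id").head(1)
        assert (firsts["rpe_prev"] == 0.0).all()

    def test_previous_rpe_is_lagged_rpe(self, merged_standard):
        ev = stay_events(merged_standard)
        one = ev[ev["session_id"] == ev["session_id"].iloc[0]]
        assert np.allclose(
            one["rpe_prev"].to_numpy()[1:], one["rpe"].to_numpy()[:-1]
        )


class TestKSweep:
    def test_recovers_generating_k(self, merged_standard):
        """Stay decisions built from wRPE at k=0.8 put the argmax there."""
        rng = np.random.default_rng(56)
        ev = stay_events(merged_standard)
        w = weighted_rpe(ev["rpe"].to_numpy(), ev["rpe_prev"].to_numpy(), 0.8)
        z = (w - w.mean()) / w.std()
        stay = rng.random(len(ev)) < expit(0.4 + 1.2 * z)
        ev = ev.assign(stay=stay)
        wins = ev[ev["outcome"] == 1]
        coefs, best, flagged = latent._sweep_class(wins, wins["stay"].to_numpy(float))
        assert not flagged
        assert abs(best - 0.8) <= 0.05

    def test_null_has_small_coefficients(self, merged_standard):
        rng = np.random.default_rng(57)
        df = merged_standard
        ks = k_sweep(df)  # behavior actually generated by the value policy
        # decouple: shuffle rpe so stay/shift is unrelated to it
        shuffled = df.copy()
        shuffled["rpe"] = rng.permutation(shuffled["rpe"].to_numpy())
        ks_null = k_sweep(shuffled)
        assert np.nanmax(np.abs(ks_null.coef_ws)) < np.nanmax(np.abs(ks.coef_ws))
        assert np.nanmax(np.abs(ks_null.coef_ws)) < 0.15

    def test_too_few_events_flagged(self, merged_standard):
        small = merged_standard.head(10)
        ks = k_sweep(small)
        assert ks.flagged_ws and ks.flagged_ls


class TestLatentChoiceCorrelation:
    def _merged_with_synthetic_stay(self, task_config, slope, predictor, seed):
        """Simulate trials, then rewrite choices so the *stay* decision follows
        a logistic function of the chosen latent predictor."""
        rng = np.random.default_rng(seed)
        params_avg = models.AvgRPEParams(0.35, 4.0, 0.55)
        trials = models.simulate_agent("avgrpe", params_avg, task_config, 10, 300, rng)
        merged = models.compute_latents(trials, "avgrpe", params_avg)
        grs = models.compute_latents(
            trials, "grs", models.GRSParams(0.35, 4.0, 0.4, -0.5)
        )
        merged["r_trace"] = grs["r_trace"]
        x = merged[predictor].to_numpy()
        z = (x - x.mean()) / x.std()
        p_stay = expit(0.8 + slope * z)
        stay = rng.random(len(merged)) < p_stay
        # rebuild the choice sequence so that consecutive-trial relations
        # encode the synthetic stay pattern within each session
        new_choice = np.empty(len(merged), dtype=object)
        for _, idx in merged.groupby("session_id").indices.items():
            cur = "A1"
            for i, row in enumerate(idx):
                new_choice[row] = cur
                if not stay[row]:
                    cur = "A2" if cur == "A1" else "A1"
        merged["choice"] = new_choice
        return merged

    @pytest.mark.parametrize(
        "predictor,slope", [("abs_avg_rpe", -0.8), ("r_trace", 0.8)]
    )
    def test_recovers_sign_of_constructed_effect(self, task_config, predictor, slope):
        merged = self._merged_with_synthetic_stay(task_config, slope, predictor, seed=58)
        table = latent_choice_correlation(
            merged, predictor, "WS", strata=(), restrict_better_late=False
        )
        coef = table["coef"].iloc[0]
        assert np.sign(coef) == np.sign(slope)
        assert abs(coef - slope) < 0.25

    def test_constant_predictor_reports_missing(self, merged_standard):
        df = merged_standard.copy()
        df["abs_avg_rpe"] = 1.0
        table = latent_choice_correlation(
            df, "abs_avg_rpe", "WS", strata=(), restrict_better_late=False
        )
        assert np.isnan(table["coef"].iloc[0])

    def test_zscore_affine_invariance(self, task_config):
        merged = self._merged_with_synthetic_stay(task_config, 0.6, "r_trace", seed=59)
        t1 = latent_choice_correlation(merged, "r_trace", "WS", strata=())
        scaled = merged.copy()
        scaled["r_trace"] = 100.0 * scaled["r_trace"] - 17.0
        t2 = latent_choice_correlation(scaled, "r_trace", "WS", strata=())
        assert np.allclose(t1["coef"], t2["coef"], equal_nan=True)

    def test_slope_recovery_across_effect_sizes(self, task_config):
        for slope in (0.0, -0.5, 1.0):
            merged = self._merged_with_synthetic_stay(
                task_config, slope, "abs_avg_rpe", seed=60 + int(slope * 10)
            )
            table = latent_choice_correlation(
                merged, "abs_avg_rpe", "WS", strata=(), restrict_better_late=False
            )
            assert abs(table["coef"].iloc[0] - slope) < 0.15


class TestMedianSplit:
    def _merged(self, task_config, seed=61):
        rng = np.random.default_rng(seed)
        params = models.AvgRPEParams(0.35, 4.0, 0.55)
        trials = models.simulate_agent("avgrpe", params, task_config, 10, 300, rng)
        merged = models.compute_latents(trials, "avgrpe", params)
        grs = models.compute_latents(trials, "grs", models.GRSParams(0.35, 4.0, 0.4, -0.5))
        merged["r_trace"] = grs["r_trace"]
        return merged

    def test_cells_partition_trials(self, task_config):
        merged = self._merged(task_config)
        cells = median_split_interaction(merged, strata=())
        ev = stay_events(merged)
        n_analyzed = len(
            ev[(ev["phase"] == "late") & (ev["action_class"] == "better") & (ev["outcome"] == 1)]
        )
        assert cells["n"].sum() == n_analyzed

    def test_margins_split_roughly_in_half(self, task_config):
        merged = self._merged(task_config)
        cells = median_split_interaction(merged, strata=()).set_index(["grs", "abs_avg_rpe"])
        n_hi = cells.loc[("high",), "n"].sum()
        n_lo = cells.loc[("low",), "n"].sum()
        assert abs(n_hi - n_lo) <= max(1, 0.05 * (n_hi + n_lo))

    def test_agrees_with_brute_force(self, task_config):
        rng = np.random.default_rng(62)
        for rep in range(50):
            n = int(rng.integers(20, 60))
            grs_vals = rng.random(n)
            unc_vals = rng.random(n)
            stay = rng.random(n) < 0.7
            expected = oracles.brute_median_split(grs_vals.tolist(), unc_vals.tolist(), stay.tolist())
            df = pd.DataFrame(
                {
                    "session_id": "B0",
                    "trial_index": np.arange(1, n + 2),
                    "block_id": 0,
                    "block_type": "HC",
                    "block_trial_index": np.arange(10, n + 11),
                    "choice": "A1",
                    "outcome": 1,
                    "reward_volume": 33.0,
                    "better_action": "A1",
                    "valid": True,
                    "r_trace": np.append(grs_vals, 0.5),
                    "abs_avg_rpe": np.append(unc_vals, 0.5),
                    "rpe": 0.0,
                }
            )
            # encode the stay pattern in the choices
            choices = ["A1"]
            for s in stay:
                choices.append(choices[-1] if s else ("A2" if choices[-1] == "A1" else "A1"))
            df["choice"] = choices
            df["better_action"] = df["choice"]  # every trial counts as 'better'
            cells = median_split_interaction(df, strata=())
            got = {
                (r["grs"], r["abs_avg_rpe"]): (r["p_ws"], r["n"])
                for _, r in cells.iterrows()
                if r["n"] > 0
            }
            for key, (p_exp, n_exp) in expected.items():
                assert got[key][1] == n_exp
                assert np.isclose(got[key][0], p_exp)

    def test_additive_drivers_put_highest_pws_in_highgrs_lowunc_cell(self, task_config):
        rng = np.random.default_rng(63)
        merged = self._merged(task_config, seed=63)
        zg = (merged["r_trace"] - merged["r_trace"].mean()) / merged["r_trace"].std()
        zu = (merged["abs_avg_rpe"] - merged["abs_avg_rpe"].mean()) / merged["abs_avg_rpe"].std()
        p_stay = expit(1.0 + 1.0 * zg - 1.0 * zu)
        stay = rng.random(len(merged)) < p_stay
        new_choice = np.empty(len(merged), dtype=object)
        for _, idx in merged.groupby("session_id").indices.items():
            cur = "A1"
            for row in idx:
                new_choice[row] = cur
                if not stay[row]:
                    cur = "A2" if cur == "A1" else "A1"
        merged = merged.assign(choice=new_choice)
        # make every analyzed trial 'better' so the filter keeps the data
        merged["better_action"] = merged["choice"]
        cells = median_split_interaction(merged, strata=()).set_index(["grs", "abs_avg_rpe"])
        assert cells.loc[("high", "low"), "p_ws"] == cells["p_ws"].max()
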