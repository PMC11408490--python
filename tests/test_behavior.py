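"""Behavioral pipeline: regressors, lasso, mixed models, coherence."""

import numpy as np
import pandas as pd
import pytest

from dopabid import behavior, synth
from dopabid.behavior import REGRESSOR_COLUMNS
from dopabid.synth import AgentParams, SubjectConfig


def brute_force_regressors(trials: pd.DataFrame) -> pd.DataFrame:
    """Naive oracle: recompute every column by scanning backwards per trial."""
    rows = []
    trials = trials.sort_values(["session_id", "trial_index"]).reset_index(drop=True)
    for idx, tr in trials.iterrows():
        if tr["result"] == "failed":
            continue
        sess = trials[
            (trials["session_id"] == tr["session_id"])
            & (trials["trial_index"] < tr["trial_index"])
        ]
        completed = sess[sess["result"] != "failed"]
        same_mag = completed[completed["magnitude_level"] == tr["magnitude_level"]]
        row = {
            "session_id": tr["session_id"],
            "trial_index": tr["trial_index"],
            "reward_value": tr["magnitude_ml"],
            "starting_bid": tr["starting_bid"],
            "prev_total_liquid": tr["cumulative_liquid_ml"],
            "day_of_week": tr["day_of_week"],
            "session_number": tr["session_id"],
            "prev_trial_failure": (
                np.nan if sess.empty else float(sess.iloc[-1]["result"] == "failed")
            ),
            "prev_trial_result": (
                np.nan if completed.empty else float(completed.iloc[-1]["result"] == "win")
            ),
            "prev_result_same_mag": (
                np.nan if same_mag.empty else float(same_mag.iloc[-1]["result"] == "win")
            ),
            "trial_number": tr["trial_index"],
            "win_streak": tr["win_streak"],
            "lose_streak": tr["lose_streak"],
        }
        cb = completed["computer_bid"].to_numpy()
        for k in (1, 2, 3, 5, 7):
            row[f"comp_bid_lag_{k}"] = cb[-k] if len(cb) >= k else np.nan
        cbm = same_mag["computer_bid"].to_numpy()
        for k in range(1, 11):
            row[f"comp_bid_same_mag_lag_{k}"] = cbm[-k] if len(cbm) >= k else np.nan
        for m in range(2, 7):
            row[f"comp_bid_same_mag_mean_{m}"] = cbm[-m:].mean() if len(cbm) >= m else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


class TestBuildRegressors:
    def test_has_all_31_candidate_columns(self, small_trials):
        reg = behavior.build_regressors(small_trials)
        assert len(REGRESSOR_COLUMNS) == 31
        assert all(c in reg.columns for c in REGRESSOR_COLUMNS)

    def test_constant_computer_bid_fills_all_lags(self, small_trials):
        trials = small_trials[small_trials["session_id"] == 0].copy()
        trials["computer_bid"] = 0.4
        trials["result"] = np.where(trials["bid"] >= 0.4, "win", "lose")
        reg = behavior.build_regressors(trials)
        lag_cols = [c for c in reg.columns if c.startswith("comp_bid")]
        vals = reg[lag_cols].to_numpy().ravel()
        vals = vals[~np.isnan(vals)]
        assert np.allclose(vals, 0.4)

    def test_streak_definition_win_win_lose(self):
        # 4 same-magnitude trials: after win, win, lose the entering streaks
        # at the 4th trial are win 0 / lose 1
        base = dict(
            subject="V", session_id=0, magnitude_level="mid", magnitude_ml=1.0,
            starting_bid=0.5, computer_bid=0.3, juice_ml=1.0, water_ml=0.8,
            day_of_week=0, velocity=0.0, absement=0.0, latent_value=0.0,
            t_trial_start=0.0, t_fractal=0.5, t_bidspace=1.5, t_bid_stable=3.0,
            t_computer_reveal=3.5, t_juice=4.5, t_water=6.0,
        )
        results = ["win", "win", "lose", "win"]
        ws, ls = [0, 1, 2, 0], [0, 0, 0, 1]
        rows = [
            dict(base, trial_index=i, bid=0.5, result=r,
                 cumulative_liquid_ml=i * 1.0, win_streak=ws[i], lose_streak=ls[i])
            for i, r in enumerate(results)
        ]
        reg = behavior.build_regressors(pd.DataFrame(rows))
        assert reg.iloc[3]["win_streak"] == 0
        assert reg.iloc[3]["lose_streak"] == 1
        assert reg.iloc[3]["prev_result_same_mag"] == 0.0

    def test_matches_brute_force_oracle(self):
        cfg = SubjectConfig(n_sessions=3, trials_per_session=80)
        for seed in (0, 1):
            trials, _ = synth.simulate_behavior(cfg, seed=seed)
            reg = behavior.build_regressors(trials).set_index(["session_id", "trial_index"])
            oracle = brute_force_regressors(trials).set_index(["session_id", "trial_index"])
            pd.testing.assert_frame_equal(
                reg[oracle.columns].sort_index(), oracle.sort_index(), check_dtype=False
            )

    def test_lags_do_not_cross_sessions(self, small_trials):
        reg = behavior.build_regressors(small_trials)
        first = reg.sort_values(["session_id", "trial_index"]).groupby("session_id").head(1)
        assert first["comp_bid_lag_1"].isna().all()
        assert first["prev_trial_result"].isna().all()


@pytest.fixture(scope="module")
def reg():
    cfg = SubjectConfig(n_sessions=8, trials_per_session=100)
    trials, _ = synth.simulate_behavior(cfg, seed=21)
    return behavior.build_regressors(trials).dropna()


class TestLassoSelect:
    def test_recovers_strong_true_support(self, reg):
        rng = np.random.default_rng(0)
        hits = 0
        for s in range(10):
            y = (
                0.5 * reg["starting_bid"]
                + 0.5 * reg["comp_bid_lag_1"]
                + 0.3 * reg["win_streak"]
                + rng.normal(0, 0.1, len(reg))
            )
            sel = behavior.lasso_select(reg, y, n_folds=10, seed=s)
            hits += {"starting_bid", "comp_bid_lag_1", "win_streak"} <= set(sel.selected)
        assert hits >= 9

    def test_null_response_selects_nothing_most_seeds(self, reg):
        rng = np.random.default_rng(1)
        empties = 0
        for s in range(6):
            y = rng.normal(size=len(reg))
            sel = behavior.lasso_select(reg, y, n_folds=10, seed=s)
            empties += len(sel.selected) == 0
        assert empties >= 4

    def test_one_se_alpha_at_least_min_alpha(self, reg):
        rng = np.random.default_rng(2)
        y = 0.4 * reg["reward_value"] + rng.normal(0, 0.2, len(reg))
        sel = behavior.lasso_select(reg, y, n_folds=10, seed=0)
        assert sel.alpha_1se >= sel.alpha_min

    def test_constant_column_dropped_with_warning(self, reg):
        reg2 = reg.copy()
        reg2["win_streak"] = 0.0
        with pytest.warns(UserWarning, match="constant"):
            sel = behavior.lasso_select(reg2, reg2["bid"], n_folds=5, seed=0)
        assert "win_streak" in sel.dropped_constant


def _agent_with_only(**weights) -> AgentParams:
    base = dict(
        trial_drift_sd=0.0, session_drift_sd=0.0, bid_noise_sd=0.08,
        w_starting_bid=0.0, w_total_liquid=0.0, w_prev_computer_bid=0.0,
        w_prev_result=0.0, w_win_streak=0.0, w_lose_streak=0.0,
    )
    base.update(weights)
    return AgentParams(**base)


class TestMixedModels:
    def test_structural_contract_model2_omits_reward(self, small_trials):
        m1 = behavior.fit_mixed_model(small_trials, 1)
        m2 = behavior.fit_mixed_model(small_trials, 2)
        assert "reward_value" in m1.fixed_effects.index
        assert "reward_value" not in m2.fixed_effects.index
        assert "magnitude" in m2.random_structure

    def test_model3_moves_prev_result_to_random_effects(self, small_trials):
        m3 = behavior.fit_mixed_model(small_trials, 3)
        assert "prev_result_same_mag" not in m3.fixed_effects.index
        assert {"win_streak", "lose_streak"} <= set(m3.fixed_effects.index)
        assert "prev_result" in m3.random_structure

    def test_invalid_model_id(self, small_trials):
        with pytest.raises(ValueError):
            behavior.fit_mixed_model(small_trials, 4)

    def test_recovers_satiety_effect_sign(self):
        cfg = SubjectConfig(
            n_sessions=50, trials_per_session=100,
            agent=_agent_with_only(w_total_liquid=0.3),
        )
        trials, _ = synth.simulate_behavior(cfg, seed=31)
        res = behavior.fit_mixed_model(trials, 2)
        fe = res.fixed_effects.loc["prev_total_liquid"]
        assert fe["coef"] > 0
        assert fe["ci_low"] > 0

    def test_recovers_previous_result_effect_sign(self):
        cfg = SubjectConfig(
            n_sessions=50, trials_per_session=100,
            agent=_agent_with_only(w_prev_result=0.05),
        )
        trials, _ = synth.simulate_behavior(cfg, seed=32)
        res = behavior.fit_mixed_model(trials, 1)
        fe = res.fixed_effects.loc["prev_result_same_mag"]
        assert fe["coef"] > 0
        assert fe["ci_low"] > 0

    def test_null_weights_cover_zero(self):
        cfg = SubjectConfig(n_sessions=20, trials_per_session=100, agent=_agent_with_only())
        covered = 0
        total = 0
        for seed in range(5):
            trials, _ = synth.simulate_behavior(cfg, seed=40 + seed)
            res = behavior.fit_mixed_model(trials, 2)
            for term in res.fixed_effects.index:
                if term == "Intercept":
                    continue
                total += 1
                lo, hi = res.fixed_effects.loc[term, ["ci_low", "ci_high"]]
                covered += lo <= 0 <= hi
        assert covered / total >= 0.8


class TestRankOrder:
    def test_perfectly_ordered_bids(self, small_trials):
        trials = small_trials.copy()
        trials["bid"] = trials["magnitude_ml"] / 2.0
        res = behavior.rank_order_check(trials)
        assert res.rho == pytest.approx(1.0)

    def test_default_config_sessions_mostly_significant(self, small_trials):
        res = behavior.rank_order_check(small_trials)
        assert res.rho > 0.5
        assert res.fraction_significant >= 0.9

    def test_shuffled_bids_near_zero(self, small_trials, rng):
        rhos = []
        for _ in range(20):
            trials = small_trials.copy()
            trials["bid"] = rng.permutation(trials["bid"].to_numpy())
            rhos.append(behavior.rank_order_check(trials).rho)
        assert np.median(np.abs(rhos)) < 0.1


class TestBidCoherence:
    def test_shared_linear_drift_zero_noise_gives_unit_rho(self):
        # a drift linear in trial index survives interpolation exactly, so
        # the shared-value signal yields rho = 1 for every pairing
        cfg = SubjectConfig(n_sessions=2, trials_per_session=120, agent=_agent_with_only())
        trials, _ = synth.simulate_behavior(cfg, seed=50)
        base = dict(zip(("low", "mid", "high"), cfg.agent.base_values))
        trials["bid"] = (
            trials["magnitude_level"].map(base) + 0.002 * trials["trial_index"]
        ).clip(0, 1)
        res = behavior.bid_coherence(trials)
        # flat edge-extrapolation before a level's first sampled trial ties
        # a few ranks, so rho sits just below 1
        for pairing in ("low:mid", "mid:high", "low:high"):
            assert res.summary[pairing]["rho_median"] > 0.99

    def test_shared_ar1_drift_dominating_noise_gives_high_rho(self):
        agent = AgentParams(
            trial_drift_sd=0.05, session_drift_sd=0.0, bid_noise_sd=0.0,
            w_starting_bid=0.0, w_total_liquid=0.0, w_prev_computer_bid=0.0,
            w_prev_result=0.0, w_win_streak=0.0, w_lose_streak=0.0, fail_prob=0.0,
        )
        cfg = SubjectConfig(n_sessions=2, trials_per_session=120, agent=agent)
        trials, _ = synth.simulate_behavior(cfg, seed=50)
        res = behavior.bid_coherence(trials)
        # interpolation makes this a lower bound on the true coherence (1)
        for pairing in ("low:mid", "mid:high", "low:high"):
            assert res.summary[pairing]["rho_median"] > 0.5

    def test_independent_values_near_zero_coherence(self):
        agent = AgentParams(
            trial_drift_sd=0.0, session_drift_sd=0.0, bid_noise_sd=0.08,
            w_starting_bid=0.0, w_total_liquid=0.0, w_prev_computer_bid=0.0,
            w_prev_result=0.0, w_win_streak=0.0, w_lose_streak=0.0,
        )
        cfg = SubjectConfig(n_sessions=4, trials_per_session=120, agent=agent)
        rhos = []
        for seed in range(10):
            trials, _ = synth.simulate_behavior(cfg, seed=60 + seed)
            res = behavior.bid_coherence(trials)
            rhos.extend(res.within["rho"].tolist())
        assert abs(np.median(rhos)) < 0.1

    def test_invariant_to_monotone_transform(self, small_trials):
        res_raw = behavior.bid_coherence(small_trials)
        trans = small_trials.copy()
        trans["bid"] = np.exp(2.0 * trans["bid"])
        res_t = behavior.bid_coherence(trans)
        raw = res_raw.within.set_index(["session_id", "pairing"])["rho"]
        t = res_t.within.set_index(["session_id", "pairing"])["rho"]
        # interpolation happens before ranking, so invariance is approximate
        assert (raw - t).abs().max() < 0.05

    def test_insufficient_trials_skipped(self, small_trials):
        tiny = small_trials.groupby("session_id").head(8)
        res = behavior.bid_coherence(tiny)
        assert len(res.skipped_sessions) == small_trials["session_id"].nunique()
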