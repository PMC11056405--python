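"""Trajectory binning, mixed model, responders, size/rate regressions."""

import numpy as np
import pandas as pd
import pytest

from fbt import analyze, synth
from fbt.episodes import extract_episodes
from oracles import pearson_chi2

T0 = pd.Timestamp("2019-01-01")


def mins(m):
    return T0 + pd.Timedelta(minutes=float(m))


def obs_frame(values_by_min, channel="co", patient_id="P0"):
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "ts": [mins(m) for m in values_by_min],
            "channel": channel,
            "value": list(values_by_min.values()),
        }
    )


def one_episode(start=60.0, end=80.0, kind="bolus", episode_id=0, patient_id="P0"):
    return pd.DataFrame(
        [{"episode_id": episode_id, "patient_id": patient_id, "kind": kind,
          "start_ts": mins(start), "end_ts": mins(end)}]
    )


class TestBonferroni:
    @pytest.mark.parametrize("m, alpha, expected", [
        (31, 0.05, 0.0016),
        (1, 0.05, 0.05),
        (10, 0.05, 0.005),
    ])
    def test_threshold(self, m, alpha, expected):
        assert float(f"{analyze.bonferroni_alpha(m, alpha):.2g}") == expected

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            analyze.bonferroni_alpha(0)


class TestBinning:
    def test_constant_channel_has_zero_changes(self):
        obs = obs_frame({m: 5.0 for m in range(0, 160, 2)})
        binned = analyze.bin_trajectories(obs, one_episode(), ("co",))
        ch = analyze.changes_from_baseline(binned)
        assert np.allclose(ch[[f"d_{k}" for k in analyze.BIN_LABELS]], 0.0)

    def test_bin_means_match_hand_computation(self):
        # episode ends at 80 min; bin 40 covers [115, 120) minutes
        values = {m: float(m) for m in range(0, 160, 2)}
        obs = obs_frame(values)
        binned = analyze.bin_trajectories(obs, one_episode(), ("co",))
        row = binned.iloc[0]
        assert row["bin_40"] == pytest.approx(np.mean([116.0, 118.0]))
        assert row["n_40"] == 2
        # baseline = mean over [30, 60)
        assert row["baseline"] == pytest.approx(np.mean([v for m, v in values.items()
                                                         if 30 <= m < 60]))

    def test_empty_bin_stays_missing(self):
        values = {m: 1.0 for m in range(0, 160, 2) if not (100 <= m < 110)}
        obs = obs_frame(values)
        binned = analyze.bin_trajectories(obs, one_episode(), ("co",))
        row = binned.iloc[0]
        assert np.isnan(row["bin_25"])  # [100, 105) has no samples
        assert row["n_25"] == 0

    def test_episode_without_baseline_omitted(self):
        values = {m: 1.0 for m in range(80, 160, 2)}  # post-window data only
        obs = obs_frame(values)
        binned = analyze.bin_trajectories(obs, one_episode(), ("co",))
        assert binned.empty

    def test_kernel_peak_lands_in_its_bin(self):
        """With channel noise far below the injected effect, the group mean
        change-from-baseline curve peaks where the kernel peaks."""
        quiet = {
            "co": synth.ChannelParams(5.0, 0.02, 0.5, 0.02),
            "map": synth.ChannelParams(75.0, 8.0, 0.9, 7.0),
            "sbp": synth.ChannelParams(112.0, 12.0, 0.9, 10.0),
            "dbp": synth.ChannelParams(52.0, 6.0, 0.9, 6.0),
            "hr": synth.ChannelParams(82.0, 8.0, 0.9, 10.0),
            "cvp": synth.ChannelParams(10.0, 2.5, 0.9, 2.5),
            "sv": synth.ChannelParams(70.0, 12.0, 0.9, 12.0),
        }
        kern = synth.EffectKernel("co", 0.2, peak_time=40.0,
                                  dissipation_half_life=15.0)
        cfg = synth.CohortConfig(n_patients=20, seed=9, channel_params=quiet,
                                 effect_kernels=(kern,), pac_removal_hazard_per_h=0.0)
        cohort = synth.generate_cohort(cfg)
        eps, _ = extract_episodes(cohort.infusions, cohort.patients, seed=1)
        binned = analyze.bin_trajectories(
            cohort.vitals, eps[eps["kind"] == "bolus"], ("co",)
        )
        peak = analyze.peak_group_change(binned, "co", kind="bolus")
        # t = 40 is the boundary between the [35,40) and [40,45) bins and the
        # kernel is near-flat across it
        assert peak.peak_time_min in (40, 45)
        assert peak.estimate == pytest.approx(0.18, abs=0.02)


class TestResponders:
    def _binned(self, rows):
        labels = analyze.BIN_LABELS
        out = []
        for i, (kind, baseline, bins) in enumerate(rows):
            row = {"episode_id": i, "patient_id": f"P{i}", "kind": kind,
                   "variable": "co", "baseline": baseline, "baseline_n": 10}
            for k, v in zip(labels, bins):
                row[f"bin_{k}"] = v
                row[f"n_{k}"] = 0 if np.isnan(v) else 2
            out.append(row)
        return pd.DataFrame(out)

    def test_threshold_rule(self):
        flat = [5.0] * 12
        up = [5.0] * 6 + [5.6] + [5.0] * 5      # +12% peak -> responder
        edge = [5.0] * 11 + [5.5]               # exactly +10% -> not (> rule)
        binned = self._binned(
            [("bolus", 5.0, up), ("bolus", 5.0, edge), ("control", 5.0, flat),
             ("control", 5.0, up)]
        )
        t = analyze.classify_responders(binned, "co")
        assert (t.responders_bolus, t.n_bolus) == (1, 2)
        assert (t.responders_control, t.n_control) == (1, 2)

    def test_zero_baseline_rules(self):
        # VIS off at baseline: any positive post value counts as an increase
        binned = self._binned(
            [("bolus", 0.0, [0.0] * 6 + [2.0] * 6), ("bolus", 0.0, [0.0] * 12),
             ("control", 0.0, [0.0] * 12), ("control", 1.0, [1.05] * 12)]
        )
        t = analyze.classify_responders(binned, "co")
        assert t.responders_bolus == 1
        assert t.responders_control == 0

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(30):
            base = rng.uniform(2, 8)
            bins = base * (1 + rng.normal(0, 0.1, 12))
            rows.append(("bolus" if i % 2 else "control", base, list(bins)))
        binned = self._binned(rows)
        t1 = analyze.classify_responders(binned, "co")
        scaled = binned.copy()
        cols = ["baseline"] + [f"bin_{k}" for k in analyze.BIN_LABELS]
        scaled[cols] = scaled[cols] * 17.3
        t2 = analyze.classify_responders(scaled, "co")
        assert (t1.responders_bolus, t1.responders_control) == (
            t2.responders_bolus, t2.responders_control)
        assert t1.chi2 == pytest.approx(t2.chi2)

    def test_mean_window_rule_differs(self):
        up_late = [5.0] * 11 + [6.5]  # max +30% but window mean +2.5%
        binned = self._binned([("bolus", 5.0, up_late), ("control", 5.0, [5.0] * 12)])
        t_max = analyze.classify_responders(binned, "co", rule="max_bin")
        t_mean = analyze.classify_responders(binned, "co", rule="mean_window")
        assert t_max.responders_bolus == 1
        assert t_mean.responders_bolus == 0

    def test_chi2_equals_hand_formula(self):
        table = [[12, 8], [5, 15]]
        chi2, p = analyze.responder_chi2(table)
        assert chi2 == pytest.approx(pearson_chi2(table))
        assert 0 <= p <= 1


class TestLMM:
    def test_noiseless_data_recovers_exact_coefficients(self):
        """With deterministic outcomes and no between-patient variance the
        mixed model equals the ordinary least-squares solution."""
        rng = np.random.default_rng(0)
        rows = []
        eid = 0
        for p in range(12):
            for kind in ("bolus", "control"):
                baseline = rng.uniform(4, 6)
                row = {"episode_id": eid, "patient_id": f"P{p}", "kind": kind,
                       "variable": "co", "baseline": baseline, "baseline_n": 10}
                for k in analyze.BIN_LABELS:
                    t_c = k - np.mean(analyze.BIN_LABELS)
                    row[f"bin_{k}"] = (
                        1.0 + 0.3 * (kind == "bolus") + 0.01 * t_c
                        + 0.002 * t_c * (kind == "bolus") + 0.9 * baseline
                    )
                    row[f"n_{k}"] = 2
                rows.append(row)
                eid += 1
        binned = pd.DataFrame(rows)
        res = analyze.fit_lmm(binned, "co")
        assert res.coef["bolus"][0] == pytest.approx(0.3, abs=1e-4)
        assert res.coef["baseline"][0] == pytest.approx(0.9, abs=1e-4)
        assert res.coef["bolus:time_c"][0] == pytest.approx(0.002, abs=1e-5)
        assert res.p_bolus < 1e-6
        assert res.n_episodes == 24 and res.n_patients == 12

    def test_requires_both_groups(self):
        rows = []
        for i in range(4):
            row = {"episode_id": i, "patient_id": f"P{i}", "kind": "bolus",
                   "variable": "co", "baseline": 5.0, "baseline_n": 5}
            for k in analyze.BIN_LABELS:
                row[f"bin_{k}"] = 5.0
                row[f"n_{k}"] = 1
            rows.append(row)
        with pytest.raises(ValueError, match="both"):
            analyze.fit_lmm(pd.DataFrame(rows), "co")

    def test_null_cohort_effect_ci_covers_zero(self):
        """On an effect-free unconfounded cohort the FB coefficient's 95% CI
        covers zero (fixed seed)."""
        cfg = synth.CohortConfig(n_patients=50, seed=31, effect_kernels=(),
                                 confounding_strength=0.0)
        cohort = synth.generate_cohort(cfg)
        eps, _ = extract_episodes(cohort.infusions, cohort.patients, seed=2)
        binned = analyze.bin_trajectories(cohort.vitals, eps, ("co",))
        res = analyze.fit_lmm(binned, "co")
        lo, hi = res.coef["bolus"][1], res.coef["bolus"][2]
        assert lo < 0.0 < hi


class TestSizeRate:
    def _toy(self, n=40, seed=0, size_coef=-0.3):
        rng = np.random.default_rng(seed)
        episodes, baselines, rows = [], [], []
        for i in range(n):
            vol = rng.uniform(250, 800)
            rate = rng.uniform(500, 1500)
            base_map = rng.normal(75, 8)
            mean_change = size_coef * vol / 100.0 + 0.05 * (base_map - 75)
            episodes.append(
                {"episode_id": i, "patient_id": f"P{i}", "kind": "bolus",
                 "start_ts": mins(60), "end_ts": mins(80),
                 "volume_ml": vol, "duration_min": vol / rate * 60.0,
                 "mean_rate_ml_h": rate}
            )
            baselines.append(
                {"episode_id": i, "patient_id": f"P{i}", "kind": "bolus",
                 "bl_hr": rng.normal(80, 8), "bl_map": base_map,
                 "bl_sbp": rng.normal(110, 9), "bl_dbp": rng.normal(52, 5),
                 "bl_cvp": rng.normal(10, 2), "bl_vis": rng.uniform(0, 10),
                 "bl_co": rng.normal(5, 1), "bl_sv": rng.normal(70, 10),
                 "age_years": rng.normal(66, 10), "sex": rng.choice(["M", "F"]),
                 "height_cm": rng.normal(171, 9)}
            )
            vis_change = rng.normal(0, 2)
            for var in ("map", "vis"):
                row = {"episode_id": i, "patient_id": f"P{i}", "kind": "bolus",
                       "variable": var,
                       "baseline": base_map if var == "map" else 1.0,
                       "baseline_n": 10}
                for k in analyze.BIN_LABELS:
                    val = row["baseline"] + (mean_change if var == "map" else vis_change)
                    row[f"bin_{k}"] = val
                    row[f"n_{k}"] = 2
                rows.append(row)
        return (pd.DataFrame(rows), pd.DataFrame(baselines),
                pd.DataFrame(episodes))

    def test_recovers_injected_size_effect(self):
        binned, baselines, episodes = self._toy()
        models = analyze.fit_size_rate_models(binned, baselines, episodes,
                                              outcomes=("map",))
        coef, lo, hi = models[0].coef("size_100ml")
        assert coef == pytest.approx(-0.3, abs=1e-6)

    def test_matches_normal_equation_oracle(self):
        binned, baselines, episodes = self._toy(n=20, seed=3)
        model = analyze.fit_size_rate_models(binned, baselines, episodes,
                                             outcomes=("map",))[0]
        # rebuild the design independently and solve by least squares
        df = baselines.set_index("episode_id")
        ch = analyze.changes_from_baseline(binned[binned["variable"] == "map"])
        y = ch.set_index("episode_id")[
            [f"d_{k}" for k in analyze.BIN_LABELS]
        ].mean(axis=1)
        dvis = analyze.changes_from_baseline(binned[binned["variable"] == "vis"])
        dvis = dvis.set_index("episode_id")[
            [f"d_{k}" for k in analyze.BIN_LABELS]
        ].mean(axis=1)
        ep = episodes.set_index("episode_id")
        X = np.column_stack(
            [
                np.ones(len(df)),
                ep["volume_ml"] / 100.0,
                ep["mean_rate_ml_h"] / 60.0,
                dvis.loc[df.index],
                df["bl_hr"], df["bl_map"], df["bl_sbp"], df["bl_dbp"],
                df["bl_cvp"], df["bl_vis"], df["age_years"],
                (df["sex"] == "M").astype(float), df["height_cm"],
            ]
        )
        beta, *_ = np.linalg.lstsq(X, y.loc[df.index].to_numpy(), rcond=None)
        got = model.table.set_index("term")["coef"]
        assert got["size_100ml"] == pytest.approx(beta[1], abs=1e-8)
        assert got["rate_ml_min"] == pytest.approx(beta[2], abs=1e-8)

    def test_rank_deficiency_reported(self):
        binned, baselines, episodes = self._toy(n=25, seed=4)
        baselines["bl_sbp"] = 2.0 * baselines["bl_map"] + 1.0
        with pytest.raises(ValueError, match="rank"):
            analyze.fit_size_rate_models(binned, baselines, episodes,
                                         outcomes=("map",))


class TestCurves:
    def test_change_of_baseline_is_zero_and_summary_shapes(self):
        values = {m: 5.0 for m in range(0, 160, 2)}
        obs = obs_frame(values)
        eps = pd.concat(
            [one_episode(episode_id=0), one_episode(episode_id=1, kind="control")],
            ignore_index=True,
        )
        binned = analyze.bin_trajectories(obs, eps, ("co",))
        ch = analyze.changes_from_baseline(binned)
        assert np.allclose(ch[[f"d_{k}" for k in analyze.BIN_LABELS]], 0.0)
        pairs = pd.DataFrame([{"bolus_episode_id": 0, "control_episode_id": 1}])
        curve = analyze.paired_effect_curve(binned, pairs, "co")
        assert np.allclose(curve["mean_diff"], 0.0)
        summary = analyze.bin_summary(binned)
        assert set(summary["kind"]) == {"bolus", "control"}
        assert "60" in summary.columns
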