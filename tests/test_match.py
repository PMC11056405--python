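"""Propensity estimation, greedy matching, and balance diagnostics."""

import numpy as np
import pandas as pd
import pytest

from fbt import derive, match
from fbt.episodes import extract_episodes
from oracles import optimal_assignment


def _logit(p):
    return np.log(p / (1 - p))


def _inv_logit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x)))


def scored_frame(bolus_logits, control_logits):
    rows = []
    for i, x in enumerate(bolus_logits):
        rows.append({"episode_id": i, "kind": "bolus", "ps": _inv_logit(x)})
    for j, x in enumerate(control_logits):
        rows.append({"episode_id": 100 + j, "kind": "control", "ps": _inv_logit(x)})
    return pd.DataFrame(rows)


class TestBaselines:
    def test_means_use_only_pre_start_window(self):
        t0 = pd.Timestamp("2019-01-01")
        mins = lambda m: t0 + pd.Timedelta(minutes=m)  # noqa: E731
        obs = pd.DataFrame(
            {
                "patient_id": "P0",
                "ts": [mins(m) for m in (10, 40, 50, 58, 60, 70)],
                "channel": "map",
                "value": [100.0, 70.0, 72.0, 74.0, 999.0, 999.0],
            }
        )
        episodes = pd.DataFrame(
            [
                {"episode_id": 0, "patient_id": "P0", "kind": "bolus",
                 "start_ts": mins(60), "end_ts": mins(80)},
            ]
        )
        patients = pd.DataFrame(
            [{"patient_id": "P0", "admit_ts": t0, "discharge_ts": mins(600),
              "age_years": 60.0, "sex": "M", "height_cm": 175.0,
              "weight_kg": 80.0, "apache2": 15, "admission_type": "elective",
              "surgery_type": "cabg", "mechanical_ventilation": True}]
        )
        bl = match.compute_baselines(episodes, obs, patients, channels=("map",))
        # observations at 10 (before window), 60 and 70 (at/after start) excluded
        assert bl.loc[0, "bl_map"] == pytest.approx((70.0 + 72.0 + 74.0) / 3)
        assert bl.loc[0, "bl_map_n"] == 3
        assert bl.loc[0, "time_since_admission_h"] == pytest.approx(1.0)

    def test_min_sample_rule_drops_episode(self):
        t0 = pd.Timestamp("2019-01-01")
        obs = pd.DataFrame(
            {"patient_id": "P0", "ts": [t0 + pd.Timedelta(minutes=50)],
             "channel": "map", "value": [70.0]}
        )
        episodes = pd.DataFrame(
            [{"episode_id": 0, "patient_id": "P0", "kind": "bolus",
              "start_ts": t0 + pd.Timedelta(minutes=60),
              "end_ts": t0 + pd.Timedelta(minutes=80)}]
        )
        patients = pd.DataFrame(
            [{"patient_id": "P0", "admit_ts": t0,
              "discharge_ts": t0 + pd.Timedelta(hours=10),
              "age_years": 60.0, "sex": "M", "height_cm": 175.0,
              "weight_kg": 80.0, "apache2": 15, "admission_type": "elective",
              "surgery_type": "cabg", "mechanical_ventilation": True}]
        )
        bl = match.compute_baselines(episodes, obs, patients, channels=("map",),
                                     min_samples=3)
        assert bl.empty


class TestPropensity:
    def _null_baselines(self, rng, n=400, frac_bolus=0.4):
        kinds = np.where(rng.uniform(size=n) < frac_bolus, "bolus", "control")
        return pd.DataFrame(
            {
                "episode_id": np.arange(n),
                "patient_id": [f"P{i % 50:03d}" for i in range(n)],
                "kind": kinds,
                "bl_map": rng.normal(75, 8, n),
                "bl_hr": rng.normal(80, 10, n),
                "age_years": rng.normal(66, 11, n),
            }
        )

    def test_null_model_scores_near_marginal_fraction(self):
        rng = np.random.default_rng(0)
        bl = self._null_baselines(rng)
        scored = match.estimate_propensity(
            bl, covariates=("bl_map", "bl_hr", "age_years")
        )
        frac = (bl["kind"] == "bolus").mean()
        assert scored["ps"].mean() == pytest.approx(frac, abs=0.02)
        assert scored["ps"].std() < 0.06

    def test_scores_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(1)
        bl = self._null_baselines(rng)
        covs = ("bl_map", "bl_hr", "age_years")
        ps1 = match.estimate_propensity(bl, covariates=covs)["ps"]
        bl2 = bl.assign(bl_map=bl["bl_map"] * 10 + 3)
        ps2 = match.estimate_propensity(bl2, covariates=covs)["ps"]
        assert np.allclose(ps1, ps2, atol=1e-6)

    def test_perfect_separation_raises(self):
        rng = np.random.default_rng(2)
        bl = self._null_baselines(rng, n=100)
        bl["bl_map"] = np.where(bl["kind"] == "bolus", 100.0, 50.0)
        with pytest.raises(ValueError, match="separation|covariate"):
            match.estimate_propensity(bl, covariates=("bl_map", "bl_hr"))

    def test_matching_reduces_map_imbalance(self, confounded_cohort):
        cohort = confounded_cohort
        eps, _ = extract_episodes(cohort.infusions, cohort.patients, seed=3)
        vis_rows = derive.vis_trace(cohort.infusions, cohort.patients)
        bl = match.compute_baselines(eps, [cohort.vitals, vis_rows], cohort.patients)
        scored = match.estimate_propensity(bl)
        res = match.match_pairs(scored, seed=8)
        rep = match.balance(bl, res.pairs)
        t = rep.table.set_index("covariate")
        assert t.loc["bl_map", "sdiff_pre"] > t.loc["bl_map", "sdiff_post"]
        assert t.loc["bl_map", "sdiff_pre"] > 10.0


class TestMatchPairs:
    def test_two_by_two_matches_bruteforce(self):
        # pairwise-distinct distances; optimal = greedy for clustered scores
        b = [0.0, 5.0]
        c = [0.1, 5.3]
        scored = scored_frame(b, c)
        res = match.match_pairs(scored, caliper_sd=1.0, seed=0)
        got = {(r.bolus_episode_id, r.control_episode_id - 100)
               for r in res.pairs.itertuples(index=False)}
        logit = _logit(scored["ps"])
        caliper = 1.0 * logit.std(ddof=1)
        assert got == set(optimal_assignment(b, c, caliper))

    @pytest.mark.parametrize("seed", range(10))
    def test_clustered_sets_match_assignment_oracle(self, seed):
        # each bolus has a designated nearby control; clusters are far apart,
        # so the greedy result must coincide with the optimal assignment
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        centers = np.arange(n) * 4.0 - 6.0
        b = centers + rng.normal(0, 0.05, n)
        c = centers + rng.normal(0, 0.05, n)
        extra = centers[: max(0, n - 2)] + 1.8  # decoys between clusters
        c_all = np.concatenate([c, extra])
        scored = scored_frame(list(b), list(c_all))
        res = match.match_pairs(scored, caliper_sd=0.5, seed=seed)
        logit = _logit(scored["ps"])
        caliper = 0.5 * logit.std(ddof=1)
        oracle = optimal_assignment(list(b), list(c_all), caliper)
        got = {(r.bolus_episode_id, r.control_episode_id - 100)
               for r in res.pairs.itertuples(index=False)}
        assert got == set(oracle)

    def test_empty_control_pool_raises(self):
        scored = scored_frame([0.0, 1.0], [])
        with pytest.raises(ValueError, match="control"):
            match.match_pairs(scored, seed=0)

    def test_identical_scores_all_matched_and_reproducible(self):
        scored = scored_frame([0.3] * 5, [0.3] * 7)
        a = match.match_pairs(scored, seed=4)
        b = match.match_pairs(scored, seed=4)
        assert len(a.pairs) == 5
        pd.testing.assert_frame_equal(a.pairs, b.pairs)
        assert (a.pairs["logit_distance"] == 0).all()

    def test_without_replacement(self):
        rng = np.random.default_rng(3)
        scored = scored_frame(list(rng.normal(0, 1, 30)), list(rng.normal(0, 1, 40)))
        res = match.match_pairs(scored, seed=1)
        assert res.pairs["control_episode_id"].is_unique
        assert res.pairs["bolus_episode_id"].is_unique
        assert (res.pairs["logit_distance"] <= res.caliper).all()

    def test_shrinking_caliper_never_increases_matches(self):
        rng = np.random.default_rng(5)
        scored = scored_frame(list(rng.normal(0, 1, 25)), list(rng.normal(0.5, 1, 30)))
        sizes = []
        for c in (1.0, 0.5, 0.2, 0.1, 0.05):
            try:
                sizes.append(len(match.match_pairs(scored, caliper_sd=c, seed=2).pairs))
            except ValueError:
                sizes.append(0)
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestBalance:
    def _baselines(self, xb, xc):
        nb, nc = len(xb), len(xc)
        return pd.DataFrame(
            {
                "episode_id": np.arange(nb + nc),
                "kind": ["bolus"] * nb + ["control"] * nc,
                "x": list(xb) + list(xc),
            }
        )

    def _pairs(self, bl):
        b = bl[bl["kind"] == "bolus"]["episode_id"].to_numpy()
        c = bl[bl["kind"] == "control"]["episode_id"].to_numpy()
        n = min(len(b), len(c))
        return pd.DataFrame(
            {"bolus_episode_id": b[:n], "control_episode_id": c[:n]}
        )

    def test_identical_groups_have_zero_sdiff(self):
        bl = self._baselines([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        rep = match.balance(bl, self._pairs(bl), covariates=("x",))
        assert rep.table["sdiff_pre"].iloc[0] == 0.0
        assert rep.table["sdiff_post"].iloc[0] == 0.0
        assert rep.all_pass

    def test_hand_computed_sdiff(self):
        # means 1 vs 2, variances 1 and 1 -> SDiff = 100%
        rng = np.random.default_rng(0)
        xb = rng.normal(0, 1, 4000) + 1.0
        xc = rng.normal(0, 1, 4000) + 2.0
        xb = (xb - xb.mean()) / xb.std(ddof=1) + 1.0
        xc = (xc - xc.mean()) / xc.std(ddof=1) + 2.0
        bl = self._baselines(xb, xc)
        rep = match.balance(bl, self._pairs(bl), covariates=("x",))
        assert rep.table["sdiff_pre"].iloc[0] == pytest.approx(100.0, abs=1e-6)

    def test_zero_variance_handling(self):
        bl = self._baselines([1.0, 1.0], [1.0, 1.0])
        rep = match.balance(bl, self._pairs(bl), covariates=("x",))
        assert rep.table["sdiff_pre"].iloc[0] == 0.0
        bl2 = self._baselines([1.0, 1.0], [2.0, 2.0])
        rep2 = match.balance(bl2, self._pairs(bl2), covariates=("x",))
        assert np.isinf(rep2.table["sdiff_pre"].iloc[0])
        assert not rep2.all_pass
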