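"""Subgroup HRs, interaction tests, AD(q), calibration, replicability, VI, KM."""

import math

import numpy as np
import pandas as pd
import pytest

from respscore import evaluation as ev
from respscore import synthetic_trial as st
from respscore import trial_io
from respscore.response_score import overall_treatment_effect


def _labels_from_truth(ds, truth, outcome, threshold=None):
    scores = truth.score(ds.baselines, outcome)
    scores.index = pd.Index(ds.baselines["patient_id"], name="patient_id")
    if threshold is None:
        threshold = float(scores.median())
    return scores, pd.Series(
        np.where(scores <= threshold, "responder", "non_responder"), index=scores.index
    )


class TestSubgroupHR:
    def test_wald_ci_attains_nominal_coverage(self):
        covered, total = 0, 0
        for seed in range(120):
            cfg = st.scenario("main_effect", n_patients=2000, seed=700 + seed,
                              outcomes=["EDSS"], overall_hr=0.6)
            ds, _ = st.simulate_trial(cfg)
            labels = pd.Series("all", index=pd.Index(ds.baselines["patient_id"], name="patient_id"))
            (est,) = ev.subgroup_hr(ds, "EDSS", labels)
            if est.evaluable:
                total += 1
                covered += int(est.ci_low <= 0.6 <= est.ci_high)
        assert total >= 110
        assert 0.90 <= covered / total <= 0.99

    def test_single_patient_group_flagged_not_evaluable(self):
        cfg = st.scenario("null", n_patients=200, seed=1, outcomes=["EDSS"])
        ds, _ = st.simulate_trial(cfg)
        ids = ds.baselines["patient_id"]
        labels = pd.Series(
            ["lonely"] + ["rest"] * (len(ids) - 1), index=pd.Index(ids, name="patient_id")
        )
        ests = {e.group: e for e in ev.subgroup_hr(ds, "EDSS", labels)}
        assert not ests["lonely"].evaluable
        assert ests["rest"].evaluable


class TestInteractionTest:
    def test_power_against_a_real_modifier(self):
        hits = 0
        for seed in range(10):
            cfg = st.scenario("single_modifier", n_patients=2000, seed=800 + seed)
            ds, truth = st.simulate_trial(cfg)
            scores, _ = _labels_from_truth(ds, truth, "EDSS")
            p = ev.interaction_test(ds, "EDSS", scores)
            hits += int(p < 0.20)
        assert hits >= 9

    def test_constant_score_flagged_nan(self):
        cfg = st.scenario("null", n_patients=300, seed=2, outcomes=["EDSS"])
        ds, _ = st.simulate_trial(cfg)
        const = pd.Series(0.5, index=pd.Index(ds.baselines["patient_id"], name="patient_id"))
        assert math.isnan(ev.interaction_test(ds, "EDSS", const))

    def test_binary_label_variant_runs(self):
        cfg = st.scenario("single_modifier", n_patients=2000, seed=3)
        ds, truth = st.simulate_trial(cfg)
        _, labels = _labels_from_truth(ds, truth, "EDSS")
        p = ev.interaction_test(ds, "EDSS", (labels == "responder").astype(float))
        assert 0 <= p <= 1


class TestADq:
    def test_flat_world_auc_near_overall_hr(self):
        cfg = st.scenario("main_effect", n_patients=10000, seed=4, outcomes=["EDSS"],
                          overall_hr=0.75)
        ds, _ = st.simulate_trial(cfg)
        rng = np.random.default_rng(0)
        scores = pd.Series(
            rng.normal(size=ds.n_patients),
            index=pd.Index(ds.baselines["patient_id"], name="patient_id"),
        )  # uninformative score in a no-HTE world
        curve = ev.adq_curve(ds, "EDSS", scores)
        overall = overall_treatment_effect(ds, "EDSS").hr("treat")
        assert curve.auc == pytest.approx(overall, abs=0.05)

    def test_hr_at_full_fraction_equals_overall_estimate(self):
        cfg = st.scenario("table2_like", n_patients=3000, seed=5, outcomes=["EDSS"])
        ds, truth = st.simulate_trial(cfg)
        scores, _ = _labels_from_truth(ds, truth, "EDSS")
        curve = ev.adq_curve(ds, "EDSS", scores)
        overall = overall_treatment_effect(ds, "EDSS").hr("treat")
        assert curve.q[-1] == 1.0
        assert curve.hr_at_q[-1] == overall

    def test_grid_must_include_one(self):
        cfg = st.scenario("null", n_patients=300, seed=6, outcomes=["EDSS"])
        ds, _ = st.simulate_trial(cfg)
        scores = pd.Series(0.0, index=pd.Index(ds.baselines["patient_id"]))
        with pytest.raises(ValueError):
            ev.adq_curve(ds, "EDSS", scores, grid=[0.25, 0.5])


class TestCalibration:
    def test_predicted_means_increase_across_bins(self):
        cfg = st.scenario("table2_like", n_patients=4000, seed=7, outcomes=["T25FW"])
        ds, truth = st.simulate_trial(cfg)
        scores, _ = _labels_from_truth(ds, truth, "T25FW")
        bins = ev.calibration(ds, "T25FW", scores)
        means = [b.predicted_mean_score for b in bins if b.evaluable]
        assert means == sorted(means)

    def test_well_specified_world_is_calibrated(self):
        cfg = st.scenario("table2_like", n_patients=20000, seed=8, outcomes=["EDSS"])
        ds, truth = st.simulate_trial(cfg)
        scores, _ = _labels_from_truth(ds, truth, "EDSS")
        bins = ev.calibration(ds, "EDSS", scores)
        hits = sum(
            1
            for b in bins
            if b.evaluable and b.ci_low <= b.predicted_mean_score <= b.ci_high
        )
        assert hits >= 3

    def test_minimum_bins_enforced(self):
        cfg = st.scenario("null", n_patients=300, seed=9, outcomes=["EDSS"])
        ds, _ = st.simulate_trial(cfg)
        scores = pd.Series(0.0, index=pd.Index(ds.baselines["patient_id"]))
        with pytest.raises(ValueError):
            ev.calibration(ds, "EDSS", scores, n_bins=1)


class TestReplicability:
    def test_single_replicate_rate_is_zero_or_one(self, xy_variable_set):
        cfg = st.scenario("single_modifier", n_patients=600, seed=10)
        ds, _ = st.simulate_trial(cfg)
        res = ev.replicability(ds, "EDSS", xy_variable_set, n_replicates=1, seed=0)
        assert res.pass_rate in (0.0, 1.0)

    def test_reproducible_under_fixed_seed(self, xy_variable_set):
        cfg = st.scenario("single_modifier", n_patients=600, seed=11)
        ds, _ = st.simulate_trial(cfg)
        a = ev.replicability(ds, "EDSS", xy_variable_set, n_replicates=5, seed=3)
        b = ev.replicability(ds, "EDSS", xy_variable_set, n_replicates=5, seed=3)
        assert a.pass_rate == b.pass_rate
        assert a.subset_frequency == b.subset_frequency

    def test_strong_hte_beats_null_on_paired_seeds(self, xy_variable_set):
        cfg_s = st.scenario("single_modifier", n_patients=900, seed=12)
        ds_s, _ = st.simulate_trial(cfg_s)
        cfg_n = st.scenario("null", n_patients=900, seed=12, outcomes=["EDSS"])
        ds_n, _ = st.simulate_trial(cfg_n)
        vs_null = trial_io.VariableSet("small", (("age", "identity"), ("edss", "identity")))
        strong = ev.replicability(ds_s, "EDSS", xy_variable_set, n_replicates=16, seed=5)
        null = ev.replicability(ds_n, "EDSS", vs_null, n_replicates=16, seed=5)
        assert strong.pass_rate > null.pass_rate

    def test_subset_frequencies_sum_to_evaluable(self, xy_variable_set):
        cfg = st.scenario("single_modifier", n_patients=600, seed=13)
        ds, _ = st.simulate_trial(cfg)
        res = ev.replicability(ds, "EDSS", xy_variable_set, n_replicates=6, seed=1)
        assert sum(res.subset_frequency.values()) == res.n_evaluable
        assert res.n_evaluable + res.failures == res.n_replicates


class TestVariableImportance:
    def _planted(self, n=500, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["x1", "x2", "x3"])
        y = (X["x1"] > X["x1"].median()).astype(int)
        return X, y

    def test_planted_signal_dominates(self):
        top, weak = 0, 0
        for seed in range(10):
            X, y = self._planted(seed=seed)
            rows = ev.variable_importance(X, y, n_trees=200, seed=seed)
            ranked = {r.variable: r.pct_vi for r in rows}
            top += int(rows[0].variable == "x1" and ranked["x1"] == 100.0)
            weak += int(ranked["x2"] < 30 and ranked["x3"] < 30)
        assert top >= 9
        assert weak >= 9

    def test_top_variable_pct_is_100(self):
        X, y = self._planted(seed=3)
        rows = ev.variable_importance(X, y, n_trees=100, seed=3)
        assert max(r.pct_vi for r in rows) == 100.0

    def test_permuted_labels_destroy_importance(self):
        X, y = self._planted(seed=4)
        rng = np.random.default_rng(4)
        y_perm = pd.Series(rng.permutation(y.to_numpy()))
        rows = ev.variable_importance(X, y_perm, n_trees=200, seed=4)
        for r in rows:
            assert abs(r.vi) < 0.10

    def test_single_class_labels_rejected(self):
        X, _ = self._planted()
        with pytest.raises(ValueError):
            ev.variable_importance(X, pd.Series(np.ones(len(X))), n_trees=10)


class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        cfg = st.scenario("null", n_patients=100, seed=14, outcomes=["EDSS"],
                          admin_censoring_days=0)
        ds, _ = st.simulate_trial(cfg)
        km = ev.km_summary(ds, "EDSS")
        assert (km["survival"] == 1.0).all()

    def test_all_events_distinct_times_matches_ecdf(self):
        n = 40
        base = pd.DataFrame(
            {"patient_id": [f"P{i}" for i in range(n)], "arm": ["treatment"] * n}
        )
        times = np.arange(1, n + 1) * 10
        events = pd.DataFrame(
            {"patient_id": base["patient_id"], "outcome": "EDSS",
             "time_days": times, "event": 1}
        )
        ds = trial_io.TrialDataset(base, events)
        merged = ds.merged("EDSS")
        km = ev.km_summary(ds, "EDSS")
        for t in (100, 250, 400):
            s = km[km["time_days"] <= t]["survival"].iloc[-1]
            assert s == pytest.approx(1 - (times <= t).mean())

    def test_censoring_does_not_bias_the_estimand(self):
        cfg_full = st.scenario("null", n_patients=10000, seed=15, outcomes=["EDSS"],
                               dropout_prob=0.0)
        cfg_cens = st.scenario("null", n_patients=10000, seed=15, outcomes=["EDSS"],
                               dropout_prob=0.5)
        ds_f, _ = st.simulate_trial(cfg_full)
        ds_c, _ = st.simulate_trial(cfg_cens)

        def s_at(ds, t):
            km = ev.km_summary(ds, "EDSS")
            ctrl = km[km["arm"] == "control"]
            return ctrl[ctrl["time_days"] <= t]["survival"].iloc[-1]

        assert abs(s_at(ds_f, 360) - s_at(ds_c, 360)) <= 0.03
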