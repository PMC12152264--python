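"""Data model, CSV round-trips, splitting, balance and imputation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from respscore import trial_io
from respscore._utils import DegenerateInputError, round_half_up
from respscore.trial_io import (
    CLINICAL_PRACTICE,
    BaselineProfile,
    TrialDataset,
    cohens_d,
    mice_impute,
    read_baseline_table,
    split_train_validation,
    write_baseline_table,
)


def _empty_events():
    return pd.DataFrame(columns=["patient_id", "outcome", "time_days", "event"])


class TestBaselineIO:
    def test_roundtrip_preserves_values_and_missingness(self, baseline_frame, tmp_path):
        df = baseline_frame.copy()
        df.loc[0, "disease_duration"] = np.nan  # missing stays missing, not zero
        path = tmp_path / "b.csv"
        write_baseline_table(df, path)
        back = read_baseline_table(path)
        assert back.shape == df.shape
        assert math.isnan(back.loc[0, "disease_duration"])
        for col in ("age", "edss", "relapses_2y"):
            np.testing.assert_array_equal(back[col].to_numpy(), df[col].to_numpy())

    def test_duplicate_patient_id_rejected(self, tmp_path):
        path = tmp_path / "b.csv"
        path.write_text(
            "patient_id,arm,age,sex,edss,relapses_2y,disease_duration\n"
            "P1,treatment,50,female,4.0,1,10\nP1,control,40,male,5.0,0,5\n"
        )
        with pytest.raises(ValueError, match="P1"):
            read_baseline_table(path)

    def test_unknown_arm_label_names_row(self, tmp_path):
        path = tmp_path / "b.csv"
        path.write_text(
            "patient_id,arm,age,sex,edss,relapses_2y,disease_duration\n"
            "P1,treatment,50,female,4.0,1,10\nP2,armX,40,male,5.0,0,5\n"
        )
        with pytest.raises(ValueError, match="armX"):
            read_baseline_table(path)

    def test_non_numeric_cell_names_column(self, tmp_path):
        path = tmp_path / "b.csv"
        path.write_text(
            "patient_id,arm,age,sex,edss,relapses_2y,disease_duration\n"
            "P1,treatment,fifty,female,4.0,1,10\n"
        )
        with pytest.raises(ValueError, match="age"):
            read_baseline_table(path)

    def test_arm_label_mapping(self, tmp_path):
        path = tmp_path / "b.csv"
        path.write_text(
            "patient_id,arm,age,sex,edss,relapses_2y,disease_duration\n"
            "P1,Siponimod,50,female,4.0,1,10\nP2,Placebo,40,male,5.0,0,5\n"
        )
        back = read_baseline_table(path)
        assert list(back["arm"]) == ["treatment", "control"]


class TestProfileInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"age": 130.0},
            {"edss": 11.0},
            {"relapses_2y": -1},
            {"disease_duration": 0.0},
        ],
    )
    def test_out_of_range_fields_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BaselineProfile(patient_id="P", arm="treatment", **kwargs)

    def test_dataset_rejects_orphan_events(self, baseline_frame):
        ev = pd.DataFrame(
            [{"patient_id": "GHOST", "outcome": "EDSS", "time_days": 90, "event": 1}]
        )
        with pytest.raises(ValueError, match="GHOST"):
            TrialDataset(baseline_frame, ev)


class TestVariableSets:
    def test_tiers_are_nested(self):
        prev: set = set()
        for vs in (
            trial_io.CLINICAL_PRACTICE,
            trial_io.ADVANCED_CLINICAL,
            trial_io.CLINICAL_MRI,
            trial_io.EXPERIMENTAL,
        ):
            current = set(vs.variables)
            assert prev <= current
            prev = current

    def test_design_matrix_transforms(self, baseline_frame):
        design = CLINICAL_PRACTICE.design_matrix(baseline_frame)
        assert list(design.columns) == [
            "age",
            "male",
            "relapses_2y",
            "log10_disease_duration",
            "edss",
        ]
        np.testing.assert_allclose(
            design["log10_disease_duration"], np.log10(baseline_frame["disease_duration"])
        )
        np.testing.assert_array_equal(
            design["male"], (baseline_frame["sex"] == "male").astype(float)
        )


class TestSplit:
    def test_published_cohort_sizes(self, split_1645=None):
        rng = np.random.default_rng(0)
        n = 1645
        base = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "arm": np.where(rng.random(n) < 2 / 3, "treatment", "control"),
                "age": rng.uniform(18, 60, n),
            }
        )
        res = split_train_validation(TrialDataset(base, _empty_events()), 0.7, seed=1)
        assert res.train.n_patients == 1152
        assert res.validation.n_patients == 493

    @pytest.mark.parametrize("n,fraction,expected", [(10, 0.5, 5), (7, 0.5, 4), (9, 0.7, 6)])
    def test_round_half_up_sizes(self, n, fraction, expected):
        base = pd.DataFrame(
            {"patient_id": [f"P{i}" for i in range(n)], "arm": ["treatment"] * n, "age": 40.0}
        )
        res = split_train_validation(TrialDataset(base, _empty_events()), fraction, seed=0)
        assert res.train.n_patients == expected

    def test_partition_and_determinism(self, baseline_frame):
        ds = TrialDataset(baseline_frame, _empty_events())
        r1 = split_train_validation(ds, 0.7, seed=11)
        r2 = split_train_validation(ds, 0.7, seed=11)
        t1 = set(r1.train.baselines["patient_id"])
        v1 = set(r1.validation.baselines["patient_id"])
        assert t1 | v1 == set(baseline_frame["patient_id"])
        assert not (t1 & v1)
        assert t1 == set(r2.train.baselines["patient_id"])

    def test_fraction_out_of_range_rejected(self, baseline_frame):
        ds = TrialDataset(baseline_frame, _empty_events())
        with pytest.raises(ValueError):
            split_train_validation(ds, 1.0, seed=0)

    def test_balance_table_covers_all_variables(self, baseline_frame):
        res = split_train_validation(TrialDataset(baseline_frame, _empty_events()), 0.7, 0)
        names = {b.variable for b in res.balance}
        assert {"arm", "age", "sex", "edss", "relapses_2y", "disease_duration"} <= names


class TestCohensD:
    def test_identical_groups_zero(self):
        r = cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.d == 0 and not r.flag

    def test_proportion_formula_hand_computed(self):
        # p_a=0.5, p_b=1.0, pooled 0.75 -> d = -0.5/sqrt(0.1875)
        r = cohens_d([0, 0, 1, 1], [1, 1, 1, 1], kind="proportion")
        assert r.d == pytest.approx(-0.5 / math.sqrt(0.75 * 0.25))
        assert r.flag

    @settings(derandomize=True, max_examples=25)
    @given(
        hst.lists(hst.floats(-50, 50), min_size=2, max_size=20),
        hst.lists(hst.floats(-50, 50), min_size=2, max_size=20),
    )
    def test_antisymmetry(self, a, b):
        try:
            d_ab = cohens_d(a, b).d
        except DegenerateInputError:
            return
        assert cohens_d(b, a).d == pytest.approx(-d_ab, abs=1e-12)

    def test_degenerate_zero_spread_unequal_means(self):
        with pytest.raises(DegenerateInputError):
            cohens_d([1.0, 1.0], [2.0, 2.0])


class TestMice:
    def _dataset(self, n=120, seed=0, mask=True):
        rng = np.random.default_rng(seed)
        x1 = rng.uniform(0, 1, n)
        base = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "arm": np.where(rng.random(n) < 0.5, "treatment", "control"),
                "x1": x1,
                "x2": 2 * x1,
                "x3": rng.normal(size=n),
            }
        )
        if mask:
            base.loc[7, "x2"] = np.nan
            base.loc[11, "x3"] = np.nan
        return TrialDataset(base, _empty_events()), x1

    def test_no_missing_returns_identical_copies(self):
        ds, _ = self._dataset(mask=False)
        out = mice_impute(ds, n_imputations=10, seed=1)
        assert len(out) == 10
        for d in out:
            pd.testing.assert_frame_equal(
                d.baselines[["x1", "x2", "x3"]], ds.baselines[["x1", "x2", "x3"]]
            )

    def test_deterministic_relation_recovered(self):
        ds, x1 = self._dataset()
        out = mice_impute(ds, n_imputations=3, seed=2, k_pmm=3)
        for d in out:
            assert d.baselines["x2"].iloc[7] == pytest.approx(2 * x1[7], abs=0.25)

    def test_no_missing_cells_remain_and_observed_preserved(self):
        ds, _ = self._dataset()
        out = mice_impute(ds, n_imputations=2, seed=3)
        observed = ds.baselines["x2"].drop(index=7)
        for d in out:
            assert not d.baselines[["x1", "x2", "x3"]].isna().any().any()
            pd.testing.assert_series_equal(d.baselines["x2"].drop(index=7), observed)

    def test_fully_missing_variable_rejected(self):
        ds, _ = self._dataset()
        ds.baselines["x3"] = np.nan
        with pytest.raises(ValueError, match="x3"):
            mice_impute(ds, 2, 0)


def test_round_half_up_matches_printed_convention():
    assert round_half_up(-0.115, 2) == -0.11
    assert round_half_up(0.125, 2) == 0.13
    assert round_half_up(1151.5, 0) == 1152
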