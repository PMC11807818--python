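"""Cohort construction: exclusion rules, landmark, covariate
reclassification, quartile assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from diisurv.cohort import (
    LANDMARK_WEEKS,
    ExclusionLog,
    apply_exclusions,
    assign_quartiles,
    build_cohort,
    classify_bp,
    classify_bp_series,
    dichotomize_age,
    dichotomize_tdi,
    reclassify_education,
)
from diisurv.dietary_scoring import DIIReferenceTable
from diisurv.errors import InvalidInputError


class TestBloodPressure:
    @pytest.mark.parametrize("sp,dp,expected", [
        (118, 76, "normal"),
        (125, 78, "elevated"),
        (118, 85, "stage1"),       # diastolic criterion alone
        (135, 70, "stage1"),
        (125, 85, "stage1"),       # gap case: elevated SP + stage1 DP
        (115, 92, "stage2"),       # diastolic alone reaches stage2
        (140, 70, "stage2"),
        (119, 79, "normal"),
        (120, 79, "elevated"),
        (129, 79, "elevated"),
        (130, 79, "stage1"),
        (139, 89, "stage1"),
        (140, 90, "stage2"),
    ])
    def test_stated_thresholds(self, sp, dp, expected):
        assert classify_bp(sp, dp) == expected

    def test_total_over_positive_grid(self):
        # every positive (SP, DP) pair maps to exactly one category
        sp = np.arange(60, 251)
        dp = np.arange(30, 151)
        SP, DP = np.meshgrid(sp, dp)
        out = classify_bp_series(SP.ravel(), DP.ravel())
        assert set(out.unique()) <= {"normal", "elevated", "stage1", "stage2"}
        assert out.notna().all()
        # scalar and vector paths agree on a subsample
        rng = np.random.default_rng(1)
        for i in rng.integers(0, len(out), 200):
            assert out.iloc[int(i)] == classify_bp(SP.ravel()[i], DP.ravel()[i])

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidInputError):
            classify_bp(0, 80)
        with pytest.raises(InvalidInputError):
            classify_bp(120, -5)


class TestEducation:
    @pytest.mark.parametrize("code,expected", [
        (1, "high"),
        (2, "median"), (5, "median"), (6, "median"),
        (3, "low"), (4, "low"), (7, "low"), (-3, "low"),
    ])
    def test_mapping(self, code, expected):
        assert reclassify_education(code) == expected

    @pytest.mark.parametrize("code", [0, 8, 99, "x", None])
    def test_unknown_codes_rejected(self, code):
        with pytest.raises(InvalidInputError):
            reclassify_education(code)


class TestDichotomize:
    def test_age_boundary_goes_older(self):
        out = dichotomize_age([57, 58, 59])
        assert list(out) == ["younger", "older", "older"]

    def test_tdi_boundary_goes_low(self):
        out = dichotomize_tdi([-3.0, -2.3, -2.2, 4.0])
        assert list(out) == ["low", "low", "high", "high"]

    def test_degenerate_single_group_warns(self):
        with pytest.warns(UserWarning, match="single group"):
            out = dichotomize_age([58.0, 58.0, 58.0])
        assert set(out) == {"older"}


class TestQuartiles:
    def test_published_cohort_size_partition(self):
        rng = np.random.default_rng(0)
        scores = rng.permutation(121_329).astype(float)  # distinct
        q = assign_quartiles(scores)
        counts = q.value_counts()
        assert counts["Q1"] == 30_333
        assert counts["Q2"] == counts["Q3"] == counts["Q4"] == 30_332

    def test_small_example(self):
        q = assign_quartiles(np.arange(1, 9, dtype=float))
        assert list(q) == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]

    def test_all_ties_collapse_to_q1_with_warning(self):
        with pytest.warns(UserWarning, match="Q1"):
            q = assign_quartiles(np.full(10, 3.0))
        assert set(q) == {"Q1"}

    def test_too_few_observations(self):
        with pytest.raises(InvalidInputError):
            assign_quartiles([1.0, 2.0, 3.0])

    @given(st.integers(4, 200), st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=40)
    def test_partition_properties(self, n, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=n)
        q = assign_quartiles(scores)
        counts = q.value_counts().reindex(["Q1", "Q2", "Q3", "Q4"]).fillna(0)
        assert counts.sum() == n
        if len(np.unique(scores)) == n:
            assert counts.max() - counts.min() <= 1
        # monotone: every member of a later quartile >= every earlier member
        for lo, hi in [("Q1", "Q2"), ("Q2", "Q3"), ("Q3", "Q4")]:
            a = scores[np.asarray(q == lo)]
            b = scores[np.asarray(q == hi)]
            if len(a) and len(b):
                assert a.max() <= b.min()


def _raw_tables(reference, n=30, seed=0):
    rng = np.random.default_rng(seed)
    intakes = pd.DataFrame({p: rng.lognormal(np.log(m), 0.2, n) for p, m in zip(
        reference.parameters, reference.table["global_mean"])})
    intakes.insert(0, "participant_id", np.arange(1, n + 1))
    intakes["total_energy_kcal"] = intakes["energy_kcal"]
    cov = pd.DataFrame({
        "participant_id": np.arange(1, n + 1),
        "age": rng.integers(40, 70, n),
        "sex": rng.choice(["female", "male"], n),
        "ethnicity": rng.choice(["white", "others"], n, p=[0.9, 0.1]),
        "education_code": rng.choice([1, 2, 3, 4, 5, 6, 7], n),
        "tdi": rng.normal(-2, 3, n),
        "bmi": rng.uniform(19, 35, n),
        "smoking": rng.choice(["rare", "previous", "current"], n),
        "alcohol": rng.choice(["rare", "previous", "current"], n),
        "physical_activity": rng.choice(["reach", "no-reach"], n),
        "systolic": rng.integers(100, 180, n),
        "diastolic": rng.integers(60, 95, n),
        "diabetes": rng.choice(["no", "yes"], n, p=[0.95, 0.05]),
        "prior_cld": False,
        "prior_malignancy": False,
    })
    fu = pd.DataFrame({
        "participant_id": np.arange(1, n + 1),
        "entry_time_weeks": 0.0,
        "event": rng.choice(["censored", "cld", "death"], n, p=[0.8, 0.1, 0.1]),
        "follow_up_weeks": rng.uniform(60, 600, n),
    })
    return intakes, cov, fu


class TestExclusions:
    def test_landmark_week_40_excluded_week_60_retained(self, reference):
        intakes, cov, fu = _raw_tables(reference, n=2, seed=1)
        fu["event"] = ["cld", "cld"]
        fu["follow_up_weeks"] = [40.0, 60.0]
        retained, log = apply_exclusions(intakes, cov, fu, reference)
        assert list(retained["participant_id"]) == [2]
        assert log.entries == [{"participant_id": 1, "reason": "landmark"}]

    def test_landmark_boundary_day_365_25(self, reference):
        intakes, cov, fu = _raw_tables(reference, n=2, seed=2)
        fu["event"] = ["censored", "censored"]
        fu["follow_up_weeks"] = [LANDMARK_WEEKS - 1e-9, LANDMARK_WEEKS]
        retained, log = apply_exclusions(intakes, cov, fu, reference)
        assert list(retained["participant_id"]) == [2]

    def test_missing_nutrient_logged_as_missing_data(self, reference):
        intakes, cov, fu = _raw_tables(reference, n=3, seed=3)
        intakes.loc[0, "fibre_g"] = np.nan
        retained, log = apply_exclusions(intakes, cov, fu, reference)
        assert log.to_frame().set_index("participant_id").loc[1, "reason"] \
            == "missing-data"

    def test_reason_precedence_missing_before_prior_before_landmark(self, reference):
        intakes, cov, fu = _raw_tables(reference, n=3, seed=4)
        # row 1 trips all three rules -> logged as missing-data only
        intakes.loc[0, "zinc_mg"] = np.nan
        cov.loc[0, "prior_cld"] = True
        fu.loc[0, "follow_up_weeks"] = 10.0
        # row 2 trips prior + landmark -> prior-disease
        cov.loc[1, "prior_malignancy"] = True
        fu.loc[1, "follow_up_weeks"] = 10.0
        retained, log = apply_exclusions(intakes, cov, fu, reference)
        reasons = log.to_frame().set_index("participant_id")["reason"]
        assert reasons.loc[1] == "missing-data"
        assert reasons.loc[2] == "prior-disease"

    def test_empty_input(self, reference):
        intakes, cov, fu = _raw_tables(reference, n=1)
        retained, log = apply_exclusions(intakes.iloc[:0], cov.iloc[:0],
                                         fu.iloc[:0], reference)
        assert retained.empty and len(log) == 0

    def test_duplicate_participant_rejected(self, reference):
        intakes, cov, fu = _raw_tables(reference, n=3)
        intakes = pd.concat([intakes, intakes.iloc[[0]]], ignore_index=True)
        with pytest.raises(InvalidInputError, match="duplicate"):
            apply_exclusions(intakes, cov, fu, reference)

    def test_counts_balance(self, reference):
        intakes, cov, fu = _raw_tables(reference, n=60, seed=5)
        fu.loc[:5, "follow_up_weeks"] = 20.0
        cov.loc[10:12, "prior_cld"] = True
        intakes.loc[20, "tea_g"] = np.nan
        retained, log = apply_exclusions(intakes, cov, fu, reference)
        assert len(retained) + len(log) == 60
        # one reason per excluded row
        assert log.to_frame()["participant_id"].is_unique


class TestBuildCohort:
    def test_analysis_columns_present(self, cohort):
        for col in ["dii", "edii", "dii_quartile", "age_group", "tdi_group",
                    "education", "bp_category", "follow_up_weeks", "event"]:
            assert col in cohort.columns
        assert cohort["follow_up_weeks"].min() >= LANDMARK_WEEKS
        assert cohort["dii_quartile"].value_counts().max() \
            - cohort["dii_quartile"].value_counts().min() <= 1

    def test_retained_plus_excluded_equals_input(self, sim_tables, reference):
        cohortdf, log = build_cohort(sim_tables["intakes"],
                                     sim_tables["covariates"],
                                     sim_tables["followup"])
        assert len(cohortdf) + len(log) == len(sim_tables["intakes"])
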