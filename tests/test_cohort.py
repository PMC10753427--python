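"""Case ascertainment, exclusion ledger, and density-matching semantics."""

import numpy as np
import pandas as pd
import pytest

from medscreen.cohort import (
    DataIntegrityError,
    ShortRiskSetError,
    apply_exclusions,
    ascertain_cases,
    density_match,
    risk_set,
)
from tests.conftest import toy_subjects


def _diag(rows):
    df = pd.DataFrame(rows, columns=["subject_id", "condition", "diagnosis_date"])
    df["diagnosis_date"] = pd.to_datetime(df["diagnosis_date"])
    return df


class TestAscertainment:
    def test_age_boundary_and_window(self):
        subjects = toy_subjects(
            [{"birth_year": 1960}, {"birth_year": 1959}, {"birth_year": 1970}]
        )
        diagnoses = _diag(
            [
                (0, "crc", "2010-05-01"),  # age 50: kept
                (1, "crc", "2010-05-01"),  # age 51: dropped
                (2, "crc", "2020-06-01"),  # outside window: dropped
            ]
        )
        cases = ascertain_cases(diagnoses, subjects)
        assert cases["subject_id"].tolist() == [0]
        assert cases["age_at_index"].tolist() == [50]

    def test_first_diagnosis_wins(self):
        subjects = toy_subjects([{"birth_year": 1975}])
        diagnoses = _diag([(0, "crc", "2012-01-01"), (0, "crc", "2009-03-05")])
        cases = ascertain_cases(diagnoses, subjects)
        assert len(cases) == 1
        assert cases["index_date"].iloc[0] == pd.Timestamp("2009-03-05")

    def test_unknown_subject_raises(self):
        subjects = toy_subjects([{}])
        diagnoses = _diag([(99, "crc", "2010-01-01")])
        with pytest.raises(DataIntegrityError):
            ascertain_cases(diagnoses, subjects)


class TestExclusions:
    def test_enrollment_and_flag_ledger(self):
        subjects = toy_subjects(
            [
                {},  # fully enrolled
                {"enrollment_start": np.datetime64("2010-01-01")},  # short
                {},  # flagged ibd
            ]
        )
        diagnoses = _diag(
            [
                (0, "crc", "2011-06-01"),
                (1, "crc", "2011-06-01"),
                (2, "crc", "2011-06-01"),
                (2, "ibd", "2005-01-01"),
            ]
        )
        cases = ascertain_cases(diagnoses, subjects)
        final, ledger = apply_exclusions(
            cases, diagnoses, subjects[["subject_id", "enrollment_start",
                                        "enrollment_end"]]
        )
        assert ledger == {
            "ascertained": 3,
            "excluded_enrollment": 1,
            "after_enrollment": 2,
            "excluded_flagged": 1,
            "final": 1,
        }
        assert final["subject_id"].tolist() == [0]

    def test_identity_when_nothing_applies(self):
        subjects = toy_subjects([{}, {}])
        diagnoses = _diag([(0, "crc", "2012-01-01"), (1, "crc", "2013-01-01")])
        cases = ascertain_cases(diagnoses, subjects)
        final, ledger = apply_exclusions(
            cases, diagnoses, subjects[["subject_id", "enrollment_start",
                                        "enrollment_end"]]
        )
        assert len(final) == len(cases)
        assert ledger["excluded_enrollment"] == 0
        assert ledger["excluded_flagged"] == 0


def _enrollment(subjects):
    return subjects[["subject_id", "enrollment_start", "enrollment_end"]]


class TestDensityMatch:
    def test_key_violation_never_selected(self):
        subjects = toy_subjects(
            [{}, {"sex": "male"}] + [{} for _ in range(3)]
        )
        diagnoses = _diag([(0, "crc", "2012-01-01")])
        cases = ascertain_cases(diagnoses, subjects)
        matched = density_match(
            cases, subjects, _enrollment(subjects), diagnoses, ratio=3, seed=0
        )
        controls = matched.loc[matched["role"] == "control", "subject_id"]
        assert 1 not in set(controls)

    def test_exact_pool_selected_regardless_of_seed(self):
        subjects = toy_subjects([{} for _ in range(11)])
        diagnoses = _diag([(0, "crc", "2012-01-01")])
        cases = ascertain_cases(diagnoses, subjects)
        picks = []
        for seed in (0, 1, 2):
            matched = density_match(
                cases, subjects, _enrollment(subjects), diagnoses, ratio=10,
                seed=seed,
            )
            picks.append(
                frozenset(matched.loc[matched["role"] == "control", "subject_id"])
            )
        assert picks[0] == picks[1] == picks[2] == frozenset(range(1, 11))

    def test_short_risk_set_raises_unless_allowed(self):
        subjects = toy_subjects([{} for _ in range(5)])
        diagnoses = _diag([(0, "crc", "2012-01-01")])
        cases = ascertain_cases(diagnoses, subjects)
        with pytest.raises(ShortRiskSetError):
            density_match(cases, subjects, _enrollment(subjects), diagnoses,
                          ratio=10, seed=0)
        matched = density_match(
            cases, subjects, _enrollment(subjects), diagnoses, ratio=10, seed=0,
            allow_short_sets=True,
        )
        assert (matched["role"] == "control").sum() == 4

    def test_future_case_serves_as_control_before_diagnosis(self):
        # subject 1 is diagnosed in 2015; at the 2012 index it is still at
        # risk, and with a pool of exactly 10 it must be sampled
        subjects = toy_subjects([{} for _ in range(11)])
        diagnoses = _diag([(0, "crc", "2012-01-01"), (1, "crc", "2015-01-01")])
        cases = ascertain_cases(diagnoses, subjects)
        matched = density_match(
            cases, subjects, _enrollment(subjects), diagnoses, ratio=10, seed=0,
            allow_short_sets=True,  # the 2015 set exhausts the tiny pool
        )
        first_set = matched[matched["set_id"] == 0]
        assert 1 in set(first_set.loc[first_set["role"] == "control", "subject_id"])
        # and subject 1 still heads its own set later
        assert (matched.loc[matched["role"] == "case", "subject_id"] == 1).any()
        # risk-set semantics: its control appearance predates its diagnosis
        appearance = matched[
            (matched["subject_id"] == 1) & (matched["role"] == "control")
        ]["index_date"]
        assert (appearance < pd.Timestamp("2015-01-01")).all()

    def test_controls_not_reused_across_sets(self, small_population):
        from medscreen.synthetic import plant_case_registry

        diagnoses = plant_case_registry(small_population, n_cases=25, seed=3,
                                        min_pool=30)
        cases = ascertain_cases(diagnoses, small_population.subjects)
        final, _ = apply_exclusions(
            cases, diagnoses, small_population.enrollment
        )
        matched = density_match(
            final, small_population.subjects, small_population.enrollment,
            diagnoses, ratio=10, seed=1,
        )
        controls = matched.loc[matched["role"] == "control", "subject_id"]
        assert controls.is_unique
        # matched keys exactly balanced within every set
        merged = matched.merge(small_population.subjects, on="subject_id")
        for key in ("sex", "district", "subpopulation", "ses", "periphery"):
            per_set = merged.groupby("set_id")[key].nunique()
            assert (per_set == 1).all()
        by = merged.pivot_table(index="set_id", columns="role",
                                values="birth_year", aggfunc=list)
        for _, row in by.iterrows():
            case_by = row["case"][0]
            assert all(abs(b - case_by) <= 2 for b in row["control"])

    def test_matches_exhaustive_risk_set_enumeration(self, small_population):
        """On a small fixture, an independent brute-force enumerator agrees
        with the package's candidate pools, and sampled controls lie inside
        them."""
        from medscreen.synthetic import plant_case_registry

        subjects = small_population.subjects.head(200).copy()
        pop_enroll = subjects[["subject_id", "enrollment_start", "enrollment_end"]]
        diagnoses = pd.DataFrame(
            {
                "subject_id": [subjects["subject_id"].iloc[0]],
                "condition": ["crc"],
                "diagnosis_date": [pd.Timestamp("2012-06-01")],
            }
        )
        cases = ascertain_cases(diagnoses, subjects)
        assert len(cases) == 1
        case = subjects.iloc[0].copy()
        case["index_date"] = pd.Timestamp("2012-06-01")

        # brute force, written independently of the package internals
        expected = []
        for _, cand in subjects.iterrows():
            if cand["subject_id"] == case["subject_id"]:
                continue
            if any(
                cand[k] != case[k]
                for k in ("sex", "district", "subpopulation", "ses", "periphery")
            ):
                continue
            if abs(cand["birth_year"] - case["birth_year"]) > 2:
                continue
            if cand["enrollment_start"] > pd.Timestamp("2009-06-01"):
                continue
            if cand["enrollment_end"] < pd.Timestamp("2012-06-01"):
                continue
            expected.append(cand["subject_id"])
        pool = risk_set(case, subjects, pop_enroll, diagnoses)
        assert sorted(pool) == sorted(expected)

        if len(expected) >= 3:
            matched = density_match(
                cases, subjects, pop_enroll, diagnoses, ratio=3, seed=5
            )
            chosen = set(
                matched.loc[matched["role"] == "control", "subject_id"]
            )
            assert chosen <= set(expected)
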